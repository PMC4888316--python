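"""The generators must be deterministic, match their closed forms, and emit
truth sets sufficient to recover every planted signal."""

import numpy as np
import pandas as pd
import pytest

from cnvgwas import synthio
from cnvgwas.synthio import PlantedCnv


def test_marker_map_size_order_and_determinism():
    mm = synthio.generate_marker_map(2, 100, 10_000, 2_000_000, seed=1)
    assert len(mm) == 200
    assert sorted(mm["chromosome"].unique()) == ["1", "2"]
    for _, sub in mm.groupby("chromosome"):
        assert (np.diff(sub["position"]) > 0).all()
    assert mm["gc_fraction"].between(0.2, 0.8).all()
    again = synthio.generate_marker_map(2, 100, 10_000, 2_000_000, seed=1)
    pd.testing.assert_frame_equal(mm, again)


def test_marker_map_gc_follows_sinusoid():
    """Fitting the wave phase by grid search recovers a strong correlation
    between gc_fraction and the generating sinusoid."""
    period = 1_000_000
    mm = synthio.generate_marker_map(1, 1000, 5_000, period, seed=7)
    pos = mm["position"].to_numpy(float)
    gc = mm["gc_fraction"].to_numpy(float)
    best = max(
        np.corrcoef(gc, np.sin(2 * np.pi * pos / period + phi))[0, 1]
        for phi in np.linspace(0, 2 * np.pi, 360, endpoint=False))
    assert best > 0.8


def test_marker_map_rejects_nonpositive_sizes():
    with pytest.raises(ValueError):
        synthio.generate_marker_map(0, 100, 10_000, 1_000_000, seed=1)
    with pytest.raises(ValueError):
        synthio.generate_marker_map(1, 100, -5.0, 1_000_000, seed=1)


@pytest.fixture
def map1000():
    return synthio.generate_marker_map(1, 1000, 10_000, 2_000_000, seed=3)


def test_lrr_null_case_and_determinism(small_map):
    n = 200
    m, _ = synthio.generate_lrr(small_map, n, [], noise_sd=0.2,
                                gc_wave_amplitude=0.0, seed=5)
    col_means = m.lrr.mean(axis=0)
    assert np.abs(col_means).max() < 4 * 0.2 / np.sqrt(n)
    m2, _ = synthio.generate_lrr(small_map, n, [], noise_sd=0.2,
                                 gc_wave_amplitude=0.0, seed=5)
    np.testing.assert_array_equal(m.lrr, m2.lrr)


def test_lrr_planted_loss_mean_matches_closed_form(map1000):
    pos = map1000["position"].to_numpy()
    cnv = PlantedCnv("1", int(pos[100]), int(pos[149]), "loss", 0.3, -1.0)
    noise_sd = 0.15
    m, truth = synthio.generate_lrr(map1000, 100, [cnv], noise_sd=noise_sd,
                                    gc_wave_amplitude=0.0, seed=9)
    carriers = truth.planted[0].carrier_ids
    rows = [m.sample_index(s) for s in carriers]
    in_event = m.lrr[np.ix_(rows, np.arange(100, 150))]
    tol = 3 * noise_sd / np.sqrt(in_event.size)
    assert abs(in_event.mean() - (-1.0)) < tol


def test_lrr_gc_wave_induces_correlation(map1000):
    m, _ = synthio.generate_lrr(map1000, 20, [], noise_sd=0.15,
                                gc_wave_amplitude=0.3, seed=13)
    gc = map1000["gc_fraction"].to_numpy(float)
    corrs = [np.corrcoef(m.lrr[i], gc)[0, 1] for i in range(20)]
    assert min(corrs) > 0.2


def test_lrr_rejects_off_map_event(map1000):
    off = PlantedCnv("9", 1, 100_000, "loss", 0.3, -1.0)
    with pytest.raises(ValueError, match="planted event"):
        synthio.generate_lrr(map1000, 10, [off], noise_sd=0.1,
                             gc_wave_amplitude=0.0, seed=1)


def test_planted_cnv_validates_shift_signs():
    with pytest.raises(ValueError):
        PlantedCnv("1", 1, 100, "loss", 0.3, +0.5)
    with pytest.raises(ValueError):
        PlantedCnv("1", 1, 100, "gain", 0.3, -0.5)


class TestTraits:
    def _cohort(self, map_, n, seed):
        m, truth = synthio.generate_lrr(map_, n, [], noise_sd=0.15,
                                        gc_wave_amplitude=0.0, seed=seed)
        return truth

    def test_null_correlation_structure(self, map1000):
        truth = self._cohort(map1000, 1000, 21)
        geno = pd.DataFrame(index=pd.Index(truth.samples, name="sample_id"))
        traits = synthio.generate_traits(truth, geno, ["A", "B", "C"],
                                         np.eye(3), seed=22)
        ebv = traits.frame[["A_ebv", "B_ebv", "C_ebv"]]
        corr = ebv.corr().to_numpy()
        off_diag = corr[~np.eye(3, dtype=bool)]
        assert np.abs(off_diag).max() < 0.1

    def test_target_correlation_recovered(self, map1000):
        """Two traits generated at r=0.8 come back near 0.8 (the strongest
        weight-gain/conformation correlation seen in real EBV panels)."""
        truth = self._cohort(map1000, 2000, 31)
        geno = pd.DataFrame(index=pd.Index(truth.samples, name="sample_id"))
        traits = synthio.generate_traits(truth, geno, ["WG", "CW"], 0.8, seed=32)
        r = np.corrcoef(traits.ebv("WG"), traits.ebv("CW"))[0, 1]
        assert 0.75 <= r <= 0.85

    def test_ols_recovers_planted_effect(self, map1000):
        pos = map1000["position"].to_numpy()
        cnv = PlantedCnv("1", int(pos[10]), int(pos[19]), "loss", 0.3, -1.0)
        _, truth = synthio.generate_lrr(map1000, 1000, [cnv], noise_sd=0.15,
                                        gc_wave_amplitude=0.0, seed=41)
        geno = truth.genotypes()
        traits = synthio.generate_traits(truth, geno, ["T"], np.eye(1),
                                         effect_map={(0, "T"): 0.5}, seed=42)
        x = geno["cnv0"].to_numpy(float)
        y = traits.ebv("T").to_numpy(float)
        slope = np.polyfit(x, y, 1)[0]
        assert 0.35 <= slope <= 0.65

    def test_rejects_non_positive_definite_target(self, map1000):
        truth = self._cohort(map1000, 10, 51)
        geno = pd.DataFrame(index=pd.Index(truth.samples, name="sample_id"))
        bad = np.array([[1.0, 1.2], [1.2, 1.0]])
        with pytest.raises(ValueError, match="positive definite"):
            synthio.generate_traits(truth, geno, ["A", "B"], bad, seed=52)

    def test_accuracy_range_respected(self, map1000):
        truth = self._cohort(map1000, 300, 61)
        geno = pd.DataFrame(index=pd.Index(truth.samples, name="sample_id"))
        traits = synthio.generate_traits(truth, geno, ["A"], np.eye(1),
                                         accuracy_range=(0.6, 0.7), seed=62)
        assert traits.accuracy("A").between(0.6, 0.7).all()


class TestAnnotations:
    def test_empty_gene_track(self, small_map):
        genes, qtls = synthio.generate_annotations(small_map, 0, 5,
                                                   (100_000, 1_000_000), seed=1)
        assert genes == []
        assert len(qtls) == 5

    def test_wide_qtl_present_for_ci_filter(self, small_map):
        _, qtls = synthio.generate_annotations(small_map, 0, 20,
                                               (35_000_000, 40_000_000), seed=2)
        assert all(q.ci_length > 30_000_000 for q in qtls)

    def test_track_files_byte_identical_for_fixed_seed(self, small_map, tmp_path):
        from cnvgwas import annotate
        for run in ("a", "b"):
            genes, qtls = synthio.generate_annotations(small_map, 10, 5,
                                                       (100_000, 2_000_000), seed=3)
            annotate.write_genepred(genes, tmp_path / f"genes_{run}.tsv")
            annotate.write_qtl_gff3(qtls, tmp_path / f"qtls_{run}.gff3")
        assert (tmp_path / "genes_a.tsv").read_bytes() == \
            (tmp_path / "genes_b.tsv").read_bytes()
        assert (tmp_path / "qtls_a.gff3").read_bytes() == \
            (tmp_path / "qtls_b.gff3").read_bytes()


class TestQpcrFixture:
    def _truth(self, map_, seed=71, n_samples=40):
        pos = map_["position"].to_numpy()
        planted = [
            PlantedCnv("1", int(pos[i * 20]), int(pos[i * 20 + 5]),
                       "loss" if i % 2 == 0 else "gain", 0.4,
                       -1.0 if i % 2 == 0 else 1.0)
            for i in range(5)
        ]
        _, truth = synthio.generate_lrr(map_, n_samples, planted, noise_sd=0.1,
                                        gc_wave_amplitude=0.0, seed=seed)
        return truth

    def test_noiseless_fixture_is_exact(self, map1000):
        from cnvgwas import qpcr
        truth = self._truth(map1000)
        table, copies, states = synthio.generate_qpcr_fixture(
            truth, n_samples=9, ct_noise_sd=0.0, seed=72)
        for s in copies.index:
            for t in copies.columns:
                rq = qpcr.ddct(table, t, s)
                assert rq == pytest.approx(copies.loc[s, t] / 2.0, abs=1e-12)

    def test_two_copies_everywhere_gives_unit_rq(self, map1000):
        from cnvgwas import qpcr
        truth = self._truth(map1000)
        # strip carriers: every sample is then diploid at every target
        for cnv in truth.planted:
            cnv.carrier_ids = []
        table, copies, _ = synthio.generate_qpcr_fixture(
            truth, n_samples=6, ct_noise_sd=0.0, seed=73)
        assert (copies == 2).all().all()
        for s in copies.index:
            assert qpcr.ddct(table, "tgt1", s) == pytest.approx(1.0, abs=1e-12)
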