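"""Trait QC, PCA, BH FDR, and the Freedman-Lane permutation GWAS."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cnvgwas import assoc, synthio
from cnvgwas.assoc import CnvGwas, TraitTable, compute_pcs, fdr_adjust, \
    filter_by_accuracy, trait_correlations
from _oracles import bh_reference


def make_traits(ebv: dict, acc: dict | None = None):
    names = list(ebv)
    n = len(next(iter(ebv.values())))
    frame = pd.DataFrame(index=pd.Index([f"S{i + 1}" for i in range(n)],
                                        name="sample_id"))
    for t in names:
        frame[f"{t}_ebv"] = ebv[t]
        frame[f"{t}_acc"] = (acc or {}).get(t, [0.9] * n)
    return TraitTable(frame)


class TestAccuracyFilter:
    def test_strictly_greater_than(self):
        tt = make_traits({"WG": [1.0, 2.0, 3.0]},
                         {"WG": [0.4, 0.5, 0.6]})
        kept = filter_by_accuracy(tt, "WG", 0.5)
        assert list(kept) == ["S3"]

    def test_all_pass(self):
        tt = make_traits({"WG": [1.0, 2.0]})
        assert len(filter_by_accuracy(tt, "WG", 0.5)) == 2

    def test_missing_ebv_excluded(self):
        tt = make_traits({"WG": [1.0, np.nan]}, {"WG": [0.9, 0.8]})
        assert list(filter_by_accuracy(tt, "WG", 0.5)) == ["S1"]

    def test_empty_result_names_trait(self):
        tt = make_traits({"WG": [1.0]}, {"WG": [0.1]})
        with pytest.raises(ValueError, match="WG"):
            filter_by_accuracy(tt, "WG", 0.5)


class TestTraitCorrelations:
    def test_self_and_anticorrelation(self):
        tt = make_traits({"A": [1.0, 2.0, 3.0], "B": [3.0, 2.0, 1.0]})
        corr = trait_correlations(tt)
        assert corr.loc["A", "A"] == pytest.approx(1.0)
        assert corr.loc["A", "B"] == pytest.approx(-1.0)
        assert corr.loc["B", "A"] == corr.loc["A", "B"]

    def test_generated_r08_recovered_at_cohort_scale(self):
        """At the 2013-animal complete-case scale the generated r=0.8
        between weight gain and conformation is estimated tightly."""
        rng = np.random.default_rng(7)
        samples = [f"S{i}" for i in range(2013)]
        truth = synthio.TruthSet(planted=[], samples=samples)
        geno = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
        tt = synthio.generate_traits(truth, geno, ["WG", "CW"], 0.8, seed=71)
        corr = trait_correlations(tt)
        assert 0.77 <= corr.loc["WG", "CW"] <= 0.83

    def test_zero_variance_trait_is_nan_with_warning(self, caplog):
        tt = make_traits({"A": [1.0, 1.0, 1.0], "B": [1.0, 2.0, 3.0]})
        with caplog.at_level("WARNING"):
            corr = trait_correlations(tt)
        assert np.isnan(corr.loc["A", "B"])
        assert any("zero-variance" in r.message for r in caplog.records)


class TestPcs:
    def test_rank_one_matrix_single_component(self):
        base = np.array([0, 1, 2, 1, 0, 2, 1, 0], dtype=float)
        G = pd.DataFrame(np.column_stack([base, 2 - base, base]),
                         index=[f"S{i}" for i in range(8)],
                         columns=["a", "b", "c"])
        pcs = compute_pcs(G, 1)
        X = (G - G.mean()) / G.std(ddof=0)
        total = (X.to_numpy() ** 2).sum()
        explained = (pcs.to_numpy() ** 2).sum()
        assert explained == pytest.approx(total, rel=1e-10)

    def test_matches_dense_eigendecomposition(self):
        rng = np.random.default_rng(3)
        G = pd.DataFrame(rng.integers(0, 3, size=(20, 10)).astype(float),
                         index=[f"S{i}" for i in range(20)])
        pcs = compute_pcs(G, 4).to_numpy()
        X = G.to_numpy()
        X = (X - X.mean(axis=0)) / X.std(axis=0)
        evals, evecs = np.linalg.eigh(X @ X.T)
        order = np.argsort(evals)[::-1][:4]
        for j, k in enumerate(order):
            ref = evecs[:, k] * np.sqrt(evals[k])
            got = pcs[:, j]
            assert np.allclose(got, ref, atol=1e-8) or \
                np.allclose(got, -ref, atol=1e-8)

    def test_pc1_separates_planted_subpopulations(self):
        labels = np.array(["A"] * 100 + ["B"] * 100)
        G = synthio.generate_genotype_matrix(
            200, 200, seed=5, variant_freq_range=(0.2, 0.7),
            subpop_labels=labels, subpop_freq_shift=0.6)
        pcs = compute_pcs(G, 2)
        z = (labels == "A").astype(float)
        r = np.corrcoef(pcs["PC1"], z)[0, 1]
        assert abs(r) > 0.9

    def test_argument_checks(self):
        G = pd.DataFrame(np.eye(4), index=list("abcd"))
        with pytest.raises(ValueError):
            compute_pcs(G, 0)
        with pytest.raises(ValueError):
            compute_pcs(G, 4)


class TestFdr:
    def test_hand_computed_case(self):
        q = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_one(self):
        np.testing.assert_allclose(fdr_adjust([1.0]), [1.0])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])

    def test_matches_independent_implementations(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(11)
        for _ in range(100):
            p = rng.uniform(1e-6, 1.0, size=int(rng.integers(1, 40)))
            q = fdr_adjust(p)
            _, q_sm, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(q, q_sm, atol=1e-12)
        # and the literal textbook min-over-j definition
        p = rng.uniform(1e-6, 1.0, size=25)
        np.testing.assert_allclose(fdr_adjust(p), bh_reference(p), atol=1e-12)

    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1,
                    max_size=50))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_monotone_in_sorted_order_and_capped(self, p):
        q = fdr_adjust(p)
        assert (q <= 1.0).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(np.asarray(q)[order]) >= -1e-12).all()


class TestGwas:
    def _planted_fit(self, beta, n=500, n_events=20, perms=2000, seed=31):
        G = synthio.generate_genotype_matrix(n, n_events, seed=seed,
                                             variant_freq_range=(0.3, 0.3),
                                             gain_fraction=0.0)
        rng = np.random.default_rng(seed + 1)
        y = pd.Series(rng.normal(0, 1, n) + beta * G["cnv0"].to_numpy(float),
                      index=G.index)
        model = CnvGwas(G, y)
        return model.fit(n_permutations=perms, seed=seed + 2)

    def test_planted_effect_recovered_significant(self):
        res = self._planted_fit(0.8)
        rec = res.record("cnv0")
        assert rec["significant"]
        assert 0.6 <= rec["beta_hat"] <= 1.0

    def test_p_perm_floor_and_range(self):
        res = self._planted_fit(2.0, perms=500)
        p = res.frame["p_perm"]
        assert (p >= 1 / 501).all()
        assert (p <= 1.0).all()

    def test_bit_reproducible_for_fixed_seed(self):
        a = self._planted_fit(0.3, perms=300, seed=41).frame
        b = self._planted_fit(0.3, perms=300, seed=41).frame
        pd.testing.assert_frame_equal(a, b)

    def test_zero_variance_event_flagged_not_fatal(self):
        G = synthio.generate_genotype_matrix(100, 5, seed=51)
        G["cnv4"] = 1  # constant
        y = pd.Series(np.random.default_rng(52).normal(size=100), index=G.index)
        res = CnvGwas(G, y).fit(n_permutations=200, seed=53)
        rec = res.record("cnv4")
        assert rec["zero_variance"]
        assert np.isnan(rec["beta_hat"]) and np.isnan(rec["p_perm"])

    def test_detection_rate_monotone_in_effect_size(self):
        rates = []
        for beta in (0.2, 0.5, 1.0):
            hits = 0
            for seed in range(20):
                res = self._planted_fit(beta, n=200, n_events=10, perms=300,
                                        seed=1000 + 37 * seed)
                hits += bool(res.record("cnv0")["significant"])
            rates.append(hits / 20)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] > rates[0]

    def test_correlated_traits_share_the_hit(self):
        """Two strongly correlated traits with a shared planted effect both
        flag the same CNV."""
        n = 600
        G = synthio.generate_genotype_matrix(n, 15, seed=61,
                                             variant_freq_range=(0.3, 0.3),
                                             gain_fraction=0.0)
        truth = synthio.TruthSet(planted=[], samples=list(G.index))
        tt = synthio.generate_traits(
            truth, G, ["MW", "MY"], 0.9,
            effect_map={("cnv0", "MW"): 0.6, ("cnv0", "MY"): 0.6}, seed=62)
        hits = {}
        for trait in ("MW", "MY"):
            res = assoc.associate(G, tt, trait, None, n_permutations=1000,
                                  seed=63, alpha=0.05)
            hits[trait] = set(res.significant_cnvs())
        assert "cnv0" in hits["MW"] and "cnv0" in hits["MY"]

    def test_summary_mentions_counts(self):
        res = self._planted_fit(1.0, n=200, n_events=5, perms=200)
        text = res.summary()
        assert "events tested: 5" in text
        assert "n=200" in text
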