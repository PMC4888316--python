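"""Synthetic SNP-array cohorts with planted CNVs and full truth sets.

The generators emulate the structure of a high-density bovine genotyping
cohort: an autosomal marker map with smoothly varying GC content, a
samples-by-markers Log R Ratio (LRR) matrix with planted loss/gain events
and a shared GC-waviness term, correlated multi-trait EBV phenotypes with
additive CNV effects and optional population stratification, gene/QTL
annotation tracks, and triplicate qPCR CT fixtures following the
CT = reference - log2(copies/2) model.  Every generator is a pure
function of its arguments including the seed, and every planted signal is
recorded in a :class:`TruthSet` so recovery can be scored exactly.

Default magnitudes: a one-copy loss shifts LRR by about -0.55 and a
three-copy gain by about +0.4 on real arrays; tests often use -1.0/+1.0
for a cleanly separable benchmark.  Noise is i.i.d. Gaussian per marker by
default, with an optional AR(1) knob for robustness checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .assoc import TraitTable
from .annotate import GeneRecord, QtlRecord
from .intensity import IntensityMatrix

DEFAULT_TRAITS = ["BW", "PWG", "WG", "CW", "MW", "PW", "CY", "MY", "PY"]


@dataclass
class PlantedCnv:
    """A planted copy-number event: span, state, shift and carriers."""

    chromosome: str
    start_bp: int
    end_bp: int
    state: str  # 'loss' or 'gain'
    carrier_fraction: float
    lrr_shift: float
    carrier_ids: list = field(default_factory=list)

    def __post_init__(self):
        if self.end_bp < self.start_bp:
            raise ValueError("end_bp < start_bp")
        if self.state not in ("loss", "gain"):
            raise ValueError("state must be 'loss' or 'gain'")
        if not (0.0 < self.carrier_fraction <= 1.0):
            raise ValueError("carrier_fraction must be in (0, 1]")
        if self.state == "loss" and self.lrr_shift >= 0:
            raise ValueError("loss events need a negative lrr_shift")
        if self.state == "gain" and self.lrr_shift <= 0:
            raise ValueError("gain events need a positive lrr_shift")

    @property
    def dose(self) -> int:
        return 0 if self.state == "loss" else 2


@dataclass
class TruthSet:
    """Ground truth emitted alongside generated data.

    ``trait_effects`` maps (planted-event index, trait name) to the
    additive effect per unit dose; ``subpopulations`` labels each sample
    and ``subpop_offsets`` gives the phenotype offset added per label.
    """

    planted: list
    samples: list
    trait_effects: dict = field(default_factory=dict)
    subpopulations: dict = field(default_factory=dict)
    subpop_offsets: dict = field(default_factory=dict)

    def genotypes(self) -> pd.DataFrame:
        """Dose matrix {0,1,2} implied by the planted events (samples x cnv<i>)."""
        data = {}
        for i, cnv in enumerate(self.planted):
            carriers = set(cnv.carrier_ids)
            data[f"cnv{i}"] = [cnv.dose if s in carriers else 1
                               for s in self.samples]
        return pd.DataFrame(data, index=pd.Index(self.samples, name="sample_id"),
                            dtype=np.int8)

    def to_json(self, path) -> None:
        payload = {
            "planted": [asdict(p) for p in self.planted],
            "samples": list(self.samples),
            "trait_effects": [
                {"cnv_index": k[0], "trait": k[1], "beta": v}
                for k, v in self.trait_effects.items()],
            "subpopulations": dict(self.subpopulations),
            "subpop_offsets": dict(self.subpop_offsets),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthSet":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            planted=[PlantedCnv(**p) for p in payload["planted"]],
            samples=payload["samples"],
            trait_effects={(d["cnv_index"], d["trait"]): d["beta"]
                           for d in payload["trait_effects"]},
            subpopulations=payload.get("subpopulations", {}),
            subpop_offsets=payload.get("subpop_offsets", {}),
        )


# ---------------------------------------------------------------------------
# Marker map

def generate_marker_map(n_chromosomes: int, markers_per_chromosome: int,
                        mean_spacing_bp: float, gc_wave_period_bp: float,
                        seed: int, gc_amplitude: float = 0.25,
                        gc_noise_sd: float = 0.02) -> pd.DataFrame:
    """Autosome-style marker map with sinusoidal GC content.

    Marker spacings are exponential with the given mean; GC fraction is
    0.5 + gc_amplitude * sin(2*pi*pos/period + phase) plus Gaussian noise,
    clipped to [0.2, 0.8] (one random phase per chromosome).
    """
    if min(n_chromosomes, markers_per_chromosome) <= 0:
        raise ValueError("counts must be positive")
    if mean_spacing_bp <= 0 or gc_wave_period_bp <= 0:
        raise ValueError("spacings must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(1, n_chromosomes + 1):
        gaps = np.maximum(1, np.round(
            rng.exponential(mean_spacing_bp, markers_per_chromosome))).astype(np.int64)
        pos = np.cumsum(gaps)
        phase = rng.uniform(0, 2 * np.pi)
        gc = (0.5 + gc_amplitude * np.sin(2 * np.pi * pos / gc_wave_period_bp + phase)
              + rng.normal(0, gc_noise_sd, markers_per_chromosome))
        gc = np.clip(gc, 0.2, 0.8)
        for j in range(markers_per_chromosome):
            rows.append((f"M{c}_{j + 1:06d}", str(c), int(pos[j]), float(gc[j])))
    return pd.DataFrame(rows, columns=["marker_id", "chromosome",
                                       "position", "gc_fraction"])


# ---------------------------------------------------------------------------
# LRR matrix

def _event_marker_mask(marker_map: pd.DataFrame, cnv: PlantedCnv) -> np.ndarray:
    return ((marker_map["chromosome"].astype(str) == str(cnv.chromosome))
            & (marker_map["position"] >= cnv.start_bp)
            & (marker_map["position"] <= cnv.end_bp)).to_numpy()


def generate_lrr(marker_map: pd.DataFrame, n_samples: int, planted,
                 noise_sd: float, gc_wave_amplitude: float, seed: int,
                 ar1: float = 0.0, sample_prefix: str = "S"):
    """LRR matrix with planted events, GC waviness and Gaussian noise.

    Baseline is Normal(0, noise_sd) per entry (optionally AR(1) along each
    chromosome); carriers of each planted event get its lrr_shift added
    over the event's markers; all samples share the GC term
    gc_wave_amplitude * (gc - mean gc).  Returns (matrix, truth).
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    rng = np.random.default_rng(seed)
    samples = [f"{sample_prefix}{i + 1:04d}" for i in range(n_samples)]
    n_markers = len(marker_map)

    lrr = rng.normal(0.0, noise_sd, size=(n_samples, n_markers))
    if ar1:
        if not (0 <= ar1 < 1):
            raise ValueError("ar1 must be in [0, 1)")
        scale = np.sqrt(1 - ar1 ** 2)
        chrom = marker_map["chromosome"].to_numpy()
        for c in pd.unique(chrom):
            cols = np.flatnonzero(chrom == c)
            for k in range(1, len(cols)):
                lrr[:, cols[k]] = (ar1 * lrr[:, cols[k - 1]]
                                   + scale * lrr[:, cols[k]])

    placed = []
    for cnv in planted:
        mask = _event_marker_mask(marker_map, cnv)
        if mask.sum() < 3:
            raise ValueError(
                f"planted event {cnv.chromosome}:{cnv.start_bp}-{cnv.end_bp} "
                f"spans {int(mask.sum())} markers of the map (need >= 3)")
        if cnv.carrier_ids:
            unknown = set(cnv.carrier_ids) - set(samples)
            if unknown:
                raise ValueError(f"carrier ids not in cohort: {sorted(unknown)}")
            carriers = list(cnv.carrier_ids)
        else:
            n_car = max(1, round(cnv.carrier_fraction * n_samples))
            carriers = sorted(rng.choice(samples, size=n_car, replace=False))
        rows = [samples.index(s) for s in carriers]
        lrr[np.ix_(rows, np.flatnonzero(mask))] += cnv.lrr_shift
        placed.append(replace(cnv, carrier_ids=list(carriers)))

    if gc_wave_amplitude:
        gc = marker_map["gc_fraction"].to_numpy(float)
        lrr += gc_wave_amplitude * (gc - gc.mean())

    matrix = IntensityMatrix(samples=samples,
                             marker_map=marker_map.reset_index(drop=True),
                             lrr=lrr, corrected=False)
    return matrix, TruthSet(planted=placed, samples=samples)


# ---------------------------------------------------------------------------
# Traits

def _corr_matrix(trait_corr_target, k: int) -> np.ndarray:
    if np.isscalar(trait_corr_target):
        corr = np.full((k, k), float(trait_corr_target))
        np.fill_diagonal(corr, 1.0)
    else:
        corr = np.asarray(trait_corr_target, dtype=float)
        if corr.shape != (k, k):
            raise ValueError(f"correlation target must be {k}x{k}")
    try:
        np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        raise ValueError("trait correlation target is not positive definite")
    return corr


def generate_traits(truth: TruthSet, genotypes: pd.DataFrame,
                    trait_names, trait_corr_target, effect_map=None,
                    accuracy_range=(0.5, 0.99), seed: int = 0) -> TraitTable:
    """Correlated EBV phenotypes with additive CNV effects.

    Base traits are multivariate normal (unit variance, the requested
    correlation); planted effects add beta * dose; samples in a labelled
    subpopulation additionally get that label's offset on every trait.
    Accuracies are uniform in ``accuracy_range``, independent of values.
    """
    samples = list(genotypes.index)
    if set(samples) - set(truth.samples):
        raise ValueError("genotypes and truth refer to different cohorts")
    k = len(trait_names)
    corr = _corr_matrix(trait_corr_target, k)
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(corr)
    Y = rng.standard_normal((len(samples), k)) @ L.T

    effect_map = dict(effect_map or {})
    for (cnv_key, trait), beta in effect_map.items():
        col = cnv_key if isinstance(cnv_key, str) else f"cnv{cnv_key}"
        if col not in genotypes.columns:
            raise ValueError(f"effect on unknown genotype column {col!r}")
        if trait not in trait_names:
            raise ValueError(f"effect on unknown trait {trait!r}")
        Y[:, trait_names.index(trait)] += beta * genotypes[col].to_numpy(float)
        idx = (int(col[3:]) if col.startswith("cnv") and col[3:].isdigit()
               else col)
        truth.trait_effects[(idx, trait)] = float(beta)

    if truth.subpopulations:
        offsets = np.array([truth.subpop_offsets.get(
            truth.subpopulations.get(s, None), 0.0) for s in samples])
        Y += offsets[:, None]

    lo, hi = accuracy_range
    acc = rng.uniform(lo, hi, size=(len(samples), k))
    frame = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    for j, t in enumerate(trait_names):
        frame[f"{t}_ebv"] = Y[:, j]
        frame[f"{t}_acc"] = acc[:, j]
    return TraitTable(frame)


def assign_subpopulations(truth: TruthSet, n_subpops: int, offsets,
                          seed: int) -> TruthSet:
    """Label samples with subpopulations (round-robin after a seeded shuffle)."""
    rng = np.random.default_rng(seed)
    order = list(truth.samples)
    rng.shuffle(order)
    labels = {s: f"P{(i % n_subpops) + 1}" for i, s in enumerate(order)}
    truth.subpopulations = labels
    truth.subpop_offsets = {f"P{i + 1}": float(offsets[i])
                            for i in range(n_subpops)}
    return truth


def generate_genotype_matrix(n_samples: int, n_events: int, seed: int,
                             variant_freq_range=(0.05, 0.5),
                             gain_fraction: float = 0.3,
                             subpop_labels=None,
                             subpop_freq_shift: float = 0.0) -> pd.DataFrame:
    """Direct dose-matrix generator for association benchmarks.

    Each event gets a variant frequency uniform in ``variant_freq_range``;
    carriers are loss with probability 1 - gain_fraction, else gain.  With
    subpopulation labels, each event's frequency is shifted by
    +-subpop_freq_shift/2 between the two labels (random sign per event),
    planting stratification for PCs to correct.
    """
    rng = np.random.default_rng(seed)
    samples = [f"S{i + 1:04d}" for i in range(n_samples)]
    lo, hi = variant_freq_range
    base = rng.uniform(lo, hi, n_events)
    if subpop_labels is not None:
        labels = np.asarray(subpop_labels)
        uniq = np.unique(labels)
        if len(uniq) != 2:
            raise ValueError("subpop_labels must contain exactly 2 labels")
        sign = rng.choice([-1.0, 1.0], n_events)
        freq = np.where((labels[:, None] == uniq[0]),
                        base + sign * subpop_freq_shift / 2,
                        base - sign * subpop_freq_shift / 2)
        freq = np.clip(freq, 0.01, 0.99)
    else:
        freq = np.broadcast_to(base, (n_samples, n_events))
    carrier = rng.random((n_samples, n_events)) < freq
    gain = rng.random((n_samples, n_events)) < gain_fraction
    dose = np.ones((n_samples, n_events), dtype=np.int8)
    dose[carrier & ~gain] = 0
    dose[carrier & gain] = 2
    return pd.DataFrame(dose, index=pd.Index(samples, name="sample_id"),
                        columns=[f"cnv{j}" for j in range(n_events)])


# ---------------------------------------------------------------------------
# Annotation tracks

def generate_annotations(marker_map: pd.DataFrame, n_genes: int, n_qtls: int,
                         qtl_span_range_bp, seed: int):
    """Random gene and QTL tracks over the map's chromosome extents.

    Genes get a strand, transcript span and 1-8 disjoint exons; QTL spans
    are uniform in ``qtl_span_range_bp`` (a range reaching past 30 Mb
    exercises the downstream confidence-interval filter).
    """
    if n_genes < 0 or n_qtls < 0:
        raise ValueError("track sizes must be non-negative")
    rng = np.random.default_rng(seed)
    extents = {str(c): (int(g["position"].min()), int(g["position"].max()))
               for c, g in marker_map.groupby("chromosome")}
    chroms = sorted(extents)

    genes = []
    for i in range(n_genes):
        chrom = chroms[int(rng.integers(len(chroms)))]
        lo, hi = extents[chrom]
        span = int(rng.integers(5_000, 60_000))
        span = min(span, max(2000, hi - lo))
        tx_start = int(rng.integers(lo, max(lo + 1, hi - span)))
        tx_end = tx_start + span - 1
        n_ex = int(rng.integers(1, 9))
        cuts = np.sort(rng.choice(np.arange(span), size=2 * n_ex, replace=False))
        exons = [(tx_start + int(cuts[2 * e]), tx_start + int(cuts[2 * e + 1]))
                 for e in range(n_ex)]
        genes.append(GeneRecord(
            symbol=f"GENE{i + 1}", chromosome=chrom,
            strand="+" if rng.random() < 0.5 else "-",
            tx_start=tx_start, tx_end=tx_end, exons=exons))

    phenotypes = ["Intramuscular fat", "Calf size", "Gestation length",
                  "Iron content", "Clinical mastitis"]
    qtls = []
    lo_span, hi_span = qtl_span_range_bp
    for i in range(n_qtls):
        chrom = chroms[int(rng.integers(len(chroms)))]
        clo, chi = extents[chrom]
        span = int(rng.integers(lo_span, hi_span + 1))
        start = int(rng.integers(clo, max(clo + 1, chi)))
        qtls.append(QtlRecord(
            qtl_id=f"QTL{i + 1}",
            phenotype=phenotypes[int(rng.integers(len(phenotypes)))],
            chromosome=chrom, ci_start=start, ci_end=start + span - 1))
    return genes, qtls


# ---------------------------------------------------------------------------
# qPCR fixtures

def generate_qpcr_fixture(truth: TruthSet, n_samples: int = 9,
                          ct_noise_sd: float = 0.2, seed: int = 0,
                          n_targets: int = 5, n_replicates: int = 3):
    """Triplicate DNA qPCR CT fixture for the first ``n_targets`` planted CNVs.

    Expected CT follows base_CT(target) - log2(copies/2) with Gaussian
    replicate noise; a dedicated 2-copy reference sample 'REF' and a
    single-copy-state DNA control gene are included.  Returns
    (CtTable, copy-number table, true state table).
    """
    from .qpcr import CtTable  # local import to avoid cycles

    if n_samples > len(truth.samples):
        raise ValueError("n_samples exceeds cohort size")
    if not truth.planted:
        raise ValueError("truth set has no planted events")
    rng = np.random.default_rng(seed)
    targets = [f"tgt{i + 1}" for i in range(min(n_targets, len(truth.planted)))]
    chosen = list(rng.choice(truth.samples, size=n_samples, replace=False))

    geno = truth.genotypes()
    copies = pd.DataFrame(index=pd.Index(chosen + ["REF"], name="sample_id"),
                          columns=targets, dtype=int)
    for j, t in enumerate(targets):
        dose = geno[f"cnv{j}"]
        for s in chosen:
            d = int(dose.loc[s])
            copies.loc[s, t] = {0: 1, 1: 2, 2: 3}[d]
        copies.loc["REF", t] = 2

    base_ct = {t: float(rng.uniform(22, 30)) for t in targets}
    control_ct = 20.0
    rows = []
    for s in list(copies.index):
        for t in targets:
            expected = base_ct[t] - np.log2(copies.loc[s, t] / 2.0)
            for r in range(n_replicates):
                rows.append((s, t, "dna", r + 1,
                             expected + rng.normal(0, ct_noise_sd)))
        for r in range(n_replicates):
            rows.append((s, "BTF3", "dna", r + 1,
                         control_ct + rng.normal(0, ct_noise_sd)))
    frame = pd.DataFrame(rows, columns=["sample_id", "target_id",
                                        "assay_type", "replicate", "ct"])
    states = copies.map(lambda c: "loss" if c < 2 else
                        ("neutral" if c == 2 else "gain"))
    table = CtTable(frame=frame, reference_sample="REF",
                    controls={"dna": "BTF3"})
    return table, copies, states
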