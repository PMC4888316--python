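"""Reference benchmarks: seeded, self-contained simulation studies that
measure the pipeline's operating characteristics.

Each function generates its own synthetic data (via :mod:`cnvgwas.synthio`),
runs the relevant stage, and returns summary numbers:

* breakpoint recall/precision of the joint segmentation on a planted event;
* type-I error calibration of the permutation association under the null;
* recovery of a planted additive effect;
* null inflation under two-subpopulation confounding, with and without
  principal-component correction;
* concordance of qPCR copy calls with planted states under CT noise.

Problem sizes are chosen so a full run takes minutes on one CPU.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import synthio
from .assoc import CnvGwas, compute_pcs
from .intensity import IntensityMatrix
from .qpcr import concordance, copy_call_from_rq, ddct
from .segmentation import SegmentationParams, segment_multivariate


def _flat_map(n_markers: int, spacing_bp: int = 5_000) -> pd.DataFrame:
    pos = np.arange(1, n_markers + 1) * spacing_bp
    return pd.DataFrame({
        "marker_id": [f"M1_{i:06d}" for i in range(1, n_markers + 1)],
        "chromosome": "1", "position": pos, "gc_fraction": 0.5,
    })


def segmentation_recovery(seeds, n_samples: int = 50, n_markers: int = 200,
                          first: int = 50, last: int = 59, shift: float = -1.0,
                          carrier_fraction: float = 0.3,
                          noise_sd: float = 0.15, tol: int = 1) -> dict:
    """Breakpoint recall and precision over seeded replicates.

    One loss of ``last - first + 1`` markers is planted on a flat-GC
    chromosome; a breakpoint is recovered when a segment boundary falls
    within ``tol`` markers of the truth.
    """
    mm = _flat_map(n_markers)
    pos = mm["position"].to_numpy()
    truth_breaks = (first, last + 1)
    n_true = n_found = n_matched_true = n_matched_found = 0
    for seed in seeds:
        cnv = synthio.PlantedCnv("1", int(pos[first]), int(pos[last]),
                                 "loss" if shift < 0 else "gain",
                                 carrier_fraction, shift)
        m, _ = synthio.generate_lrr(mm, n_samples, [cnv], noise_sd=noise_sd,
                                    gc_wave_amplitude=0.0, seed=seed)
        m.corrected = True  # constant GC: nothing to remove
        segs = segment_multivariate(m, SegmentationParams())
        found = sorted(s.first_marker_index for s in segs
                       if s.first_marker_index != 0)
        n_true += len(truth_breaks)
        n_found += len(found)
        n_matched_true += sum(any(abs(b - t) <= tol for b in found)
                              for t in truth_breaks)
        n_matched_found += sum(any(abs(b - t) <= tol for t in truth_breaks)
                               for b in found)
    return {
        "recall": n_matched_true / n_true if n_true else float("nan"),
        "precision": n_matched_found / n_found if n_found else 1.0,
        "n_true_breakpoints": n_true,
        "n_found_breakpoints": n_found,
    }


def null_calibration(seed: int, n_samples: int = 500, n_events: int = 200,
                     n_permutations: int = 2000, alpha: float = 0.05) -> dict:
    """Raw permutation-p rejection rate when the trait has no CNV effects."""
    G = synthio.generate_genotype_matrix(n_samples, n_events, seed=seed)
    rng = np.random.default_rng(seed + 1)
    y = pd.Series(rng.normal(0, 1, n_samples), index=G.index)
    res = CnvGwas(G, y).fit(n_permutations=n_permutations, seed=seed + 2)
    p = res.frame["p_perm"].dropna()
    return {
        "rejection_rate": float((p < alpha).mean()),
        "n_events": int(len(p)),
    }


def planted_effect_recovery(seed: int, beta: float = 0.8,
                            carrier_fraction: float = 0.3,
                            n_samples: int = 500, n_events: int = 50,
                            n_permutations: int = 2000,
                            alpha: float = 0.05) -> dict:
    """Fit one trait with a single planted additive effect; report its record."""
    G = synthio.generate_genotype_matrix(
        n_samples, n_events, seed=seed,
        variant_freq_range=(carrier_fraction, carrier_fraction),
        gain_fraction=0.0)
    rng = np.random.default_rng(seed + 1)
    y = pd.Series(rng.normal(0, 1, n_samples)
                  + beta * G["cnv0"].to_numpy(float), index=G.index)
    res = CnvGwas(G, y).fit(n_permutations=n_permutations, seed=seed + 2,
                            alpha=alpha)
    rec = res.record("cnv0")
    return {
        "beta_hat": float(rec["beta_hat"]),
        "q_fdr": float(rec["q_fdr"]),
        "significant": bool(rec["significant"]),
    }


def stratification_comparison(seeds, n_samples: int = 500,
                              n_events: int = 200, offset: float = 1.0,
                              freq_shift: float = 0.3, k_pcs: int = 10,
                              n_permutations: int = 1000,
                              alpha: float = 0.05) -> dict:
    """Null rejection rates under two-subpopulation confounding.

    The trait is pure subpopulation offset plus noise; event frequencies
    differ between the subpopulations, so uncorrected tests are inflated
    while PC-corrected tests should return to the nominal level.
    """
    rates_without, rates_with = [], []
    for seed in seeds:
        labels = np.array(["A"] * (n_samples // 2)
                          + ["B"] * (n_samples - n_samples // 2))
        G = synthio.generate_genotype_matrix(
            n_samples, n_events, seed=seed, variant_freq_range=(0.1, 0.4),
            subpop_labels=labels, subpop_freq_shift=freq_shift)
        rng = np.random.default_rng(seed + 1)
        y = pd.Series(offset * (labels == "B") + rng.normal(0, 1, n_samples),
                      index=G.index)
        res0 = CnvGwas(G, y).fit(n_permutations=n_permutations, seed=seed + 2)
        rates_without.append(float((res0.frame["p_perm"].dropna() < alpha).mean()))
        pcs = compute_pcs(G, k_pcs)
        res1 = CnvGwas(G, y, pcs).fit(n_permutations=n_permutations,
                                      seed=seed + 2)
        rates_with.append(float((res1.frame["p_perm"].dropna() < alpha).mean()))
    return {
        "rate_without_pcs": float(np.mean(rates_without)),
        "rate_with_pcs": float(np.mean(rates_with)),
        "per_seed_without": rates_without,
        "per_seed_with": rates_with,
    }


def qpcr_concordance(seeds, ct_noise_sd: float = 0.2, n_samples: int = 9,
                     n_targets: int = 5) -> dict:
    """Mean agreement of qPCR copy calls with planted array states."""
    mm = _flat_map(300)
    pos = mm["position"].to_numpy()
    planted = [synthio.PlantedCnv("1", int(pos[i * 30]), int(pos[i * 30 + 5]),
                                  "loss" if i % 2 else "gain", 0.5,
                                  -0.55 if i % 2 else 0.4)
               for i in range(n_targets)]
    values = []
    for seed in seeds:
        _, truth = synthio.generate_lrr(mm, 30, planted, noise_sd=0.1,
                                        gc_wave_amplitude=0.0, seed=seed)
        table, _, states = synthio.generate_qpcr_fixture(
            truth, n_samples=n_samples, ct_noise_sd=ct_noise_sd,
            seed=seed + 10_000, n_targets=n_targets)
        array = {(s, t): states.loc[s, t]
                 for s in states.index for t in states.columns if s != "REF"}
        qcalls = {(s, t): copy_call_from_rq(ddct(table, t, s))
                  for (s, t) in array}
        values.append(concordance(array, qcalls))
    return {"mean_concordance": float(np.mean(values)),
            "n_seeds": len(values)}
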