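"""2^-ddCT relative quantification for CNV validation.

CT is the qPCR cycle at which a target's amplification crosses threshold;
one cycle corresponds to a factor of two in starting template.  For a
target and sample, dCT = mean CT(target) - mean CT(control gene); ddCT
subtracts the reference sample's dCT, and the relative quantity is
RQ = 2^-ddCT.  A diploid locus has RQ 1; a one-copy loss 0.5; a
three-copy gain 1.5.  Amplification efficiency is taken as a perfect
doubling (the plain Livak method); replicate CTs are averaged before any
delta is formed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ["sample_id", "target_id", "assay_type", "replicate", "ct"]


@dataclass
class CtTable:
    """Long table of CT values plus the reference sample and control targets.

    ``controls`` maps assay type ('dna' or 'rna') to the control target id
    (e.g. a single-copy DNA control gene and an RNA housekeeping gene).
    """

    frame: pd.DataFrame
    reference_sample: str
    controls: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in CT_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"CT table missing columns: {missing}")
        ct = self.frame["ct"].to_numpy(float)
        if np.any(~np.isfinite(ct)) or np.any(ct <= 0):
            raise ValueError("CT values must be finite and positive")
        if self.reference_sample not in set(self.frame["sample_id"]):
            raise ValueError(f"reference sample {self.reference_sample!r} "
                             "has no CT rows")

    def mean_ct(self, sample: str, target: str) -> float:
        sub = self.frame[(self.frame["sample_id"] == sample)
                         & (self.frame["target_id"] == target)]
        if sub.empty:
            raise KeyError(f"no CT rows for sample {sample!r}, target {target!r}")
        return float(sub["ct"].mean())

    def assay_type_of(self, target: str) -> str:
        sub = self.frame[self.frame["target_id"] == target]
        if sub.empty:
            raise KeyError(f"unknown target {target!r}")
        return str(sub["assay_type"].iloc[0])

    def samples(self) -> list[str]:
        return sorted(set(self.frame["sample_id"]))

    def targets(self, assay_type: str | None = None) -> list[str]:
        sub = self.frame
        if assay_type is not None:
            sub = sub[sub["assay_type"] == assay_type]
        return sorted(set(sub["target_id"]) - set(self.controls.values()))

    @classmethod
    def read(cls, path, reference_sample: str, controls: dict) -> "CtTable":
        return cls(pd.read_csv(path, sep="\t",
                               dtype={"sample_id": str, "target_id": str}),
                   reference_sample, dict(controls))

    def write(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def ddct(ct: CtTable, target: str, sample: str) -> float:
    """Relative quantity 2^-ddCT of ``target`` in ``sample`` vs the reference."""
    assay = ct.assay_type_of(target)
    control = ct.controls.get(assay)
    if control is None:
        raise ValueError(f"no control target configured for assay {assay!r}")
    for s in (sample, ct.reference_sample):
        try:
            ct.mean_ct(s, control)
        except KeyError:
            raise ValueError(f"sample {s!r} lacks control-gene ({control!r}) CTs")
    d_sample = ct.mean_ct(sample, target) - ct.mean_ct(sample, control)
    d_ref = ct.mean_ct(ct.reference_sample, target) - ct.mean_ct(
        ct.reference_sample, control)
    return float(2.0 ** -(d_sample - d_ref))


def copy_call_from_rq(rq: float, reference_copies: int = 2) -> int:
    """Integer copy number from a relative quantity (half-up rounding)."""
    if rq <= 0:
        raise ValueError("relative quantity must be positive")
    return max(0, math.floor(rq * reference_copies + 0.5))


def rq_table(ct: CtTable, targets=None, samples=None) -> pd.DataFrame:
    """RQ and copy call for every (sample, target) pair."""
    targets = targets if targets is not None else ct.targets()
    samples = samples if samples is not None else ct.samples()
    rows = []
    for t in targets:
        for s in samples:
            rq = ddct(ct, t, s)
            rows.append((s, t, rq, copy_call_from_rq(rq)))
    return pd.DataFrame(rows, columns=["sample_id", "target_id", "rq", "copies"])


def _normalize_call(value) -> str:
    """Map an integer copy count (or state label) to loss/neutral/gain."""
    if isinstance(value, str):
        if value not in ("loss", "neutral", "gain"):
            raise ValueError(f"unknown state label {value!r}")
        return value
    copies = int(value)
    if copies < 2:
        return "loss"
    if copies == 2:
        return "neutral"
    return "gain"


def concordance(calls_a: Mapping, calls_b: Mapping) -> float:
    """Fraction of (sample, event) keys on which two call sets agree.

    Each mapping's values may be state labels or integer copy numbers
    (< 2 -> loss, 2 -> neutral, > 2 -> gain); the measure is symmetric.
    """
    keys_a, keys_b = set(calls_a), set(calls_b)
    if keys_a != keys_b:
        missing = sorted(keys_a ^ keys_b)
        raise ValueError(f"call sets cover different pairs: {missing[:10]}")
    if not keys_a:
        raise ValueError("empty call sets")
    agree = sum(_normalize_call(calls_a[k]) == _normalize_call(calls_b[k])
                for k in keys_a)
    return agree / len(keys_a)


def anova_copy_groups(groups) -> tuple[float, float]:
    """One-way fixed-effects ANOVA across copy-number groups.

    ``groups`` is a mapping or sequence of per-group value arrays (e.g.
    expression RQs of 2-copy vs 3-copy animals).  Returns (F, p).
    """
    if isinstance(groups, Mapping):
        arrays = [np.asarray(v, float) for v in groups.values()]
    else:
        arrays = [np.asarray(v, float) for v in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    n_total = sum(len(a) for a in arrays)
    df_error = n_total - len(arrays)
    if df_error < 2:
        raise ValueError("need at least 2 error degrees of freedom")
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)
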