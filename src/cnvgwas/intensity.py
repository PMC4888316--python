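"""Log R Ratio matrices and their preprocessing.

The Log R Ratio (LRR) of a SNP probe is the log2 ratio of observed to
expected total intensity; deletions pull it down, duplications push it up.
This module reads marker maps and sample-by-marker LRR matrices, restricts
them to autosomes, imputes missing entries, and removes GC-content
"waviness" — the long-range intensity artifact correlated with regional GC
fraction — by a per-sample linear regression of LRR on marker GC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MAP_COLUMNS = ["marker_id", "chromosome", "position", "gc_fraction"]


def chromosome_sort_key(chrom: str):
    """Natural ordering: numeric chromosome labels first, then lexicographic."""
    try:
        return (0, int(chrom), "")
    except (TypeError, ValueError):
        return (1, 0, str(chrom))


def validate_marker_map(marker_map: pd.DataFrame) -> None:
    missing = [c for c in MAP_COLUMNS if c not in marker_map.columns]
    if missing:
        raise ValueError(f"marker map is missing columns: {missing}")
    dup = marker_map["marker_id"][marker_map["marker_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate marker ids: {sorted(dup.unique())[:10]}")
    gc = marker_map["gc_fraction"].to_numpy(float)
    if np.any((gc < 0) | (gc > 1)):
        raise ValueError("gc_fraction outside [0, 1]")
    for chrom, sub in marker_map.groupby("chromosome", sort=False):
        pos = sub["position"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError(
                f"positions not strictly increasing on chromosome {chrom}"
            )


def read_marker_map(path) -> pd.DataFrame:
    mm = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chromosome": str})
    validate_marker_map(mm)
    return mm.reset_index(drop=True)


def write_marker_map(marker_map: pd.DataFrame, path) -> None:
    marker_map.to_csv(path, sep="\t", index=False)


@dataclass
class IntensityMatrix:
    """Samples x markers LRR matrix together with its marker map.

    ``lrr`` rows follow ``samples``, columns follow the row order of
    ``marker_map`` (sorted by chromosome then position).  Missing entries
    are NaN until :func:`impute_missing` is applied.
    """

    samples: list[str]
    marker_map: pd.DataFrame
    lrr: np.ndarray
    corrected: bool = False

    def __post_init__(self):
        self.lrr = np.asarray(self.lrr, dtype=float)
        if self.lrr.shape != (len(self.samples), len(self.marker_map)):
            raise ValueError(
                f"LRR shape {self.lrr.shape} does not match "
                f"{len(self.samples)} samples x {len(self.marker_map)} markers"
            )
        if len(set(self.samples)) != len(self.samples):
            seen: set[str] = set()
            dups = [s for s in self.samples if s in seen or seen.add(s)]
            raise ValueError(f"duplicate sample ids: {dups}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.marker_map)

    def sample_index(self, sample_id: str) -> int:
        return self.samples.index(sample_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.lrr, index=pd.Index(self.samples, name="sample_id"),
            columns=self.marker_map["marker_id"].tolist(),
        )


def read_lrr_matrix(path, marker_map: pd.DataFrame, dialect: str = "matrix") -> IntensityMatrix:
    """Read an LRR matrix in one of two TSV dialects.

    ``matrix``: first column sample_id, header row of marker ids.
    ``long``: columns sample_id, marker_id, lrr (final-report style, pivoted).
    Markers absent from the map are an error; the matrix is reordered to the
    map's marker order, and map markers without a column raise as well.
    """
    if dialect not in ("matrix", "long"):
        raise ValueError(f"unknown dialect {dialect!r}; use 'matrix' or 'long'")
    try:
        if dialect == "matrix":
            df = pd.read_csv(path, sep="\t", index_col=0,
                             float_precision="round_trip")
            df.index = df.index.astype(str)
        else:
            longdf = pd.read_csv(
                path, sep="\t", dtype={"sample_id": str, "marker_id": str},
                float_precision="round_trip",
            )
            need = {"sample_id", "marker_id", "lrr"}
            if not need.issubset(longdf.columns):
                raise ValueError(
                    f"long dialect needs columns {sorted(need)}, "
                    f"got {list(longdf.columns)}"
                )
            dup = longdf.duplicated(["sample_id", "marker_id"])
            if dup.any():
                offenders = longdf.loc[dup, ["sample_id", "marker_id"]].iloc[:5]
                raise ValueError(
                    f"duplicated (sample, marker) rows, e.g. {offenders.values.tolist()}"
                )
            df = longdf.pivot(index="sample_id", columns="marker_id", values="lrr")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed LRR file {path}: {exc}") from exc

    if df.index.duplicated().any():
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"duplicate sample ids in {path}: {dups}")

    known = set(marker_map["marker_id"])
    unknown = [m for m in df.columns if m not in known]
    if unknown:
        raise ValueError(f"markers not in the map: {unknown[:10]}")
    order = [m for m in marker_map["marker_id"] if m in df.columns]
    if len(order) < len(marker_map):
        missing = set(marker_map["marker_id"]) - set(df.columns)
        raise ValueError(f"map markers missing from matrix: {sorted(missing)[:10]}")
    df = df[order]
    return IntensityMatrix(
        samples=[str(s) for s in df.index],
        marker_map=marker_map.reset_index(drop=True),
        lrr=df.to_numpy(dtype=float),
    )


def write_lrr_matrix(m: IntensityMatrix, path) -> None:
    # shortest-repr floats so read -> write -> read is bit-exact
    m.to_frame().to_csv(path, sep="\t", float_format=lambda v: repr(float(v)))


def restrict_map_to_autosomes(marker_map: pd.DataFrame, allowed_chromosomes):
    """Drop markers outside ``allowed_chromosomes``; report retention."""
    allowed = set(map(str, allowed_chromosomes))
    if not allowed:
        raise ValueError("allowed chromosome set is empty")
    keep = marker_map["chromosome"].astype(str).isin(allowed)
    retained = int(keep.sum())
    total = len(marker_map)
    if retained == 0:
        raise ValueError("no markers retained after autosome restriction")
    report = {
        "total_markers": total,
        "retained_markers": retained,
        "retained_pct": round(100.0 * retained / total, 2),
    }
    log.info(
        "autosome restriction: retained %d of %d markers (%.2f%%)",
        retained, total, report["retained_pct"],
    )
    return marker_map.loc[keep].reset_index(drop=True), report


def restrict_to_autosomes(m: IntensityMatrix, allowed_chromosomes):
    new_map, report = restrict_map_to_autosomes(m.marker_map, allowed_chromosomes)
    keep = m.marker_map["chromosome"].astype(str).isin(set(map(str, allowed_chromosomes)))
    out = IntensityMatrix(
        samples=list(m.samples),
        marker_map=new_map,
        lrr=m.lrr[:, keep.to_numpy()],
        corrected=m.corrected,
    )
    return out, report


def impute_missing(m: IntensityMatrix) -> IntensityMatrix:
    """Mean-impute missing LRR entries per marker (cohort column mean).

    Markers missing in every sample are set to 0 (the LRR baseline).
    """
    lrr = m.lrr.copy()
    mask = ~np.isfinite(lrr)
    n_missing = int(mask.sum())
    if n_missing:
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            col_means = np.nanmean(np.where(mask, np.nan, lrr), axis=0)
        col_means = np.where(np.isfinite(col_means), col_means, 0.0)
        rows, cols = np.nonzero(mask)
        lrr[rows, cols] = col_means[cols]
        log.info("imputed %d missing LRR entries", n_missing)
    return replace(m, lrr=lrr)


def _trimmed_slopes(lrr: np.ndarray, gcc: np.ndarray) -> np.ndarray:
    """Per-sample slope of LRR on centered GC, with one outlier-trimming pass.

    Copy-number events are gross outliers relative to the LRR noise; left in
    the fit they bias the slope whenever they sit in GC-skewed regions, so
    markers beyond 3 robust SDs of the first-pass residuals are dropped and
    the slope refit on the rest.
    """
    denom = float(gcc @ gcc)
    b0 = (lrr @ gcc) / denom
    resid = lrr - np.outer(b0, gcc)
    med = np.median(resid, axis=1, keepdims=True)
    mad = np.median(np.abs(resid - med), axis=1, keepdims=True)
    sigma = 1.4826 * mad
    sigma[sigma == 0] = np.inf  # flat residuals: keep everything
    keep = np.abs(resid - med) <= 3.0 * sigma
    # masked per-sample refit: slope of lrr on gc over the kept markers
    w = keep.astype(float)
    n_keep = w.sum(axis=1, keepdims=True)
    gc_mean = (w * gcc).sum(axis=1, keepdims=True) / n_keep
    y_mean = (w * lrr).sum(axis=1, keepdims=True) / n_keep
    gdev = (gcc[None, :] - gc_mean) * w
    num = (gdev * (lrr - y_mean)).sum(axis=1)
    den = (gdev ** 2).sum(axis=1)
    b1 = np.where(den > 0, num / np.where(den > 0, den, 1.0), b0)
    return b1


def gc_correct(m: IntensityMatrix, force: bool = False) -> IntensityMatrix:
    """Remove GC waviness by per-sample regression of LRR on marker GC.

    For each sample the slope b of LRR ~ gc is estimated (OLS with one
    outlier-trimming pass, so copy-number shifts do not contaminate it) and
    b * (gc - mean(gc)) is subtracted, which removes the GC-linear
    component while preserving the sample's mean LRR exactly.  With
    constant GC the slope is undefined and the correction is a logged
    no-op.
    """
    if m.corrected and not force:
        raise ValueError("matrix is already GC-corrected")
    gc = m.marker_map["gc_fraction"].to_numpy(float)
    gcc = gc - gc.mean()
    denom = float(gcc @ gcc)
    if denom == 0.0:
        log.warning("constant gc_fraction: GC correction is a no-op")
        return replace(m, lrr=m.lrr.copy(), corrected=True)

    lrr = m.lrr
    if np.isfinite(lrr).all():
        slopes = _trimmed_slopes(lrr, gcc)
        corrected = lrr - np.outer(slopes, gcc)
    else:
        corrected = lrr.copy()
        for i in range(m.n_samples):
            row = lrr[i]
            ok = np.isfinite(row)
            g = gc[ok] - gc[ok].mean()
            if float(g @ g) == 0.0:
                continue
            b = float(_trimmed_slopes(row[ok][None, :], g)[0])
            corrected[i, ok] = row[ok] - b * g
    return replace(m, lrr=corrected, corrected=True)
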