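"""Joint copy-number segmentation of a cohort LRR matrix.

The vendor "multivariate" segmentation used on SNP-array cohorts is
proprietary; this module implements greedy recursive binary splitting on
the pooled (all-samples) within-segment sum of squares, honoring the three
published constraints: a segment-count budget per 10k markers, a minimum
marker count per segment, and a maximum pairwise p-value between the two
segments flanking a candidate breakpoint.  The pairwise test is a paired
t-test across samples on the difference of each sample's two flanking
segment means — pairing is what keeps rare events detectable, since
carriers inflate the across-sample variance of the segment means
themselves.  Per-sample three-state calls
(loss / neutral / gain) are then assigned from segment means with an
inclusive +-threshold rule.

Splitting proceeds per chromosome.  Each active segment contributes its
best candidate breakpoint (largest pooled SSE reduction; ties go to the
leftmost) to a priority queue; candidates are accepted in order of gain,
subject to the minimum-marker, Welch-test and budget constraints.  A
rejected candidate finalizes its segment.
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .intensity import IntensityMatrix, chromosome_sort_key

log = logging.getLogger(__name__)

LOSS, NEUTRAL, GAIN = -1, 0, 1
STATE_NAMES = {LOSS: "loss", NEUTRAL: "neutral", GAIN: "gain"}


@dataclass(frozen=True)
class SegmentationParams:
    """Published thresholds of the multivariate segmentation.

    max_segments_per_10k_markers: density cap on emitted segments.
    min_markers: minimum markers per segment.
    max_pairwise_p: paired-test p-value a breakpoint's flanking segments
        must beat to be accepted.
    state_threshold: |segment mean| at or beyond which a sample is called
        loss/gain rather than neutral.
    """

    max_segments_per_10k_markers: int = 20
    min_markers: int = 3
    max_pairwise_p: float = 0.005
    state_threshold: float = 0.4

    def __post_init__(self):
        if self.max_segments_per_10k_markers <= 0 or self.min_markers <= 0:
            raise ValueError("segment counts must be positive")
        if not (0.0 < self.max_pairwise_p < 1.0):
            raise ValueError("max_pairwise_p must be in (0, 1)")
        if self.state_threshold <= 0:
            raise ValueError("state_threshold must be positive")


@dataclass
class Segment:
    chromosome: str
    first_marker_index: int  # index into the chromosome's marker order
    last_marker_index: int
    start_bp: int
    end_bp: int
    per_sample_mean: np.ndarray  # mean corrected LRR per sample

    @property
    def n_markers(self) -> int:
        return self.last_marker_index - self.first_marker_index + 1


def segment_budget(n_markers: int, per_10k: int) -> int:
    """Segment cap for a chromosome: ``per_10k`` per started 10k-marker window."""
    return per_10k * math.ceil(n_markers / 10000)


def _best_split(S1, S2, lo, hi, min_markers):
    """Best single breakpoint of [lo, hi] by pooled SSE reduction.

    Returns (gain, split_b) where the left child is [lo, b] — or None if no
    candidate leaves both children with >= min_markers markers.  S1/S2 are
    per-sample cumulative sums (with a leading zero column) of the LRR and
    its square along the chromosome.
    """
    first_b = lo + min_markers - 1
    last_b = hi - min_markers
    if first_b > last_b:
        return None
    bs = np.arange(first_b, last_b + 1)
    n1 = (bs - lo + 1).astype(float)
    n2 = (hi - bs).astype(float)
    sum_left = S1[:, bs + 1] - S1[:, lo:lo + 1]
    sum_tot = (S1[:, hi + 1] - S1[:, lo])[:, None]
    sum_right = sum_tot - sum_left
    gain = (sum_left ** 2 / n1 + sum_right ** 2 / n2
            - sum_tot ** 2 / (n1 + n2)).sum(axis=0)
    k = int(np.argmax(gain))  # argmax takes the first max: leftmost tie-break
    return float(gain[k]), int(bs[k])


def _segment_chromosome(X: np.ndarray, params: SegmentationParams):
    """Greedy recursive binary splitting of one chromosome.

    X is samples x markers.  Returns a sorted list of (lo, hi) marker-index
    ranges partitioning the chromosome.
    """
    n_samples, m = X.shape
    if m < params.min_markers:
        log.warning("chromosome with %d < %d markers kept as one segment",
                    m, params.min_markers)
        return [(0, m - 1)]
    budget = segment_budget(m, params.max_segments_per_10k_markers)
    zero = np.zeros((n_samples, 1))
    S1 = np.concatenate([zero, np.cumsum(X, axis=1)], axis=1)
    S2 = np.concatenate([zero, np.cumsum(X ** 2, axis=1)], axis=1)

    segments = {(0, m - 1)}
    heap = []
    cand = _best_split(S1, S2, 0, m - 1, params.min_markers)
    if cand is not None:
        heapq.heappush(heap, (-cand[0], 0, m - 1, cand[1]))

    while heap and len(segments) < budget:
        neg_gain, lo, hi, b = heapq.heappop(heap)
        if (lo, hi) not in segments:
            continue  # stale (cannot happen with one candidate per segment)
        n1 = b - lo + 1
        n2 = hi - b
        left_means = (S1[:, b + 1] - S1[:, lo]) / n1
        right_means = (S1[:, hi + 1] - S1[:, b + 1]) / n2
        with np.errstate(divide="ignore", invalid="ignore"):
            t, p = stats.ttest_1samp(left_means - right_means, 0.0)
        if not np.isfinite(p) or p > params.max_pairwise_p:
            continue  # candidate rejected: the segment is final
        segments.remove((lo, hi))
        for child in ((lo, b), (b + 1, hi)):
            segments.add(child)
            c = _best_split(S1, S2, child[0], child[1], params.min_markers)
            if c is not None:
                heapq.heappush(heap, (-c[0], child[0], child[1], c[1]))
    return sorted(segments)


def segment_multivariate(m: IntensityMatrix, params: SegmentationParams | None = None):
    """Segment every chromosome of a GC-corrected LRR matrix.

    Returns segments in (chromosome, position) order; on every chromosome
    the marker ranges are contiguous, disjoint and exhaustive.
    """
    params = params or SegmentationParams()
    if not m.corrected:
        raise ValueError("segment a GC-corrected matrix (run gc_correct first)")
    if not np.isfinite(m.lrr).all():
        raise ValueError("LRR contains missing values; impute before segmenting")

    chroms = sorted(m.marker_map["chromosome"].unique(), key=chromosome_sort_key)
    out: list[Segment] = []
    chrom_col = m.marker_map["chromosome"].to_numpy()
    pos_col = m.marker_map["position"].to_numpy()
    for chrom in chroms:
        cols = np.flatnonzero(chrom_col == chrom)
        X = m.lrr[:, cols]
        pos = pos_col[cols]
        for lo, hi in _segment_chromosome(X, params):
            out.append(Segment(
                chromosome=str(chrom),
                first_marker_index=lo,
                last_marker_index=hi,
                start_bp=int(pos[lo]),
                end_bp=int(pos[hi]),
                per_sample_mean=X[:, lo:hi + 1].mean(axis=1),
            ))
    log.info("segmented %d markers on %d chromosomes into %d segments",
             m.n_markers, len(chroms), len(out))
    return out


@dataclass
class StateCalls:
    """Per-sample three-state calls for every segment.

    ``states`` is samples x segments with values -1 (loss), 0 (neutral),
    +1 (gain); ``means`` holds the corresponding per-sample segment means.
    """

    samples: list[str]
    segments: list[Segment]
    states: np.ndarray
    means: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j, seg in enumerate(self.segments):
            for i, s in enumerate(self.samples):
                rows.append((s, seg.chromosome, seg.start_bp, seg.end_bp,
                             seg.first_marker_index, seg.last_marker_index,
                             STATE_NAMES[int(self.states[i, j])],
                             float(self.means[i, j])))
        return pd.DataFrame(rows, columns=[
            "sample_id", "chromosome", "start_bp", "end_bp",
            "first_marker_index", "last_marker_index", "state", "mean_lrr"])


def call_states(segments: list[Segment], m: IntensityMatrix,
                threshold: float = 0.4) -> StateCalls:
    """Call loss/neutral/gain per (sample, segment) by the inclusive rule:

    mean <= -threshold -> loss; mean >= +threshold -> gain; else neutral.
    """
    means = np.column_stack([seg.per_sample_mean for seg in segments]) \
        if segments else np.empty((m.n_samples, 0))
    states = np.zeros(means.shape, dtype=np.int8)
    states[means <= -threshold] = LOSS
    states[means >= threshold] = GAIN
    return StateCalls(samples=list(m.samples), segments=list(segments),
                      states=states, means=means)


def segments_to_frame(segments: list[Segment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.chromosome, s.start_bp, s.end_bp, s.n_markers) for s in segments],
        columns=["chromosome", "start_bp", "end_bp", "n_markers"])
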