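"""Independent brute-force oracles used only by the test suite.

These deliberately use the slowest, most literal formulation of each
operation (exhaustive search, per-basepair set membership) so they stay
independent of the implementations they check.
"""

import itertools

import numpy as np


def pooled_sse(X, lo, hi):
    """Within-segment sum of squares over all samples for markers [lo, hi]."""
    block = X[:, lo:hi + 1]
    means = block.mean(axis=1, keepdims=True)
    return float(((block - means) ** 2).sum())


def exhaustive_best_partition(X, min_markers, max_breaks=2):
    """Minimum total pooled SSE over all partitions with <= max_breaks breaks.

    Breakpoint b means the left segment ends at marker b.  Returns
    (best_sse, best_breaks).
    """
    m = X.shape[1]
    best = (pooled_sse(X, 0, m - 1), ())
    candidates = range(min_markers - 1, m - min_markers)
    for k in range(1, max_breaks + 1):
        for breaks in itertools.combinations(candidates, k):
            bounds = [-1, *breaks, m - 1]
            if any(bounds[i + 1] - bounds[i] < min_markers
                   for i in range(len(bounds) - 1)):
                continue
            sse = sum(pooled_sse(X, bounds[i] + 1, bounds[i + 1])
                      for i in range(len(bounds) - 1))
            if sse < best[0]:
                best = (sse, breaks)
    return best


def interval_union(intervals):
    """Brute-force union of 1-based inclusive intervals via a basepair set."""
    points = set()
    for s, e in intervals:
        points.update(range(s, e + 1))
    if not points:
        return []
    merged = []
    run_start = prev = None
    for p in sorted(points):
        if run_start is None:
            run_start = prev = p
        elif p == prev + 1:
            prev = p
        else:
            merged.append((run_start, prev))
            run_start = prev = p
    merged.append((run_start, prev))
    return merged


def bp_overlap(a, b):
    """Per-basepair overlap of two 1-based inclusive intervals."""
    return len(set(range(a[0], a[1] + 1)) & set(range(b[0], b[1] + 1)))


def bp_gene_geometry(event, gene):
    """Per-basepair geometry classification mirroring the overlap rules."""
    ev = set(range(event[0], event[1] + 1))
    body = set(range(gene.tx_start, gene.tx_end + 1))
    if not (ev & body):
        return None
    exonic = set()
    for s, e in gene.exons:
        exonic.update(range(s, e + 1))
    if body <= ev:
        return "gene-within-cnv"
    if ev & exonic:
        return "exon-overlap"
    if ev <= body:
        return "intron-contained"
    return "partial"


def bh_reference(p):
    """Textbook BH step-up, computed by the literal min-over-j definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        q[idx] = min(
            min(p[order[j - 1]] * m / j for j in range(rank_pos, m + 1)), 1.0)
    return q
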