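"""Non-redundant CNV events from per-sample segment state calls.

Variant segments (loss or gain in at least one sample) are merged per
chromosome when they overlap or are bookended (adjacent marker ranges),
producing pairwise non-overlapping events with per-sample states and
loss/gain frequencies.  Events are then filtered by a two-step rule —
minimum carrier count first, maximum length second — named CNV1..CNVn by
descending loss frequency, and converted to an additive genotype matrix
(loss=0, neutral=1, gain=2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intensity import chromosome_sort_key
from .segmentation import GAIN, LOSS, NEUTRAL, STATE_NAMES, StateCalls

log = logging.getLogger(__name__)


@dataclass
class CnvEvent:
    chromosome: str
    start_bp: int
    end_bp: int
    samples: list[str]
    states: np.ndarray  # per-sample {-1, 0, +1}
    name: str = ""

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int8)
        if len(self.states) != len(self.samples):
            raise ValueError("states and samples disagree in length")
        if self.end_bp < self.start_bp:
            raise ValueError("end_bp < start_bp")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def loss_freq(self) -> float:
        return float(np.mean(self.states == LOSS))

    @property
    def gain_freq(self) -> float:
        return float(np.mean(self.states == GAIN))

    @property
    def neutral_freq(self) -> float:
        return float(np.mean(self.states == NEUTRAL))

    @property
    def variant_freq(self) -> float:
        return float(np.mean(self.states != NEUTRAL))

    @property
    def carrier_count(self) -> int:
        return int(np.sum(self.states != NEUTRAL))

    def state_of(self, sample_id: str) -> str:
        return STATE_NAMES[int(self.states[self.samples.index(sample_id)])]


def _resolve_mixed_states(states_block: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Collapse a sample's states over constituent segments to one state.

    Most extreme state wins; a sample carrying both loss and gain gets the
    state of the longer total span, ties going to loss.
    """
    n_samples = states_block.shape[0]
    out = np.zeros(n_samples, dtype=np.int8)
    has_loss = (states_block == LOSS).any(axis=1)
    has_gain = (states_block == GAIN).any(axis=1)
    out[has_loss & ~has_gain] = LOSS
    out[~has_loss & has_gain] = GAIN
    mixed = np.flatnonzero(has_loss & has_gain)
    for i in mixed:
        loss_span = int(lengths[states_block[i] == LOSS].sum())
        gain_span = int(lengths[states_block[i] == GAIN].sum())
        out[i] = GAIN if gain_span > loss_span else LOSS
        log.info("sample with both loss and gain in one merged event: "
                 "loss span %d bp vs gain span %d bp -> %s",
                 loss_span, gain_span, STATE_NAMES[int(out[i])])
    return out


def merge_events(calls: StateCalls) -> list[CnvEvent]:
    """Merge variant segments into non-redundant per-chromosome events.

    Segments variant in no sample are dropped.  Variant segments that
    overlap in basepairs or are bookended (consecutive marker ranges) form
    one event spanning their union.
    """
    variant_cols = np.flatnonzero((calls.states != NEUTRAL).any(axis=0))
    by_chrom: dict[str, list[int]] = {}
    for j in variant_cols:
        by_chrom.setdefault(calls.segments[j].chromosome, []).append(int(j))

    events: list[CnvEvent] = []
    for chrom in sorted(by_chrom, key=chromosome_sort_key):
        idx = sorted(by_chrom[chrom],
                     key=lambda j: calls.segments[j].first_marker_index)
        groups: list[list[int]] = [[idx[0]]]
        for j in idx[1:]:
            prev = calls.segments[groups[-1][-1]]
            cur = calls.segments[j]
            bookended = cur.first_marker_index == prev.last_marker_index + 1
            overlapping = cur.start_bp <= prev.end_bp
            if bookended or overlapping:
                groups[-1].append(j)
            else:
                groups.append([j])
        for grp in groups:
            segs = [calls.segments[j] for j in grp]
            block = calls.states[:, grp]
            lengths = np.array([s.end_bp - s.start_bp + 1 for s in segs])
            events.append(CnvEvent(
                chromosome=chrom,
                start_bp=min(s.start_bp for s in segs),
                end_bp=max(s.end_bp for s in segs),
                samples=list(calls.samples),
                states=_resolve_mixed_states(block, lengths),
            ))
    log.info("merged %d variant segments into %d non-redundant events",
             len(variant_cols), len(events))
    return events


def filter_events(events: list[CnvEvent], min_carrier_samples: int = 10,
                  max_length_bp: int = 5_000_000):
    """Two-step filter: carrier count first, then length.

    Step 1 drops events variant in fewer than ``min_carrier_samples``
    samples; step 2 drops events longer than ``max_length_bp``.  Returns
    (retained events, report of counts at each step).
    """
    if min_carrier_samples < 1:
        raise ValueError("min_carrier_samples must be >= 1")
    step1 = [e for e in events if e.carrier_count >= min_carrier_samples]
    step2 = [e for e in step1 if e.length_bp <= max_length_bp]
    report = {
        "input_events": len(events),
        "after_carrier_filter": len(step1),
        "after_length_filter": len(step2),
        "min_carrier_samples": min_carrier_samples,
        "max_length_bp": max_length_bp,
    }
    log.info("event filter: %d -> %d (carriers >= %d) -> %d (length <= %d bp)",
             len(events), len(step1), min_carrier_samples, len(step2),
             max_length_bp)
    return step2, report


def carrier_threshold_frequency_pct(min_carrier_samples: int, n_samples: int) -> float:
    """The carrier-count filter expressed as a cohort percentage."""
    if n_samples <= 0:
        raise ValueError("n_samples must be positive")
    return round(100.0 * min_carrier_samples / n_samples, 2)


def name_by_loss_frequency(events: list[CnvEvent]) -> list[CnvEvent]:
    """Name events CNV1..CNVn by descending loss frequency.

    Ties break by chromosome order then start position.  Returns the events
    in name order.
    """
    ordered = sorted(events, key=lambda e: (
        -e.loss_freq, chromosome_sort_key(e.chromosome), e.start_bp))
    for i, e in enumerate(ordered, start=1):
        e.name = f"CNV{i}"
    return ordered


def build_genotypes(events: list[CnvEvent], samples: list[str] | None = None) -> pd.DataFrame:
    """Additive genotype matrix: loss -> 0, neutral -> 1, gain -> 2."""
    if not events:
        raise ValueError("no events to genotype")
    samples = samples or events[0].samples
    data = {}
    for e in events:
        if e.samples != samples:
            s = pd.Series(e.states, index=e.samples).reindex(samples)
            if s.isna().any():
                missing = s.index[s.isna()].tolist()
                raise ValueError(f"event {e.name or '?'} lacks states for {missing}")
            states = s.to_numpy(dtype=np.int8)
        else:
            states = e.states
        data[e.name or f"{e.chromosome}:{e.start_bp}-{e.end_bp}"] = states + 1
    return pd.DataFrame(data, index=pd.Index(samples, name="sample_id"), dtype=np.int8)


def events_to_frame(events: list[CnvEvent]) -> pd.DataFrame:
    return pd.DataFrame([{
        "name": e.name,
        "chromosome": e.chromosome,
        "start_bp": e.start_bp,
        "end_bp": e.end_bp,
        "length_bp": e.length_bp,
        "carrier_count": e.carrier_count,
        "loss_freq": e.loss_freq,
        "gain_freq": e.gain_freq,
        "variant_freq": e.variant_freq,
    } for e in events])


def write_events_bed(events: list[CnvEvent], path) -> None:
    """BED output: 0-based half-open, converted from 1-based inclusive."""
    with open(path, "w") as fh:
        for e in events:
            fh.write(f"{e.chromosome}\t{e.start_bp - 1}\t{e.end_bp}\t{e.name}\n")


def read_events_bed(path, samples: list[str] | None = None) -> list[pd.Series]:
    bed = pd.read_csv(path, sep="\t", header=None,
                      names=["chromosome", "start", "end", "name"],
                      dtype={"chromosome": str})
    bed["start_bp"] = bed["start"] + 1
    bed["end_bp"] = bed["end"]
    return bed[["name", "chromosome", "start_bp", "end_bp"]]
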