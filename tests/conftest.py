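import numpy as np
import pandas as pd
import pytest

from cnvgwas import synthio
from cnvgwas.intensity import IntensityMatrix


@pytest.fixture
def small_map():
    """2 chromosomes x 100 markers, ~10 kb spacing."""
    return synthio.generate_marker_map(2, 100, 10_000, 2_000_000, seed=11)


@pytest.fixture
def flat_gc_map():
    """Single-chromosome map with constant GC (no waviness to remove)."""
    pos = np.arange(1, 201) * 5_000
    return pd.DataFrame({
        "marker_id": [f"M1_{i:06d}" for i in range(1, 201)],
        "chromosome": "1",
        "position": pos,
        "gc_fraction": 0.5,
    })


def make_matrix(lrr, marker_map, corrected=True, samples=None):
    lrr = np.asarray(lrr, dtype=float)
    samples = samples or [f"S{i + 1:04d}" for i in range(lrr.shape[0])]
    return IntensityMatrix(samples=samples, marker_map=marker_map.reset_index(drop=True),
                           lrr=lrr, corrected=corrected)


def planted_loss_matrix(seed, n_samples=50, n_markers=200, first=50, last=59,
                        shift=-1.0, carrier_fraction=0.3, noise_sd=0.15):
    """The standard segmentation benchmark: one planted loss on one chromosome."""
    pos = np.arange(1, n_markers + 1) * 5_000
    mm = pd.DataFrame({
        "marker_id": [f"M1_{i:06d}" for i in range(1, n_markers + 1)],
        "chromosome": "1", "position": pos, "gc_fraction": 0.5,
    })
    cnv = synthio.PlantedCnv("1", int(pos[first]), int(pos[last]),
                             "loss" if shift < 0 else "gain",
                             carrier_fraction, shift)
    m, truth = synthio.generate_lrr(mm, n_samples, [cnv], noise_sd=noise_sd,
                                    gc_wave_amplitude=0.0, seed=seed)
    m.corrected = True  # flat GC; nothing to remove
    return m, truth
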