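import numpy as np
import pandas as pd
import pytest

from cadkit.intervals import GenomicInterval
from cadkit.signal import SAMPLE_COLUMNS, SignalMatrix
from cadkit.simulate import SimConfig, simulate_peaks, simulate_timecourse


def random_intervals(rng, n, chrom="chr1", max_pos=10_000, max_len=400, prefix="iv"):
    """n random intervals on a toy chromosome (may overlap)."""
    out = []
    for i in range(n):
        start = int(rng.integers(0, max_pos - max_len))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length, f"{prefix}_{i:04d}"))
    return out


def make_stage_matrix(values, stages=None, condition="control", unit="rpkm"):
    """SignalMatrix with one replicate per stage from a peaks x stages array."""
    values = np.asarray(values, dtype=float)
    T = values.shape[1]
    stages = stages or [f"s{i}" for i in range(1, T + 1)]
    samples = pd.DataFrame(
        [
            (f"{condition}_{st}_r1", st, i + 1, condition, 1, 1e7)
            for i, st in enumerate(stages)
        ],
        columns=SAMPLE_COLUMNS,
    )
    vals = pd.DataFrame(
        values,
        index=pd.Index([f"peak_{i:05d}" for i in range(values.shape[0])], name="peak_id"),
        columns=samples["sample"].tolist(),
    )
    return SignalMatrix(values=vals, samples=samples, unit=unit)


@pytest.fixture(scope="session")
def small_sim():
    """A 400-peak simulated time course shared by read-only tests."""
    cfg = SimConfig(n_peaks=400, seed=11)
    peaks = simulate_peaks(cfg)
    counts, truth = simulate_timecourse(cfg, peaks)
    return cfg, peaks, counts, truth
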