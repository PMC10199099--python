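"""Peaks x samples signal matrices: normalization, metaprofiles, bootstrap.

The :class:`SignalMatrix` is the central container downstream of peak
merging: a peaks x samples grid of raw counts or RPKM, with an ordered
sample sheet (stage, condition, replicate, library size).  RPKM here is
reads per kilobase of peak per million mapped reads,

    rpkm = count * 1e9 / (peak_length_bp * library_size),

and "normalized signal" for trajectory work means log2(RPKM + 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .intervals import PeakSet

logger = logging.getLogger(__name__)

#: recognised units for SignalMatrix.values
UNITS = ("raw_count", "rpkm", "log2_rpkm", "zscore")

SAMPLE_COLUMNS = ["sample", "stage", "stage_index", "condition", "replicate", "library_size"]


@dataclass
class SignalMatrix:
    """Peaks x samples numeric grid plus an ordered sample sheet.

    ``values``: DataFrame indexed by peak id, one column per sample.
    ``samples``: DataFrame with columns ``sample, stage, stage_index,
    condition, replicate, library_size``; stage_index is a contiguous
    1..T ordering shared across conditions.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    unit: str = "raw_count"

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}")
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns {missing}")
        if list(self.values.columns) != list(self.samples["sample"]):
            raise ValueError("values columns and sample sheet rows disagree")
        if self.unit in ("raw_count", "rpkm") and (self.values.values < 0).any():
            raise ValueError(f"negative values not allowed for unit {self.unit}")
        idx = sorted(self.samples["stage_index"].unique())
        if idx != list(range(1, len(idx) + 1)):
            raise ValueError("stage_index must be contiguous 1..T")

    @property
    def peak_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def stages(self) -> list[str]:
        """Stage names in stage_index order."""
        s = self.samples.drop_duplicates("stage_index").sort_values("stage_index")
        return list(s["stage"])

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.samples["condition"]))

    def stage_means(self, condition: str) -> pd.DataFrame:
        """Average replicates: peaks x stages matrix for one condition."""
        sub = self.samples[self.samples["condition"] == condition]
        if sub.empty:
            raise KeyError(f"no samples for condition {condition!r}")
        out = {}
        for sidx, grp in sub.groupby("stage_index"):
            out[int(sidx)] = self.values[list(grp["sample"])].mean(axis=1)
        stages = self.stages
        df = pd.DataFrame({stages[i - 1]: out[i] for i in sorted(out)})
        return df

    def write_tsv(self, matrix_path: str | Path, meta_path: str | Path) -> None:
        self.values.to_csv(matrix_path, sep="\t", index_label="peak_id")
        self.samples.to_csv(meta_path, sep="\t", index=False)

    @classmethod
    def read_tsv(
        cls, matrix_path: str | Path, meta_path: str | Path, unit: str = "raw_count"
    ) -> "SignalMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col="peak_id", comment="#")
        samples = pd.read_csv(meta_path, sep="\t", comment="#")
        return cls(values=values, samples=samples, unit=unit)


@dataclass(frozen=True)
class ProfileConfig:
    """Window geometry for signal pileups around peak centers."""

    flank_bp: int = 3000
    bin_bp: int = 50

    def __post_init__(self) -> None:
        if self.flank_bp <= 0 or self.bin_bp <= 0:
            raise ValueError("flank_bp and bin_bp must be positive")
        if self.flank_bp % self.bin_bp != 0:
            raise ValueError("flank_bp must be divisible by bin_bp")

    @property
    def n_bins(self) -> int:
        return 2 * self.flank_bp // self.bin_bp


@dataclass(frozen=True)
class BootstrapConfig:
    n_boot: int = 1000
    level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.level < 1.0):
            raise ValueError("level must lie in (0, 1)")
        if self.n_boot < 100:
            raise ValueError("n_boot must be >= 100")


def rpkm_normalize(
    counts: SignalMatrix,
    peak_lengths: Mapping[str, int] | pd.Series,
    library_sizes: Mapping[str, float] | pd.Series | None = None,
) -> SignalMatrix:
    """Convert raw counts to RPKM.

    ``library_sizes`` defaults to the sample sheet's ``library_size``
    column; an explicit mapping sample -> mapped reads overrides it.
    RPKM is invariant to jointly rescaling counts and library sizes.
    """
    if counts.unit != "raw_count":
        raise ValueError("rpkm_normalize expects unit raw_count")
    lengths = pd.Series(peak_lengths, dtype=float)
    missing = set(counts.peak_ids) - set(lengths.index)
    if missing:
        raise ValueError(f"peak_lengths missing {len(missing)} peak id(s)")
    lengths = lengths.reindex(counts.values.index)
    if (lengths <= 0).any():
        raise ValueError("peak lengths must be positive")
    if library_sizes is None:
        libs = pd.Series(
            counts.samples["library_size"].values,
            index=counts.samples["sample"].values,
            dtype=float,
        )
    else:
        libs = pd.Series(library_sizes, dtype=float)
    missing_s = set(counts.values.columns) - set(libs.index)
    if missing_s:
        raise ValueError(f"library_sizes missing samples {sorted(missing_s)}")
    libs = libs.reindex(counts.values.columns)
    if (libs <= 0).any():
        raise ValueError("library sizes must be positive")
    rpkm = counts.values * 1e9
    rpkm = rpkm.div(lengths, axis=0).div(libs, axis=1)
    return SignalMatrix(values=rpkm, samples=counts.samples.copy(), unit="rpkm")


def log_transform(m: SignalMatrix, pseudocount: float = 1.0) -> SignalMatrix:
    """log2(x + pseudocount); the "normalized signal" scale for CAD/GCR work."""
    if m.unit != "rpkm":
        raise ValueError("log_transform expects unit rpkm")
    if (m.values.values < 0).any():
        raise ValueError("negative input to log_transform")
    vals = np.log2(m.values + pseudocount)
    return SignalMatrix(values=vals, samples=m.samples.copy(), unit="log2_rpkm")


CoverageLike = Mapping[str, np.ndarray] | Callable[[str, int, int], np.ndarray]


def _fetch(signal: CoverageLike, chrom: str, start: int, end: int) -> np.ndarray | None:
    """Per-bp coverage for [start, end); None when out of bounds."""
    if callable(signal):
        try:
            arr = signal(chrom, start, end)
        except (KeyError, IndexError):
            return None
        return None if arr is None else np.asarray(arr, dtype=float)
    track = signal.get(chrom)
    if track is None or start < 0 or end > len(track):
        return None
    return np.asarray(track[start:end], dtype=float)


def metaprofile(
    signal: CoverageLike,
    regions: PeakSet,
    cfg: ProfileConfig = ProfileConfig(),
    use_summit: bool = False,
) -> np.ndarray:
    """Mean signal per bin in a +/- flank window around each peak center.

    ``signal`` is either a dict chrom -> per-bp coverage array or a
    callable ``(chrom, start, end) -> array``.  The center is the
    interval midpoint (or the narrowPeak summit when ``use_summit``).
    Windows falling outside the available track are dropped with a
    warning; the profile is the per-bin mean over the remaining regions.
    """
    if len(regions) == 0:
        raise ValueError("metaprofile requires at least one region")
    n_bins = cfg.n_bins
    acc = np.zeros(n_bins)
    n_used = 0
    dropped = 0
    for iv in regions:
        center = iv.start + iv.summit if (use_summit and iv.summit is not None) else iv.center
        lo, hi = center - cfg.flank_bp, center + cfg.flank_bp
        per_bp = _fetch(signal, iv.chrom, lo, hi)
        if per_bp is None or len(per_bp) != 2 * cfg.flank_bp:
            dropped += 1
            continue
        acc += per_bp.reshape(n_bins, cfg.bin_bp).mean(axis=1)
        n_used += 1
    if dropped:
        warnings.warn(f"metaprofile: dropped {dropped} out-of-bounds window(s)")
    if n_used == 0:
        raise ValueError("metaprofile: every window fell out of bounds")
    return acc / n_used


def bootstrap_ci_mean(
    trajectories: pd.DataFrame | np.ndarray,
    cfg: BootstrapConfig = BootstrapConfig(),
) -> pd.DataFrame:
    """Percentile-bootstrap confidence band for a per-stage mean trajectory.

    Rows are peaks/genes of one class, columns are ordered stages.
    Rows are resampled with replacement ``n_boot`` times, the per-stage
    mean recomputed each draw, and the band taken at the
    ``(1 - level)/2`` and ``(1 + level)/2`` quantiles.  Deterministic
    given ``cfg.seed``.

    Returns a DataFrame with columns ``mean, lower, upper`` indexed by
    stage.
    """
    if isinstance(trajectories, pd.DataFrame):
        data = trajectories.values.astype(float)
        stage_index = list(trajectories.columns)
    else:
        data = np.asarray(trajectories, dtype=float)
        stage_index = list(range(data.shape[1]))
    n = data.shape[0]
    if n < 2:
        raise ValueError("bootstrap CI undefined for fewer than 2 rows")
    rng = np.random.default_rng(cfg.seed)
    idx = rng.integers(0, n, size=(cfg.n_boot, n))
    boot_means = data[idx].mean(axis=1)  # n_boot x T
    alpha = (1.0 - cfg.level) / 2.0
    lower = np.quantile(boot_means, alpha, axis=0)
    upper = np.quantile(boot_means, 1.0 - alpha, axis=0)
    return pd.DataFrame(
        {"mean": data.mean(axis=0), "lower": lower, "upper": upper},
        index=pd.Index(stage_index, name="stage"),
    )
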