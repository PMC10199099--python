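"""Chromatin accessibility dynamics: open/close trajectories and GCRs.

A peak's accessibility time course is binarized against an RPKM
threshold (default 2.0: at or above counts as open) and the resulting
open/closed sequence classified into

* ``stable_open`` / ``stable_closed`` — no state switch;
* ``OC_k`` — open at stages 1..k, closed from stage k+1 on (the locus
  closes after stage k);
* ``CO_k`` — closed at stages 1..k, open from stage k+1 on;
* ``complex`` — more than one switch.

k indexes the last stage in the original state, so with stages
[MEF, day0, day1, day3, day5, day7], CO1/CO2/CO3 peaks open at day0,
day1 and day3 respectively.

Gradually closed regions (GCRs) are peaks whose normalized
(log2 RPKM+1) signal declines across every adjacent stage pair relative
to a threshold theta = fraction x (global range of the normalized
matrix).  Two readings of "declining relative to theta" are exposed as
modes; ``monotone_min_step`` (every drop >= theta) is the default.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .signal import SignalMatrix

logger = logging.getLogger(__name__)

DEFAULT_STAGES = ("MEF", "day0", "day1", "day3", "day5", "day7")

CLASS_STABLE_OPEN = "stable_open"
CLASS_STABLE_CLOSED = "stable_closed"
CLASS_COMPLEX = "complex"


@dataclass(frozen=True)
class CadConfig:
    """Binarization and stage ordering for trajectory classification."""

    open_threshold: float = 2.0
    stages: tuple[str, ...] = DEFAULT_STAGES
    boundary_is_open: bool = True

    def __post_init__(self) -> None:
        if self.open_threshold <= 0:
            raise ValueError("open_threshold must be positive")
        if len(self.stages) < 3:
            raise ValueError("need at least 3 stages")


@dataclass(frozen=True)
class CadLabel:
    """Trajectory class plus the transition index k (None when no switch)."""

    class_: str
    transition_index: int | None = None

    @property
    def name(self) -> str:
        if self.transition_index is None:
            return self.class_
        return f"{self.class_}{self.transition_index}"


@dataclass(frozen=True)
class GcrConfig:
    """Threshold rule for gradually-closed-region detection.

    ``range_fraction`` scales the global signal range into theta;
    ``mode`` selects the reading of the per-step rule; ``min_total_drop``
    (literal_max_step mode only) defaults to theta itself.
    """

    range_fraction: float = 0.05
    mode: str = "monotone_min_step"
    min_total_drop: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.range_fraction < 1.0):
            raise ValueError("range_fraction must lie in (0, 1)")
        if self.mode not in ("monotone_min_step", "literal_max_step"):
            raise ValueError(f"unknown GCR mode {self.mode!r}")


def binarize(
    m: SignalMatrix, cfg: CadConfig = CadConfig(), condition: str | None = None
) -> pd.DataFrame:
    """Peaks x stages boolean grid (True = open) for one condition.

    Replicates are averaged on the RPKM scale first; a value at the
    threshold counts as open when ``boundary_is_open`` (the default).
    """
    if m.unit != "rpkm":
        raise ValueError("binarize expects an RPKM matrix")
    if condition is None:
        conds = m.conditions
        if len(conds) != 1:
            raise ValueError(f"matrix has conditions {conds}; pick one")
        condition = conds[0]
    means = m.stage_means(condition)
    missing = [s for s in cfg.stages if s not in means.columns]
    if missing:
        raise ValueError(f"missing stage column(s) {missing} for {condition!r}")
    means = means[list(cfg.stages)]
    if cfg.boundary_is_open:
        return means >= cfg.open_threshold
    return means > cfg.open_threshold


def classify_trajectory(states: Sequence[bool]) -> CadLabel:
    """Classify one open/closed sequence (length >= 3) into a CadLabel."""
    s = [bool(x) for x in states]
    if len(s) < 3:
        raise ValueError("trajectory must span at least 3 stages")
    switches = [i for i in range(len(s) - 1) if s[i] != s[i + 1]]
    if not switches:
        return CadLabel(CLASS_STABLE_OPEN if s[0] else CLASS_STABLE_CLOSED)
    if len(switches) == 1:
        k = switches[0] + 1  # last stage (1-based) in the original state
        return CadLabel("OC" if s[0] else "CO", k)
    return CadLabel(CLASS_COMPLEX)


def classify_all(
    m: SignalMatrix,
    cfg: CadConfig = CadConfig(),
    condition: str | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Classify every peak's trajectory for one condition.

    Returns ``(labels, summary)``: a per-peak frame with columns
    ``condition, class, transition_index, label`` indexed by peak id,
    and the per-label count series (summing to the number of peaks).
    """
    if condition is None:
        conds = m.conditions
        if len(conds) != 1:
            raise ValueError(f"matrix has conditions {conds}; pick one")
        condition = conds[0]
    grid = binarize(m, cfg, condition).values
    records = []
    for pid, row in zip(m.peak_ids, grid):
        lab = classify_trajectory(row)
        records.append((pid, condition, lab.class_, lab.transition_index, lab.name))
    labels = pd.DataFrame.from_records(
        records, columns=["peak_id", "condition", "class", "transition_index", "label"]
    ).set_index("peak_id")
    summary = labels["label"].value_counts().sort_index()
    return labels, summary


def class_shift_table(labels_a: pd.DataFrame, labels_b: pd.DataFrame) -> pd.DataFrame:
    """Cross-tab of per-peak labels between two conditions (rows = A)."""
    joined = labels_a[["label"]].join(
        labels_b[["label"]], how="inner", lsuffix="_a", rsuffix="_b"
    )
    return pd.crosstab(joined["label_a"], joined["label_b"])


def gcr_threshold(m: SignalMatrix | pd.DataFrame, cfg: GcrConfig = GcrConfig()) -> float:
    """theta = range_fraction x (global max - global min) of the matrix."""
    values = m.values.values if isinstance(m, SignalMatrix) else np.asarray(m, dtype=float)
    if values.size == 0:
        raise ValueError("empty matrix")
    rng = float(values.max() - values.min())
    if rng == 0.0:
        warnings.warn("constant signal matrix: GCR threshold is 0")
    return cfg.range_fraction * rng


def is_gcr_trajectory(traj: Sequence[float], theta: float, cfg: GcrConfig) -> bool:
    """Apply the per-trajectory GCR rule for the configured mode."""
    x = np.asarray(traj, dtype=float)
    if len(x) < 3:
        raise ValueError("trajectory must span at least 3 stages")
    drops = x[:-1] - x[1:]
    if cfg.mode == "monotone_min_step":
        return bool((drops >= theta).all())
    min_total = theta if cfg.min_total_drop is None else cfg.min_total_drop
    return bool(
        (drops >= 0).all() and (drops <= theta).all() and (x[0] - x[-1]) >= min_total
    )


@dataclass
class GcrResult:
    """GCR membership (called on the reference condition) plus the mean
    normalized trajectory of that set in every condition."""

    theta: float
    reference: str
    members: list[str]
    mean_trajectories: pd.DataFrame  # conditions x stages

    def __len__(self) -> int:
        return len(self.members)


def detect_gcr(
    m: SignalMatrix,
    cfg: GcrConfig = GcrConfig(),
    reference: str | None = None,
    theta: float | None = None,
) -> GcrResult:
    """Detect gradually closed regions on the reference condition.

    ``m`` must be on the normalized (log2_rpkm) scale.  theta defaults
    to :func:`gcr_threshold` of the whole matrix.  Membership is decided
    from the reference condition's stage means; the mean trajectory of
    the member set is then reported for every condition so that a
    knockdown's slower closing shows up as an elevated curve at
    intermediate stages.
    """
    if m.unit != "log2_rpkm":
        raise ValueError("detect_gcr expects a log2_rpkm matrix")
    if len(m.stages) < 3:
        raise ValueError("need at least 3 stages")
    if reference is None:
        reference = m.conditions[0]
    if theta is None:
        theta = gcr_threshold(m, cfg)
    ref_means = m.stage_means(reference)
    mask = np.array(
        [is_gcr_trajectory(row, theta, cfg) for row in ref_means.values]
    )
    members = [pid for pid, keep in zip(ref_means.index, mask) if keep]
    rows = {}
    for cond in m.conditions:
        means = m.stage_means(cond)
        if members:
            rows[cond] = means.loc[members].mean(axis=0)
        else:
            rows[cond] = pd.Series(np.nan, index=means.columns)
    traj = pd.DataFrame(rows).T
    traj.index.name = "condition"
    return GcrResult(theta=theta, reference=reference, members=members, mean_trajectories=traj)
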