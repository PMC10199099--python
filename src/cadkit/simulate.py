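"""Synthetic reprogramming time-course data with planted ground truth.

Emulates a two-condition (control / knockdown), six-stage ATAC-seq peak
count matrix plus coupled CUT&Tag densities and expression
trajectories, so every pipeline stage can be exercised against known
truth without any external download:

* peaks placed without overlap on a toy genome (3 chromosomes, 10 Mb);
* per-peak trajectory classes (stable, OC_k, CO_k, gradually-closing,
  complex) with negative-binomial replicate noise whose mean inverts
  RPKM normalization by construction;
* a knockdown condition in which a planted fraction of closing peaks
  close one stage late — the "slower closing of somatic loci" readout;
* per-region CUT&Tag densities with a planted increased set and a
  global scale offset between conditions (exercises M-A rescaling);
* one gene per non-complex peak whose expression follows its promoter
  accessibility up to an affine map plus Gaussian noise.

All emitted artifacts are reproducible bit-for-bit from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .dynamics import DEFAULT_STAGES
from .intervals import GeneModel, GenomicInterval, PeakSet
from .signal import SAMPLE_COLUMNS, SignalMatrix

PEAK_WIDTH_BP = 500
MIN_SPACING_BP = 1500
TOY_CHROMS = {"chr1": 10_000_000, "chr2": 10_000_000, "chr3": 10_000_000}

CONDITION_CONTROL = "control"
CONDITION_KNOCKDOWN = "knockdown"


def default_class_mix(n_stages: int = 6) -> dict[str, float]:
    """Mix over stable / OC_k / CO_k / gcr / complex summing to 1."""
    mix: dict[str, float] = {"stable_open": 0.15, "stable_closed": 0.15}
    per_k = 0.25 / (n_stages - 1)
    for k in range(1, n_stages):
        mix[f"OC{k}"] = per_k
        mix[f"CO{k}"] = per_k
    mix["gcr"] = 0.10
    mix["complex"] = 0.10
    return mix


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic time course.

    ``open_rpkm`` / ``closed_rpkm`` set a 4x separation between the
    open state and the binarization boundary of 2 RPKM; NB dispersion
    0.05 gives realistic replicate over-dispersion without defeating
    classification; the knockdown delays 30% of closing peaks by one
    stage.
    """

    n_peaks: int = 5000
    stages: tuple[str, ...] = DEFAULT_STAGES
    class_mix: Mapping[str, float] | None = None
    open_rpkm: float = 8.0
    closed_rpkm: float = 0.5
    nb_dispersion: float = 0.05
    n_replicates: int = 2
    library_size: float = 1e7
    delay_fraction: float = 0.3
    delay_stages: int = 1
    density_increase_fraction: float = 0.1
    density_effect: float = 4.0
    density_y_scale: float = 2.0
    expression_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        mix = self.mix
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        if self.density_effect < 1:
            raise ValueError("density effect must be >= 1 (1 plants nothing)")
        if not (0 <= self.delay_fraction <= 1):
            raise ValueError("delay_fraction must lie in [0, 1]")
        if self.open_rpkm <= self.closed_rpkm:
            raise ValueError("open_rpkm must exceed closed_rpkm")
        if self.delay_stages < 0:
            raise ValueError("delay_stages must be >= 0")

    @property
    def mix(self) -> dict[str, float]:
        if self.class_mix is not None:
            return dict(self.class_mix)
        return default_class_mix(len(self.stages))

    @property
    def n_stages(self) -> int:
        return len(self.stages)


@dataclass
class SyntheticTruth:
    """Planted per-peak and per-gene ground truth.

    ``peaks``: frame indexed by peak id with columns ``class`` (planted
    control-condition label), ``transition_index``, ``delayed``,
    ``gcr``, ``class_knockdown`` (effective label after the delay) and,
    once :func:`simulate_cuttag` has run, ``density_class``.
    ``genes``: frame indexed by gene id with ``peak_id`` and
    ``archetype``.
    """

    peaks: pd.DataFrame
    genes: pd.DataFrame | None = None


def simulate_peaks(cfg: SimConfig) -> PeakSet:
    """Place ``n_peaks`` non-overlapping 500 bp peaks on the toy genome.

    Peaks sit on a slot grid guaranteeing >= 1.5 kb spacing; which slots
    are used is drawn from the seeded RNG, so placement is deterministic
    per (config, seed).
    """
    slot = PEAK_WIDTH_BP + MIN_SPACING_BP
    slots: list[tuple[str, int]] = []
    for chrom, size in TOY_CHROMS.items():
        slots.extend((chrom, s * slot) for s in range(size // slot))
    if cfg.n_peaks > len(slots):
        raise ValueError(
            f"toy genome holds at most {len(slots)} peaks, asked for {cfg.n_peaks}"
        )
    rng = np.random.default_rng(cfg.seed)
    chosen = rng.choice(len(slots), size=cfg.n_peaks, replace=False)
    chosen_slots = sorted(slots[i] for i in chosen)
    return PeakSet(
        GenomicInterval(chrom, start, start + PEAK_WIDTH_BP, f"peak_{i + 1:06d}")
        for i, (chrom, start) in enumerate(chosen_slots)
    )


def _state_trajectory(label: str, T: int, rng: np.random.Generator) -> np.ndarray:
    """Open-fraction trajectory in [0, 1] for one planted class."""
    if label == "stable_open":
        return np.ones(T)
    if label == "stable_closed":
        return np.zeros(T)
    if label.startswith("OC"):
        k = int(label[2:])
        return np.array([1.0] * k + [0.0] * (T - k))
    if label.startswith("CO"):
        k = int(label[2:])
        return np.array([0.0] * k + [1.0] * (T - k))
    if label == "gcr":
        # placeholder; GCR means are built on the log scale elsewhere
        return np.linspace(1.0, 0.0, T)
    if label == "complex":
        while True:
            s = rng.integers(0, 2, size=T).astype(float)
            if (np.abs(np.diff(s)) > 0).sum() >= 2:
                return s
    raise ValueError(f"unknown planted class {label!r}")


def _mean_rpkm(
    label: str, T: int, cfg: SimConfig, rng: np.random.Generator, delay: int = 0
) -> np.ndarray:
    """Per-stage mean RPKM for one peak, optionally closing late.

    Binary classes interpolate between ``closed_rpkm`` and
    ``open_rpkm``; GCR peaks descend linearly on the log2 scale from
    open to closed, with a delayed variant holding its starting level
    for ``delay`` stages before descending.
    """
    if label == "gcr":
        log_path = np.linspace(np.log2(cfg.open_rpkm), np.log2(cfg.closed_rpkm), T)
        if delay:
            log_path = np.concatenate([np.repeat(log_path[0], delay), log_path[:-delay]])
        return np.exp2(log_path)
    if delay and label.startswith("OC"):
        k = min(int(label[2:]) + delay, T - 1)
        label = f"OC{k}"
    states = _state_trajectory(label, T, rng)
    return cfg.closed_rpkm + states * (cfg.open_rpkm - cfg.closed_rpkm)


def _nb_counts(
    mean_counts: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """NB draws with Var = mu + dispersion * mu^2 (Poisson when disp -> 0)."""
    mu = np.asarray(mean_counts, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def simulate_timecourse(
    cfg: SimConfig, peaks: PeakSet
) -> tuple[SignalMatrix, SyntheticTruth]:
    """Emit the raw-count matrix for both conditions plus the truth table.

    Mean counts are ``rpkm * length * library_size / 1e9`` so that RPKM
    normalization inverts the construction in expectation; replicate
    counts are NB draws around those means.  In the knockdown condition
    a planted fraction of OC and GCR peaks closes ``delay_stages``
    late.
    """
    rng = np.random.default_rng(cfg.seed)
    T = cfg.n_stages
    mix = cfg.mix
    classes = list(mix)
    probs = np.array([mix[c] for c in classes])
    planted = rng.choice(classes, size=len(peaks), p=probs)

    delayed = np.zeros(len(peaks), dtype=bool)
    closing = np.array([c.startswith("OC") or c == "gcr" for c in planted])
    idx_closing = np.flatnonzero(closing)
    n_delay = int(round(cfg.delay_fraction * len(idx_closing)))
    if n_delay and cfg.delay_stages:
        delayed[rng.choice(idx_closing, size=n_delay, replace=False)] = True

    length = PEAK_WIDTH_BP
    scale = length * cfg.library_size / 1e9  # RPKM -> expected count

    samples = []
    for cond in (CONDITION_CONTROL, CONDITION_KNOCKDOWN):
        for sidx, stage in enumerate(cfg.stages, start=1):
            for rep in range(1, cfg.n_replicates + 1):
                samples.append(
                    (f"{cond}_{stage}_r{rep}", stage, sidx, cond, rep, cfg.library_size)
                )
    sample_sheet = pd.DataFrame(samples, columns=SAMPLE_COLUMNS)

    values = np.zeros((len(peaks), len(samples)), dtype=np.int64)
    class_kd = []
    for i, label in enumerate(planted):
        mean_a = _mean_rpkm(label, T, cfg, rng)
        delay = cfg.delay_stages if delayed[i] else 0
        mean_b = _mean_rpkm(label, T, cfg, rng, delay=delay) if delay else mean_a
        if label == "complex":
            # knockdown shares the control's (randomly drawn) pattern
            mean_b = mean_a
        col = 0
        for cond_mean in (mean_a, mean_b):
            for sidx in range(T):
                for _rep in range(cfg.n_replicates):
                    values[i, col] = _nb_counts(
                        cond_mean[sidx] * scale, cfg.nb_dispersion, rng
                    )
                    col += 1
        if label.startswith("OC") and delay:
            class_kd.append(f"OC{min(int(label[2:]) + delay, T - 1)}")
        else:
            class_kd.append(label)

    counts = SignalMatrix(
        values=pd.DataFrame(values, index=pd.Index(peaks.ids, name="peak_id"),
                            columns=sample_sheet["sample"].tolist()),
        samples=sample_sheet,
        unit="raw_count",
    )
    transition = [
        int(c[2:]) if c[:2] in ("OC", "CO") else None for c in planted
    ]
    truth = SyntheticTruth(
        peaks=pd.DataFrame(
            {
                "class": planted,
                "transition_index": pd.array(transition, dtype="Int64"),
                "delayed": delayed,
                "gcr": planted == "gcr",
                "class_knockdown": class_kd,
            },
            index=pd.Index(peaks.ids, name="peak_id"),
        )
    )
    return counts, truth


def simulate_cuttag(
    cfg: SimConfig, peaks: PeakSet, truth: SyntheticTruth
) -> tuple[pd.Series, pd.Series]:
    """Two per-region density vectors (x, y) with a planted increased set.

    Baseline region intensities are Gamma-distributed (shape 2, mean
    100); a planted fraction gets its x-rate multiplied by
    ``density_effect``; y is globally rescaled by ``density_y_scale``
    so the M-A fit has real bias to remove; both sides are Poisson
    sampled.  The planted class is recorded in ``truth.peaks
    ['density_class']``.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    n = len(peaks)
    lam = rng.gamma(shape=2.0, scale=50.0, size=n)
    effect = cfg.density_effect
    increased = np.zeros(n, dtype=bool)
    n_inc = int(round(cfg.density_increase_fraction * n))
    if n_inc and effect != 1.0:
        increased[rng.choice(n, size=n_inc, replace=False)] = True
    lam_x = np.where(increased, lam * effect, lam)
    x = rng.poisson(lam_x).astype(float)
    y = rng.poisson(lam * cfg.density_y_scale).astype(float)
    truth.peaks["density_class"] = np.where(increased, "increased", "no_change")
    ids = pd.Index(peaks.ids, name="region_id")
    return pd.Series(x, index=ids, name="x"), pd.Series(y, index=ids, name="y")


def simulate_expression(
    cfg: SimConfig, peaks: PeakSet, truth: SyntheticTruth
) -> tuple[pd.DataFrame, list[GeneModel]]:
    """One gene per non-complex peak, expression tracking accessibility.

    The expression trajectory is an affine map (offset 4, gain 0.5) of
    the peak's noise-free log2 mean-RPKM trajectory in the control
    condition, plus Gaussian noise; the TSS sits at the peak center on
    a coin-flipped strand.  Gene archetypes (= the peak's planted
    class) land in ``truth.genes``.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    T = cfg.n_stages
    rows, genes, gene_ids, archetypes, peak_ids = [], [], [], [], []
    for iv, (pid, rec) in zip(peaks, truth.peaks.iterrows()):
        label = rec["class"]
        if label == "complex":
            continue
        mean = _mean_rpkm(label, T, cfg, rng)
        traj = 4.0 + 0.5 * np.log2(mean + 1.0)
        noise = rng.normal(0.0, cfg.expression_noise_sd, size=T)
        gid = f"gene_{len(gene_ids) + 1:05d}"
        strand = "+" if rng.integers(0, 2) else "-"
        tss = iv.center
        if strand == "+":
            genes.append(GeneModel(iv.chrom, tss, tss + 5000, strand, gid))
        else:
            genes.append(GeneModel(iv.chrom, max(0, tss - 4999), tss + 1, strand, gid))
        rows.append(traj + noise)
        gene_ids.append(gid)
        archetypes.append(label)
        peak_ids.append(pid)
    expr = pd.DataFrame(
        np.array(rows), index=pd.Index(gene_ids, name="gene_id"), columns=list(cfg.stages)
    )
    truth.genes = pd.DataFrame(
        {"peak_id": peak_ids, "archetype": archetypes},
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return expr, genes


#: archetype shapes on a raw 0..1 amplitude scale
ARCHETYPE_SHAPES: dict[str, tuple[float, ...]] = {
    "up_early": (0.0, 0.8, 1.0, 1.0, 1.0, 1.0),
    "up_late": (0.0, 0.0, 0.0, 0.2, 0.8, 1.0),
    "down_early": (1.0, 0.2, 0.0, 0.0, 0.0, 0.0),
    "down_late": (1.0, 1.0, 1.0, 0.8, 0.2, 0.0),
    "transient_up": (0.0, 0.7, 1.0, 0.7, 0.2, 0.0),
    "flat": (0.5, 0.5, 0.5, 0.5, 0.5, 0.5),
}


def _zscale(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


#: archetype patterns on the z-score scale trajectory clustering sees
#: (per-pattern mean 0, sd 1; flat is the all-zero pattern)
ARCHETYPES: dict[str, np.ndarray] = {
    name: _zscale(np.asarray(shape, dtype=float))
    for name, shape in ARCHETYPE_SHAPES.items()
}


def simulate_archetype_trajectories(
    n_per_archetype: int = 100,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Six canonical trajectory archetypes with Gaussian noise.

    Patterns live on the z-score scale on which trajectory clustering
    operates (standardized change patterns, flat = no change).  Returns
    the genes x stages matrix and the per-gene archetype truth, for
    benchmarking trajectory clustering.
    """
    rng = np.random.default_rng(seed)
    rows, labels, ids = [], [], []
    for name, base in ARCHETYPES.items():
        for i in range(n_per_archetype):
            rows.append(base + rng.normal(0.0, noise_sd, size=len(base)))
            labels.append(name)
            ids.append(f"{name}_{i + 1:03d}")
    idx = pd.Index(ids, name="gene_id")
    mat = pd.DataFrame(np.array(rows), index=idx, columns=list(DEFAULT_STAGES))
    return mat, pd.Series(labels, index=idx, name="archetype")
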