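"""Self-organizing-map clustering of z-scored trajectories.

An online rectangular-grid SOM groups expression (or accessibility)
time courses into pattern groups: at each training step one row is
drawn at random, its best-matching unit (BMU, minimum Euclidean
distance, ties to the lowest node index) located, and every node pulled
toward the row with a Gaussian neighborhood weight around the BMU.
Learning rate and neighborhood radius decay exponentially over
training.  With a 1 x K grid this yields K ordered "change pattern"
groups; with the radius forced to zero the update degenerates to online
k-means.

All randomness flows from the config seed, so training is
reproducible end to end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SomConfig:
    """Grid geometry and training schedule.

    ``sigma0`` defaults to half the larger grid dimension; the radius
    and learning rate decay exponentially so that they reach
    ``sigma_end`` / ``lr_end`` at the final step — an ordering phase
    with wide neighborhoods followed by near-k-means convergence.
    """

    grid: tuple[int, int] = (1, 6)
    sigma0: float | None = None
    sigma_end: float = 0.2
    lr0: float = 0.5
    lr_end: float = 0.01
    iters: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        r, c = self.grid
        if r * c < 2:
            raise ValueError("grid must have at least 2 nodes")
        if self.iters != 0 and self.iters < 100:
            raise ValueError("iters must be >= 100 (or 0 for no training)")
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")

    @property
    def n_nodes(self) -> int:
        return self.grid[0] * self.grid[1]

    @property
    def sigma_start(self) -> float:
        return self.sigma0 if self.sigma0 is not None else max(self.grid) / 2.0


@dataclass
class SomGrid:
    """Trained node weights plus their rectangular grid coordinates."""

    weights: np.ndarray  # n_nodes x n_features
    coords: np.ndarray  # n_nodes x 2 (row, col)
    config: SomConfig

    def __post_init__(self) -> None:
        if not np.isfinite(self.weights).all():
            raise ValueError("non-finite SOM weights")


def zscore_rows(m: pd.DataFrame) -> pd.DataFrame:
    """Standardize each row to mean 0, sd 1; constant rows are dropped.

    Uses the population (ddof=0) standard deviation.
    """
    vals = m.values.astype(float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)
    keep = sd[:, 0] > 0
    if not keep.all():
        warnings.warn(f"zscore_rows: dropped {int((~keep).sum())} constant row(s)")
    z = (vals[keep] - mu[keep]) / sd[keep]
    return pd.DataFrame(z, index=m.index[keep], columns=m.columns)


def _bmu(weights: np.ndarray, x: np.ndarray) -> int:
    """Best-matching unit: argmin Euclidean distance, ties to lowest index."""
    d = ((weights - x) ** 2).sum(axis=1)
    return int(np.argmin(d))  # argmin returns the first minimum


def som_train(data: pd.DataFrame | np.ndarray, cfg: SomConfig = SomConfig()) -> SomGrid:
    """Train an online SOM on row-standardized trajectories.

    Weights are initialized from data rows sampled without replacement
    (scale-correct start).  At step t (0-based),

        lr(t)    = lr0 * exp(-t / tau_lr)
        sigma(t) = sigma0 * exp(-t / tau_sigma)
        h(node)  = exp(-d_grid(node, BMU)^2 / (2 sigma(t)^2))
        w_node  += lr(t) * h(node) * (x - w_node)

    with the time constants chosen so lr and sigma land on ``lr_end``
    and ``sigma_end`` at the last step.  A zero radius restricts the
    update to the BMU alone (online k-means).  ``iters = 0`` returns
    the seeded initialization untouched.
    """
    X = data.values.astype(float) if isinstance(data, pd.DataFrame) else np.asarray(data, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite input to som_train")
    n, _ = X.shape
    if n < cfg.n_nodes:
        raise ValueError(f"need >= {cfg.n_nodes} rows to seed the grid")
    rng = np.random.default_rng(cfg.seed)
    init_idx = rng.choice(n, size=cfg.n_nodes, replace=False)
    weights = X[init_idx].copy()
    rows, cols = cfg.grid
    coords = np.array([(i // cols, i % cols) for i in range(cfg.n_nodes)], dtype=float)
    grid_d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)

    sigma0 = cfg.sigma_start
    tau_sigma = (
        cfg.iters / np.log(sigma0 / cfg.sigma_end)
        if sigma0 > cfg.sigma_end > 0
        else np.inf
    )
    tau_lr = (
        cfg.iters / np.log(cfg.lr0 / cfg.lr_end)
        if cfg.lr0 > cfg.lr_end > 0
        else np.inf
    )
    for t in range(cfg.iters):
        x = X[rng.integers(0, n)]
        bmu = _bmu(weights, x)
        lr = cfg.lr0 * np.exp(-t / tau_lr)
        sigma = sigma0 * np.exp(-t / tau_sigma)
        if sigma > 1e-12:
            h = np.exp(-grid_d2[bmu] / (2.0 * sigma**2))
        else:  # degenerate neighborhood: only the BMU moves (online k-means)
            h = np.zeros(cfg.n_nodes)
            h[bmu] = 1.0
        weights += (lr * h)[:, None] * (x - weights)
    return SomGrid(weights=weights, coords=coords, config=cfg)


def som_assign(
    grid: SomGrid, data: pd.DataFrame, order_by_extremum: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign each row to its BMU and summarize the clusters.

    Returns ``(labels, summary)``: per-row frame with ``cluster``
    (``G1``..``GK``) and ``bmu_distance`` columns, and a summary frame
    with cluster sizes and mean trajectories.  Node
    numbering from training is arbitrary, so by default clusters are
    relabeled by the stage of their mean-trajectory extremum (peak
    stage, then sign) to give stable group names across runs; empty
    nodes keep a label but a NaN trajectory.
    """
    X = data.values.astype(float)
    if X.shape[1] != grid.weights.shape[1]:
        raise ValueError(
            f"feature dimension {X.shape[1]} != grid dimension {grid.weights.shape[1]}"
        )
    if X.shape[0] == 0:
        empty = pd.DataFrame(columns=["cluster", "bmu_distance"])
        return empty, pd.DataFrame(columns=["size", *data.columns])
    d2 = ((X[:, None, :] - grid.weights[None, :, :]) ** 2).sum(axis=2)
    bmu = d2.argmin(axis=1)
    bmu_dist = np.sqrt(d2[np.arange(len(bmu)), bmu])

    n_nodes = grid.weights.shape[0]
    means = np.full((n_nodes, X.shape[1]), np.nan)
    sizes = np.zeros(n_nodes, dtype=int)
    for k in range(n_nodes):
        mask = bmu == k
        sizes[k] = int(mask.sum())
        if sizes[k]:
            means[k] = X[mask].mean(axis=0)

    if order_by_extremum:
        keys = []
        for k in range(n_nodes):
            traj = means[k] if sizes[k] else grid.weights[k]
            ext = int(np.argmax(np.abs(traj)))
            keys.append((ext, -traj[ext], k))
        node_order = [k for *_, k in sorted(keys)]
    else:
        node_order = list(range(n_nodes))
    rank = {node: i for i, node in enumerate(node_order)}
    names = [f"G{rank[k] + 1}" for k in range(n_nodes)]

    labels = pd.DataFrame(
        {"cluster": [names[k] for k in bmu], "bmu_distance": bmu_dist},
        index=data.index,
    )
    summary = pd.DataFrame(
        means[node_order],
        index=pd.Index([f"G{i + 1}" for i in range(n_nodes)], name="cluster"),
        columns=data.columns,
    )
    summary.insert(0, "size", sizes[node_order])
    return labels, summary
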