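"""Cross-condition comparisons of peak sets and signal densities.

Two families of operations live here:

* set-level — directional overlap fractions and 2/3-way Venn counts
  over a merged interval universe;
* signal-level — a replicate-free increased / decreased / no_change
  classification of per-region densities between two conditions, using
  an M-A representation (M = log2 ratio, A = mean log2 intensity), a
  robust linear rescaling of M against A to remove global bias, and a
  two-sided exact conditional Poisson test.

The decision rule: a region is ``increased`` when rescaled M >= m_cutoff
and p <= p_cutoff, ``decreased`` symmetrically, otherwise ``no_change``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval, PeakSet, intersect, merge_intervals


@dataclass(frozen=True)
class CompareConfig:
    m_cutoff: float = 1.0
    p_cutoff: float = 0.01
    pseudocount: float = 0.5
    fc_filter: float = 1.5
    bh_alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.m_cutoff <= 0:
            raise ValueError("m_cutoff must be positive")
        if not (0.0 < self.p_cutoff < 1.0):
            raise ValueError("p_cutoff must lie in (0, 1)")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


def overlap_fraction(a: PeakSet, b: PeakSet, min_overlap_bp: int = 1) -> float:
    """Percentage of a's intervals overlapping >= 1 interval of b.

    Directional: ``overlap_fraction(a, b) != overlap_fraction(b, a)``
    in general.
    """
    if len(a) == 0:
        raise ValueError("overlap_fraction: empty query set")
    hits = intersect(a, b, min_overlap_bp)
    n_hit = sum(1 for v in hits.values() if v)
    return 100.0 * n_hit / len(a)


def venn_counts(
    sets: Mapping[str, PeakSet] | Sequence[PeakSet],
    reference: PeakSet | None = None,
) -> pd.Series:
    """Membership-pattern counts over a merged universe for 2 or 3 sets.

    Every interval of the universe (the merged union of the inputs
    unless ``reference`` is given) is assigned a boolean membership
    pattern by >=1 bp overlap with each input set; the returned counts
    are indexed by tuples like ``(True, False, True)`` in input order
    and sum to the universe size.
    """
    if not isinstance(sets, Mapping):
        sets = {f"set{i + 1}": s for i, s in enumerate(sets)}
    names = list(sets)
    if not (2 <= len(names) <= 3):
        raise ValueError("venn_counts supports 2 or 3 sets")
    for name, s in sets.items():
        if len(s) == 0:
            raise ValueError(f"venn_counts: set {name!r} is empty")
    if reference is None:
        pooled: list = []
        for s in sets.values():
            pooled.extend(s)
        universe = merge_intervals(
            PeakSet(
                GenomicInterval(iv.chrom, iv.start, iv.end, f"u_{i:06d}")
                for i, iv in enumerate(pooled)
            ),
            min_overlap_bp=1,
        )
    else:
        universe = reference
    membership = {}
    for name in names:
        hits = intersect(universe, sets[name])
        membership[name] = {uid: bool(h) for uid, h in hits.items()}
    patterns = [tuple(membership[n][uid] for n in names) for uid in universe.ids]
    index = pd.MultiIndex.from_tuples(
        list(product([True, False], repeat=len(names))), names=names
    )
    counts = pd.Series(0, index=index, dtype=int)
    for pat in patterns:
        counts[pat] += 1
    return counts


def ma_values(
    x: np.ndarray, y: np.ndarray, pseudocount: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """M = log2((x+c)/(y+c)) and A = 0.5*log2((x+c)(y+c))."""
    xc = np.asarray(x, dtype=float) + pseudocount
    yc = np.asarray(y, dtype=float) + pseudocount
    return np.log2(xc / yc), 0.5 * np.log2(xc * yc)


def ma_fit(
    x: np.ndarray,
    y: np.ndarray,
    pseudocount: float = 0.5,
    trim: float = 0.1,
) -> tuple[float, float]:
    """Robust linear fit M = a + b*A over common regions.

    An ordinary least-squares pass is followed by a refit on the middle
    ``1 - 2*trim`` of M residuals, which discounts genuinely changed
    regions when estimating the global bias line.  Requires >= 10
    regions and non-degenerate A variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 10:
        raise ValueError("ma_fit requires >= 10 common regions")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("ma_fit requires non-negative signals")
    M, A = ma_values(x, y, pseudocount)
    if np.var(A) < 1e-12:
        raise ValueError("degenerate A variance: cannot fit M ~ A")
    X = np.column_stack([np.ones_like(A), A])
    beta, *_ = np.linalg.lstsq(X, M, rcond=None)
    resid = M - X @ beta
    lo, hi = np.quantile(resid, [trim, 1.0 - trim])
    keep = (resid >= lo) & (resid <= hi)
    if keep.sum() >= 10 and np.var(A[keep]) > 1e-12:
        beta, *_ = np.linalg.lstsq(X[keep], M[keep], rcond=None)
    return float(beta[0]), float(beta[1])


def _poisson_rate_test(x: int, y: float) -> float:
    """Two-sided exact conditional test of two Poisson counts.

    Conditions on the total: x | x+y ~ Binomial(x+y, 1/2) under the
    null of equal rates (y is rounded to the nearest count).
    """
    xi, yi = int(round(x)), int(round(y))
    n = xi + yi
    if n == 0:
        return 1.0
    return float(stats.binomtest(xi, n, 0.5, alternative="two-sided").pvalue)


def classify_density(
    region_ids: Sequence[str],
    x: np.ndarray,
    y: np.ndarray,
    cfg: CompareConfig = CompareConfig(),
    common: np.ndarray | None = None,
) -> pd.DataFrame:
    """Classify per-region densities into increased / decreased / no_change.

    ``x`` and ``y`` are per-region summed signals in the two conditions,
    aligned to ``region_ids``.  ``common`` optionally masks the regions
    used to fit the M-A bias line (e.g. regions carrying a called peak
    in both conditions); all regions are rescaled with the fitted line.
    The p-value compares x against the bias-corrected y by an exact
    conditional Poisson test, so the classes are invariant to a global
    rescaling of y.

    Returns a DataFrame indexed by region id with columns
    ``x, y, M, A, M_rescaled, p, class``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (len(region_ids) == len(x) == len(y)):
        raise ValueError("region_ids, x and y must align")
    if common is None:
        common = np.ones(len(x), dtype=bool)
    else:
        common = np.asarray(common, dtype=bool)
    a, b = ma_fit(x[common], y[common], cfg.pseudocount)
    M, A = ma_values(x, y, cfg.pseudocount)
    M_rescaled = M - (a + b * A)
    # bias-corrected y on the raw scale: the y that would make M_rescaled the
    # observed departure from the fitted line
    y_adj = (y + cfg.pseudocount) * np.exp2(a + b * A) - cfg.pseudocount
    y_adj = np.maximum(y_adj, 0.0)
    p = np.array([_poisson_rate_test(xi, yi) for xi, yi in zip(x, y_adj)])
    zero = (x == 0) & (y == 0)
    p[zero] = 1.0
    M_rescaled = np.where(zero, 0.0, M_rescaled)
    cls = np.where(
        (M_rescaled >= cfg.m_cutoff) & (p <= cfg.p_cutoff),
        "increased",
        np.where(
            (M_rescaled <= -cfg.m_cutoff) & (p <= cfg.p_cutoff),
            "decreased",
            "no_change",
        ),
    )
    return pd.DataFrame(
        {
            "x": x,
            "y": y,
            "M": M,
            "A": A,
            "M_rescaled": M_rescaled,
            "p": p,
            "class": cls,
        },
        index=pd.Index(region_ids, name="region_id"),
    )


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change_filter(
    fc: Sequence[float], q: Sequence[float], fc_threshold: float = 1.5, alpha: float = 0.05
) -> np.ndarray:
    """Differential-expression style filter: |fold change| >= threshold
    and BH-adjusted p < alpha.  ``fc`` is on the linear scale."""
    fc = np.asarray(fc, dtype=float)
    q = np.asarray(q, dtype=float)
    mag = np.maximum(np.abs(fc), np.where(fc != 0, 1.0 / np.abs(fc), np.inf))
    return (mag >= fc_threshold) & (q < alpha)
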