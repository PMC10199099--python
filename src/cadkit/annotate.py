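"""Peak-to-gene assignment and region-class x expression-group crosstabs.

A peak is assigned a genic context per gene it touches: ``promoter``
when it overlaps the strand-aware promoter window around the TSS
(default +/-2 kb), else ``gene_body`` when it overlaps the gene span,
else nothing; peaks touching no gene are ``intergenic``.  Promoter
takes precedence over gene body for the same gene.

Integration crosstabs count, for each region class (OC_k, increased,
...), how many of its annotated genes fall in each expression pattern
group, with a one-sided hypergeometric over-representation test per
cell and BH correction across cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .compare import bh_adjust
from .intervals import GeneModel, PeakSet


@dataclass(frozen=True)
class AnnotationConfig:
    promoter_upstream_bp: int = 2000
    promoter_downstream_bp: int = 2000

    def __post_init__(self) -> None:
        if self.promoter_upstream_bp < 0 or self.promoter_downstream_bp < 0:
            raise ValueError("promoter window sizes must be >= 0")
        if self.promoter_upstream_bp == 0 and self.promoter_downstream_bp == 0:
            raise ValueError("promoter window cannot be empty on both sides")


def promoter_window(gene: GeneModel, cfg: AnnotationConfig) -> tuple[int, int]:
    """Half-open promoter interval around the TSS, oriented by strand.

    On + the window is [tss - upstream, tss + downstream); on - it is
    the mirror image [tss + 1 - downstream, tss + 1 + upstream), so a
    coordinate-mirrored genome maps + promoters onto - promoters
    exactly.
    """
    u, d = cfg.promoter_upstream_bp, cfg.promoter_downstream_bp
    if gene.strand == "+":
        lo, hi = gene.tss - u, gene.tss + d
    else:
        lo, hi = gene.tss + 1 - d, gene.tss + 1 + u
    return max(0, lo), max(0, hi)


def assign_gene_context(
    ps: PeakSet,
    genes: Sequence[GeneModel],
    cfg: AnnotationConfig = AnnotationConfig(),
) -> pd.DataFrame:
    """Per-peak genic context labels, one row per (peak, gene) hit.

    A peak may hit several genes; each hit is reported with context
    ``promoter`` or ``gene_body`` (promoter wins when both windows are
    touched for the same gene).  Peaks hitting nothing appear once with
    context ``intergenic`` and a null gene id.
    """
    by_chrom: dict[str, list[tuple[int, int, int, int, GeneModel]]] = {}
    for g in genes:
        plo, phi = promoter_window(g, cfg)
        by_chrom.setdefault(g.chrom, []).append((plo, phi, g.start, g.end, g))

    rows: list[tuple[str, str, str | None]] = []
    for iv in ps:
        hits = 0
        for plo, phi, gstart, gend, g in by_chrom.get(iv.chrom, ()):
            in_promoter = min(iv.end, phi) - max(iv.start, plo) >= 1 and phi > plo
            in_body = min(iv.end, gend) - max(iv.start, gstart) >= 1
            if in_promoter:
                rows.append((iv.id, "promoter", g.gene_id))
                hits += 1
            elif in_body:
                rows.append((iv.id, "gene_body", g.gene_id))
                hits += 1
        if hits == 0:
            rows.append((iv.id, "intergenic", None))
    return pd.DataFrame(rows, columns=["peak_id", "context", "gene_id"])


def genes_for_region_class(
    labels: Mapping[str, str] | pd.Series,
    annotation: pd.DataFrame,
) -> dict[str, set[str]]:
    """Deduplicated gene set per region class.

    ``labels`` maps peak id -> class; ``annotation`` is the output of
    :func:`assign_gene_context` (or any frame with peak_id / gene_id
    columns).  Unknown peak ids in the annotation raise.
    """
    labels = dict(labels.items() if isinstance(labels, pd.Series) else labels.items())
    out: dict[str, set[str]] = {}
    for pid, gid in zip(annotation["peak_id"], annotation["gene_id"]):
        if pid not in labels:
            raise KeyError(f"annotation references unknown peak id {pid!r}")
        if gid is None or (isinstance(gid, float) and pd.isna(gid)):
            continue
        out.setdefault(labels[pid], set()).add(gid)
    for cls in set(labels.values()):
        out.setdefault(cls, set())
    return out


def integrate_with_expression(
    gene_sets: Mapping[str, Iterable[str]],
    expr_groups: Mapping[str, str] | pd.Series,
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Crosstab region-class gene sets against expression pattern groups.

    Cells count distinct genes per (region class, expression group);
    genes absent from ``expr_groups`` land in an ``unassigned`` column.
    Each counted cell gets a one-sided hypergeometric over-representation
    p-value (universe = all genes carrying a peak unless given
    explicitly) and a BH-adjusted q across all tested cells.

    Returns a long-format frame with columns ``region_class,
    expr_group, count, class_size, group_size, universe, p, q``.
    """
    if isinstance(expr_groups, pd.Series):
        expr_groups = expr_groups.to_dict()
    if universe is None:
        universe_set = set()
        for gs in gene_sets.values():
            universe_set |= set(gs)
    else:
        universe_set = set(universe)
    N = len(universe_set)
    groups = sorted(set(expr_groups.values()))
    group_members = {
        g: {gene for gene, grp in expr_groups.items() if grp == g and gene in universe_set}
        for g in groups
    }

    rows = []
    for cls, genes in gene_sets.items():
        genes = set(genes) & universe_set
        n_cls = len(genes)
        unassigned = {g for g in genes if g not in expr_groups}
        for grp in groups:
            members = group_members[grp]
            k = len(genes & members)
            # P(X >= k) for X ~ Hypergeom(N, |group|, |class|)
            p = float(stats.hypergeom.sf(k - 1, N, len(members), n_cls)) if N else 1.0
            rows.append((cls, grp, k, n_cls, len(members), N, p))
        rows.append((cls, "unassigned", len(unassigned), n_cls, None, N, None))
    table = pd.DataFrame(
        rows,
        columns=["region_class", "expr_group", "count", "class_size", "group_size", "universe", "p"],
    )
    tested = table["p"].notna()
    q = pd.Series(np.nan, index=table.index, dtype=float)
    if tested.any():
        q[tested] = bh_adjust(table.loc[tested, "p"].to_numpy(dtype=float))
    table["q"] = q
    return table


def audit_trail(
    labels: Mapping[str, str] | pd.Series,
    annotation: pd.DataFrame,
    expr_groups: Mapping[str, str] | pd.Series,
) -> pd.DataFrame:
    """Row-per-link audit: region class -> peak -> gene -> expression group."""
    if isinstance(labels, pd.Series):
        labels = labels.to_dict()
    if isinstance(expr_groups, pd.Series):
        expr_groups = expr_groups.to_dict()
    rows = []
    for pid, gid in zip(annotation["peak_id"], annotation["gene_id"]):
        if gid is None or (isinstance(gid, float) and pd.isna(gid)):
            continue
        rows.append((labels.get(pid), pid, gid, expr_groups.get(gid, "unassigned")))
    return pd.DataFrame(rows, columns=["region_class", "peak_id", "gene_id", "expr_group"])
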