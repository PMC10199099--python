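"""Peak-to-gene context assignment and expression-group integration."""

import numpy as np
import pandas as pd
import pytest

from helpers_oracles import hypergeom_tail_oracle

from cadkit.annotate import (
    AnnotationConfig,
    assign_gene_context,
    audit_trail,
    genes_for_region_class,
    integrate_with_expression,
    promoter_window,
)
from cadkit.intervals import GeneModel, GenomicInterval, PeakSet


CFG = AnnotationConfig()  # +/- 2 kb promoter


def _context_oracle(peaks, genes, cfg):
    """Exhaustive window-overlap scan, independent of the implementation."""
    rows = []
    for chrom, s, e, pid in peaks:
        hit = False
        for g in genes:
            if g.chrom != chrom:
                continue
            if g.strand == "+":
                plo, phi = g.tss - cfg.promoter_upstream_bp, g.tss + cfg.promoter_downstream_bp
            else:
                plo = g.tss + 1 - cfg.promoter_downstream_bp
                phi = g.tss + 1 + cfg.promoter_upstream_bp
            plo = max(0, plo)
            in_prom = min(e, phi) - max(s, plo) >= 1
            in_body = min(e, g.end) - max(s, g.start) >= 1
            if in_prom:
                rows.append((pid, "promoter", g.gene_id))
                hit = True
            elif in_body:
                rows.append((pid, "gene_body", g.gene_id))
                hit = True
        if not hit:
            rows.append((pid, "intergenic", None))
    return sorted(rows, key=lambda r: (r[0], r[1], str(r[2])))


class TestAssignGeneContext:
    def test_peak_over_tss_is_promoter(self):
        ps = PeakSet([GenomicInterval("chr1", 4900, 5400, "p")])
        genes = [GeneModel("chr1", 5000, 20_000, "+", "g1")]
        out = assign_gene_context(ps, genes, CFG)
        assert out.iloc[0].tolist() == ["p", "promoter", "g1"]

    def test_peak_deep_in_gene_body(self):
        ps = PeakSet([GenomicInterval("chr1", 10_000, 10_500, "p")])
        genes = [GeneModel("chr1", 5000, 20_000, "+", "g1")]
        out = assign_gene_context(ps, genes, CFG)
        assert out.iloc[0]["context"] == "gene_body"

    def test_intergenic_peak(self):
        ps = PeakSet([GenomicInterval("chr1", 100_000, 100_500, "p")])
        genes = [GeneModel("chr1", 5000, 20_000, "+", "g1")]
        out = assign_gene_context(ps, genes, CFG)
        assert out.iloc[0]["context"] == "intergenic"
        assert pd.isna(out.iloc[0]["gene_id"])

    def test_peak_hits_multiple_genes(self):
        ps = PeakSet([GenomicInterval("chr1", 4000, 6000, "p")])
        genes = [
            GeneModel("chr1", 5000, 9000, "+", "g1"),
            GeneModel("chr1", 1000, 5500, "+", "g2"),
        ]
        out = assign_gene_context(ps, genes, CFG)
        assert set(out["gene_id"]) == {"g1", "g2"}

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        peaks = PeakSet(
            GenomicInterval("chr1", int(s), int(s) + 500, f"p{i:03d}")
            for i, s in enumerate(rng.integers(0, 200_000, size=100) )
        )
        genes = [
            GeneModel("chr1", int(s), int(s) + int(l), "+-"[int(st)], f"g{i:03d}")
            for i, (s, l, st) in enumerate(
                zip(
                    rng.integers(0, 200_000, size=20),
                    rng.integers(2000, 30_000, size=20),
                    rng.integers(0, 2, size=20),
                )
            )
        ]
        got = assign_gene_context(peaks, genes, CFG)
        got_rows = sorted(
            (
                (r.peak_id, r.context, None if pd.isna(r.gene_id) else r.gene_id)
                for r in got.itertuples()
            ),
            key=lambda r: (r[0], r[1], str(r[2])),
        )
        expect = _context_oracle(
            [(iv.chrom, iv.start, iv.end, iv.id) for iv in peaks], genes, CFG
        )
        assert got_rows == expect

    def test_strand_mirror_symmetry(self):
        """Mirroring the genome maps + promoters onto - promoters exactly."""
        L = 100_000
        cfg = AnnotationConfig(promoter_upstream_bp=2000, promoter_downstream_bp=500)
        plus = GeneModel("chr1", 40_000, 60_000, "+", "g")
        minus = GeneModel("chr1", L - 60_000, L - 40_000, "-", "g")
        plo, phi = promoter_window(plus, cfg)
        mlo, mhi = promoter_window(minus, cfg)
        assert (mlo, mhi) == (L - phi, L - plo)


class TestGenesForRegionClass:
    def test_shared_gene_counted_once(self):
        ann = pd.DataFrame(
            {"peak_id": ["p1", "p2"], "context": ["promoter"] * 2, "gene_id": ["g1", "g1"]}
        )
        sets = genes_for_region_class({"p1": "OC1", "p2": "OC1"}, ann)
        assert sets == {"OC1": {"g1"}}

    def test_intergenic_only_class_is_empty(self):
        ann = pd.DataFrame(
            {"peak_id": ["p1"], "context": ["intergenic"], "gene_id": [None]}
        )
        sets = genes_for_region_class({"p1": "CO2"}, ann)
        assert sets == {"CO2": set()}

    def test_matches_set_union_oracle(self):
        rng = np.random.default_rng(3)
        peaks = [f"p{i}" for i in range(50)]
        labels = {p: f"class{rng.integers(0, 3)}" for p in peaks}
        rows = [
            (p, "promoter", f"g{rng.integers(0, 20)}")
            for p in peaks
            for _ in range(rng.integers(0, 3))
        ]
        ann = pd.DataFrame(rows, columns=["peak_id", "context", "gene_id"])
        got = genes_for_region_class(labels, ann)
        expect = {}
        for p, _, g in rows:
            expect.setdefault(labels[p], set()).add(g)
        for cls in set(labels.values()):
            expect.setdefault(cls, set())
        assert got == expect

    def test_unknown_peak_id_rejected(self):
        ann = pd.DataFrame(
            {"peak_id": ["ghost"], "context": ["promoter"], "gene_id": ["g1"]}
        )
        with pytest.raises(KeyError):
            genes_for_region_class({"p1": "OC1"}, ann)


class TestIntegration:
    def test_all_genes_in_one_group(self):
        table = integrate_with_expression(
            {"increased": {"g1", "g2", "g3"}},
            {"g1": "G3", "g2": "G3", "g3": "G3"},
            universe={"g1", "g2", "g3", "g4", "g5"},
        )
        counted = table[table["expr_group"] == "G3"]
        assert counted["count"].tolist() == [3]
        other = table[(table["expr_group"] != "G3") & (table["expr_group"] != "unassigned")]
        assert (other["count"] == 0).all()

    def test_hypergeometric_matches_tail_sum(self):
        """10 class genes, 6 in a 50-gene group, universe 200."""
        universe = [f"g{i}" for i in range(200)]
        group = {g: "G1" for g in universe[:50]}
        class_genes = set(universe[44:50]) | set(universe[150:154])  # 6 in group
        table = integrate_with_expression({"cls": class_genes}, group, universe)
        p = table[table["expr_group"] == "G1"]["p"].iat[0]
        assert p == pytest.approx(hypergeom_tail_oracle(6, 200, 50, 10), rel=1e-9)

    def test_null_assignment_rarely_significant(self):
        """Independent random group labels: BH-significant cells are rare."""
        flagged = 0
        n_rep = 60
        for rep in range(n_rep):
            rng = np.random.default_rng(500 + rep)
            genes = [f"g{i}" for i in range(1000)]
            groups = {g: f"G{rng.integers(1, 7)}" for g in genes}
            class_genes = set(rng.choice(genes, size=100, replace=False))
            table = integrate_with_expression({"cls": class_genes}, groups, genes)
            q = table["q"].dropna()
            if (q < 0.05).any():
                flagged += 1
        assert flagged / n_rep <= 0.05 + 0.07  # binomial slack at n=60

    def test_audit_trail_links_every_counted_gene(self):
        ann = pd.DataFrame(
            {
                "peak_id": ["p1", "p2", "p3"],
                "context": ["promoter", "gene_body", "intergenic"],
                "gene_id": ["g1", "g2", None],
            }
        )
        labels = {"p1": "OC1", "p2": "OC1", "p3": "CO2"}
        trail = audit_trail(labels, ann, {"g1": "G1"})
        assert len(trail) == 2
        assert trail.loc[trail["gene_id"] == "g2", "expr_group"].iat[0] == "unassigned"
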