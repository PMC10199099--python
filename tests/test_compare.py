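"""Overlap fractions, Venn counts, M-A density classification, BH."""

import numpy as np
import pytest

from helpers_oracles import bh_oracle, intersect_oracle_all_pairs

from cadkit.compare import (
    CompareConfig,
    bh_adjust,
    classify_density,
    ma_fit,
    ma_values,
    overlap_fraction,
    venn_counts,
)
from cadkit.intervals import GenomicInterval, PeakSet, merge_intervals
from conftest import random_intervals


class TestOverlapFraction:
    def test_identity_is_100(self):
        rng = np.random.default_rng(0)
        a = PeakSet(random_intervals(rng, 10))
        assert overlap_fraction(a, a) == 100.0

    def test_disjoint_is_0(self):
        a = PeakSet([GenomicInterval("chr1", 0, 10, "a")])
        b = PeakSet([GenomicInterval("chr1", 100, 110, "b")])
        assert overlap_fraction(a, b) == 0.0

    def test_one_of_four(self):
        a = PeakSet(
            [GenomicInterval("chr1", i * 1000, i * 1000 + 100, f"a{i}") for i in range(4)]
        )
        b = PeakSet([GenomicInterval("chr1", 50, 60, "b")])
        assert overlap_fraction(a, b) == 25.0

    def test_empty_query_rejected(self):
        b = PeakSet([GenomicInterval("chr1", 0, 10, "b")])
        with pytest.raises(ValueError):
            overlap_fraction(PeakSet([]), b)


class TestVennCounts:
    def test_identical_pair_all_both(self):
        rng = np.random.default_rng(1)
        a = PeakSet(random_intervals(rng, 20, prefix="a"))
        b = a.subset(a.ids)
        counts = venn_counts({"A": a, "B": b})
        assert counts[(True, True)] == len(merge_intervals(a))
        assert counts[(True, False)] == 0
        assert counts[(False, True)] == 0

    def test_disjoint_pair_no_both(self):
        a = PeakSet([GenomicInterval("chr1", 0, 10, "a")])
        b = PeakSet([GenomicInterval("chr1", 100, 110, "b")])
        counts = venn_counts({"A": a, "B": b})
        assert counts[(True, True)] == 0
        assert counts.sum() == 2

    @pytest.mark.parametrize("seed", range(3))
    def test_three_sets_match_membership_oracle(self, seed):
        rng = np.random.default_rng(seed)
        sets = {
            name: PeakSet(random_intervals(rng, 30, prefix=name))
            for name in ("A", "B", "C")
        }
        counts = venn_counts(sets)
        pooled = [iv for s in sets.values() for iv in s]
        universe = merge_intervals(
            PeakSet(
                GenomicInterval(iv.chrom, iv.start, iv.end, f"u{i}")
                for i, iv in enumerate(pooled)
            )
        )
        assert counts.sum() == len(universe)
        # per-interval membership via the brute-force overlap oracle
        uni = [(iv.chrom, iv.start, iv.end, iv.id) for iv in universe]
        member = {}
        for name, s in sets.items():
            hits = intersect_oracle_all_pairs(
                uni, [(iv.chrom, iv.start, iv.end, iv.id) for iv in s]
            )
            member[name] = {uid: bool(v) for uid, v in hits.items()}
        for pattern, n in counts.items():
            expect = sum(
                1
                for uid, *_ in [(iv.id,) for iv in universe]
                if tuple(member[name][uid] for name in sets) == pattern
            )
            assert n == expect

    def test_more_than_three_sets_unsupported(self):
        rng = np.random.default_rng(2)
        sets = [PeakSet(random_intervals(rng, 5, prefix=f"s{i}")) for i in range(4)]
        with pytest.raises(ValueError):
            venn_counts(sets)


class TestMaFit:
    def test_symmetric_data_fits_zero_line(self):
        rng = np.random.default_rng(3)
        x = rng.gamma(2.0, 50.0, 200)
        a, b = ma_fit(x, x.copy())
        assert abs(a) < 1e-6 and abs(b) < 1e-6

    def test_global_scaling_absorbed(self):
        # counts large enough that the pseudocount is negligible
        rng = np.random.default_rng(4)
        x = rng.uniform(50.0, 1000.0, 200)
        y = 4.0 * x
        a, b = ma_fit(x, y)
        M, A = ma_values(x, y)
        rescaled = M - (a + b * A)
        assert np.abs(rescaled).max() < 0.05

    def test_recovers_planted_line(self):
        rng = np.random.default_rng(5)
        A = rng.uniform(4, 10, 500)
        M = 0.7 + 0.3 * A + rng.normal(0, 0.05, 500)
        c = 0.5
        x = np.exp2(A + M / 2) - c
        y = np.exp2(A - M / 2) - c
        a, b = ma_fit(x, y, pseudocount=c)
        assert a == pytest.approx(0.7, abs=0.05)
        assert b == pytest.approx(0.3, abs=0.05)

    def test_degenerate_a_variance_rejected(self):
        x = np.full(20, 100.0)
        with pytest.raises(ValueError, match="degenerate"):
            ma_fit(x, x)

    def test_too_few_regions_rejected(self):
        with pytest.raises(ValueError):
            ma_fit(np.arange(5.0), np.arange(5.0))


class TestClassifyDensity:
    def test_equal_signals_all_no_change(self):
        rng = np.random.default_rng(6)
        x = rng.gamma(2.0, 50.0, 100)
        ids = [f"r{i}" for i in range(100)]
        res = classify_density(ids, x, x.copy())
        assert (res["class"] == "no_change").all()

    def test_null_calibration(self):
        """Equal-mean Poisson pairs: non-no_change calls stay below 2 x p_cutoff."""
        rng = np.random.default_rng(7)
        lam = rng.gamma(2.0, 50.0, 5000)
        x = rng.poisson(lam).astype(float)
        y = rng.poisson(lam).astype(float)
        ids = [f"r{i}" for i in range(5000)]
        res = classify_density(ids, x, y)
        assert (res["class"] != "no_change").mean() <= 2 * CompareConfig().p_cutoff

    def test_planted_fourfold_recovered(self):
        rng = np.random.default_rng(8)
        n = 2000
        lam = rng.gamma(2.0, 50.0, n)
        planted = np.zeros(n, dtype=bool)
        planted[rng.choice(n, size=n // 10, replace=False)] = True
        x = rng.poisson(np.where(planted, 4.0 * lam, lam)).astype(float)
        y = rng.poisson(lam).astype(float)
        res = classify_density([f"r{i}" for i in range(n)], x, y)
        called = (res["class"] == "increased").values
        assert (called & planted).sum() / planted.sum() >= 0.90
        assert (called & ~planted).sum() / (~planted).sum() <= 0.01

    def test_invariant_to_global_y_rescaling(self):
        rng = np.random.default_rng(9)
        lam = rng.gamma(2.0, 80.0, 1000)
        x = rng.poisson(lam).astype(float)
        y = rng.poisson(lam).astype(float)
        ids = [f"r{i}" for i in range(1000)]
        base = classify_density(ids, x, y)
        scaled = classify_density(ids, x, y * 8.0)
        agree = (base["class"].values == scaled["class"].values).mean()
        assert agree >= 0.995

    def test_all_zero_region_is_no_change(self):
        rng = np.random.default_rng(10)
        x = np.append(rng.gamma(2.0, 50.0, 50), 0.0)
        y = np.append(rng.gamma(2.0, 50.0, 50), 0.0)
        res = classify_density([f"r{i}" for i in range(51)], x, y)
        assert res.iloc[-1]["class"] == "no_change"
        assert res.iloc[-1]["p"] == 1.0


class TestBhAdjust:
    def test_stepup_hand_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_textbook_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(int(rng.integers(1, 9)))
        assert np.allclose(bh_adjust(p), bh_oracle(p))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
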