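"""Zone detection rules, group statistics, and brood-viability arithmetic."""

import math

import numpy as np
import pytest

from gonadfoci.core import NucleusROI
from gonadfoci.synth import generate_row_flags, generate_staging_counts
from gonadfoci.zones import (
    assign_rows,
    boundary_by_count_rule,
    brood_viability,
    compare_groups,
    majority_zone,
    peak_window,
)


def square_roi(rid, cx, cy=5.0, half=2.0):
    return NucleusROI(id=rid, polygon=[[cx - half, cy - half], [cx + half, cy - half],
                                       [cx + half, cy + half], [cx - half, cy + half]])


class TestAssignRows:
    def test_explicit_pitch(self):
        rois = [square_roi(f"n{i}", x) for i, x in enumerate([5, 15, 25])]
        assign_rows(rois, row_pitch=10)
        assert [r.row_index for r in rois] == [0, 1, 2]

    def test_all_equal_centroids(self):
        rois = [square_roi(f"n{i}", 7.0) for i in range(4)]
        assign_rows(rois, row_pitch=10)
        assert all(r.row_index == 0 for r in rois)

    def test_default_pitch_from_median_spacing(self):
        rois = [square_roi(f"n{i}", 10.0 * i) for i in range(6)]
        assign_rows(rois)
        assert [r.row_index for r in rois] == list(range(6))

    def test_scene_rows_match_ground_truth(self, demo_scene):
        spec, (stack, rois, truth) = demo_scene
        assign_rows(rois)
        for r in rois:
            assert r.row_index == truth.row_index[r.id]


def brute_force_longest_run(row_flags):
    """Exhaustive scan over all contiguous runs of positive rows."""
    rows = sorted(row_flags)
    best = None
    for i, a in enumerate(rows):
        for b in rows[i:]:
            if all(row_flags.get(r, False) for r in range(a, b + 1)):
                if best is None or (b - a) > (best[1] - best[0]):
                    best = (a, b)
    return best


class TestMajorityZone:
    def test_simple_block(self):
        rows, flags = [], []
        for r in range(15):
            for _ in range(4):
                rows.append(r)
                flags.append(3 <= r <= 10)
        z = majority_zone(flags, rows)
        assert (z.start_row, z.end_row, z.length_rows) == (3, 10, 8)

    def test_no_positive_rows(self):
        z = majority_zone([False] * 10, list(range(10)))
        assert z.length_rows == 0

    def test_strict_majority(self):
        # exactly 50% flagged is NOT a majority
        rows = [0, 0, 0, 0]
        z = majority_zone([True, True, False, False], rows)
        assert z.length_rows == 0

    def test_matches_exhaustive_oracle(self):
        """Random layouts vs brute-force run enumeration."""
        rng = np.random.default_rng(31)
        for trial in range(100):
            n_rows = int(rng.integers(3, 30))
            per_row = int(rng.integers(1, 6))
            rows, flags = [], []
            row_flags = {}
            for r in range(n_rows):
                f = rng.uniform(size=per_row) > 0.5
                rows.extend([r] * per_row)
                flags.extend(bool(v) for v in f)
                row_flags[r] = f.sum() > 0.5 * per_row
            z = majority_zone(flags, rows)
            expected = brute_force_longest_run(row_flags)
            if expected is None:
                assert z.length_rows == 0
            else:
                assert (z.start_row, z.end_row) == expected

    def test_synthetic_flags_recover_zone(self):
        rows, flags = generate_row_flags(30, 10, zone=(8, 19), seed=5)
        z = majority_zone(flags, rows)
        assert (z.start_row, z.end_row) == (8, 19)


class TestBoundaryByCountRule:
    def test_direct_rule_application(self):
        rows, rad51, msh5 = generate_staging_counts(25, 10, start_row=4, end_row=12, seed=2)
        z = boundary_by_count_rule(
            rad51, msh5, rows,
            start_predicate=lambda c: c >= 1,
            end_predicate=lambda c: c == 6,
        )
        assert (z.start_row, z.end_row) == (4, 12)
        assert z.start_row <= z.end_row

    def test_end_rule_unmet(self):
        rows = [0, 0, 1, 1]
        with pytest.raises(ValueError, match="end rule unmet"):
            boundary_by_count_rule(
                [1, 1, 1, 1], [0, 0, 0, 0], rows,
                start_predicate=lambda c: c >= 1,
                end_predicate=lambda c: c == 6,
            )

    def test_start_rule_unmet(self):
        with pytest.raises(ValueError, match="start rule unmet"):
            boundary_by_count_rule(
                [0, 0], [6, 6], [0, 1],
                start_predicate=lambda c: c >= 1,
                end_predicate=lambda c: c == 6,
            )


def brute_force_best_window(by_row, width):
    lo, hi = min(by_row), max(by_row)
    best, best_med = None, -math.inf
    for s in range(lo, hi - width + 2):
        vals = [v for r in range(s, s + width) for v in by_row.get(r, [])]
        if vals:
            med = float(np.median(vals))
            if med > best_med:
                best, best_med = s, med
    return best


class TestPeakWindow:
    def test_constant_counts_tie_to_earliest(self):
        rows = [r for r in range(20) for _ in range(3)]
        counts = [5.0] * len(rows)
        z = peak_window(counts, rows, width_rows=10)
        assert (z.start_row, z.end_row) == (0, 9)

    def test_width_equal_total(self):
        rows = [r for r in range(10) for _ in range(2)]
        counts = list(range(20))
        z = peak_window(counts, rows, width_rows=10)
        assert (z.start_row, z.end_row) == (0, 9)

    def test_too_few_rows(self):
        with pytest.raises(ValueError):
            peak_window([1, 2], [0, 1], width_rows=10)

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(13)
        for trial in range(100):
            n_rows = int(rng.integers(12, 40))
            per_row = int(rng.integers(1, 5))
            width = int(rng.integers(2, 11))
            rows = [r for r in range(n_rows) for _ in range(per_row)]
            counts = [float(v) for v in rng.integers(0, 40, size=len(rows))]
            by_row = {}
            for r, c in zip(rows, counts):
                by_row.setdefault(r, []).append(c)
            z = peak_window(counts, rows, width_rows=width)
            assert z.start_row == brute_force_best_window(by_row, width)

    def test_rising_falling_profile(self):
        # counts rise to row 17 then crash: the maximal-median width-10
        # window is (8, 17), reached first among ties
        rows, counts = [], []
        for r in range(25):
            level = float(r) if r <= 17 else 0.0
            for _ in range(4):
                rows.append(r)
                counts.append(level)
        z = peak_window(counts, rows, width_rows=10)
        assert (z.start_row, z.end_row) == (8, 17)


def fisher_exact_oracle(table):
    """Two-sided Fisher p by direct hypergeometric enumeration."""
    a, b = table[0]
    c, d = table[1]
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def pmf(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = pmf(a)
    return sum(pmf(x) for x in range(max(0, c1 - r2), min(r1, c1) + 1)
               if pmf(x) <= p_obs * (1 + 1e-9))


class TestCompareGroups:
    def test_identical_groups_mann_whitney(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = compare_groups(x, x, test="mann-whitney")
        assert res.p_value == pytest.approx(1.0, abs=0.05)

    def test_welch_t_runs(self):
        rng = np.random.default_rng(0)
        res = compare_groups(rng.normal(0, 1, 30), rng.normal(2, 1, 30), test="welch-t")
        assert res.p_value < 1e-6

    def test_fisher_matches_enumeration_oracle(self):
        for table in ([[5, 0], [0, 5]], [[10, 10], [10, 10]], [[3, 7], [8, 2]], [[1, 9], [5, 5]]):
            res = compare_groups(np.array(table), test="fisher-exact")
            assert res.p_value == pytest.approx(fisher_exact_oracle(table), rel=1e-9)

    def test_empty_group(self):
        with pytest.raises(ValueError):
            compare_groups([], [1.0], test="mann-whitney")


class TestBroodViability:
    def test_formula_application(self):
        bv = brood_viability(100, 100, 5, 90, 0)
        assert bv.total_eggs == 100
        assert bv.pct_hatching == pytest.approx(95.0)
        assert bv.pct_adulthood == pytest.approx(90.0)
        assert bv.pct_males == 0.0

    def test_whichever_is_larger_rule(self):
        bv = brood_viability(100, 95, 0, 120, 6)
        assert bv.total_eggs == 120
        assert bv.pct_males == pytest.approx(5.0)

    def test_all_unhatched(self):
        bv = brood_viability(50, 50, 50, 0, 0)
        assert bv.pct_hatching == 0.0

    def test_bounds(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            e1, e2 = rng.integers(1, 200, size=2)
            total = max(e1, e2)
            unh = int(rng.integers(0, total + 1))
            adults = int(rng.integers(0, total + 1))
            males = int(rng.integers(0, adults + 1)) if adults else 0
            bv = brood_viability(int(e1), int(e2), unh, adults, males)
            assert 0 <= bv.pct_hatching <= 100
            assert 0 <= bv.pct_adulthood <= 100
            if adults:
                assert 0 <= bv.pct_males <= 100
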