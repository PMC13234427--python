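"""Dice/Hausdorff/area metrics and the slice-decision classifier."""

import numpy as np
import pytest
from scipy.spatial import ConvexHull
from scipy.spatial.distance import cdist
from shapely.geometry import Polygon

from saxcompare.segmetrics import (area_differences, classify_slices,
                                   decision_rates, dice, hausdorff,
                                   hausdorff_points, stratum_summary)
from saxcompare.core import geometry_boundary_points

from conftest import circle_ring, make_case


class TestDice:
    def test_identity_disjoint_offset(self):
        sq = Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])
        off = Polygon([(0.5, 0), (1.5, 0), (1.5, 1), (0.5, 1)])
        far = Polygon([(5, 5), (6, 5), (6, 6), (5, 6)])
        assert dice(sq, sq) == pytest.approx(1.0)
        assert dice(sq, far) == pytest.approx(0.0)
        assert dice(sq, off) == pytest.approx(0.5)

    def test_both_empty_undefined(self):
        assert dice(Polygon(), Polygon()) is None

    def test_symmetric(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            pts = rng.uniform(0, 5, (10, 2))
            a = Polygon(pts[ConvexHull(pts).vertices])
            pts2 = pts + rng.uniform(-1, 1, 2)
            b = Polygon(pts2[ConvexHull(pts2).vertices])
            assert dice(a, b) == pytest.approx(dice(b, a), abs=1e-12)


class TestHausdorff:
    def test_identical_zero(self):
        c = Polygon(circle_ring(0, 0, 10, 180))
        assert hausdorff(c, c) == 0.0

    def test_concentric_circles(self):
        a = Polygon(circle_ring(0, 0, 10, 720))
        b = Polygon(circle_ring(0, 0, 12, 720))
        assert hausdorff(a, b, max_arc=0.1) == pytest.approx(2.0, abs=0.1)

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            pts = rng.uniform(0, 20, (8, 2))
            a = Polygon(pts[ConvexHull(pts).vertices])
            pts2 = rng.uniform(0, 20, (8, 2))
            b = Polygon(pts2[ConvexHull(pts2).vertices])
            pa = geometry_boundary_points(a, 0.5)
            pb = geometry_boundary_points(b, 0.5)
            d = cdist(pa, pb)
            brute = max(d.min(axis=1).max(), d.min(axis=0).max())
            assert hausdorff_points(pa, pb) == pytest.approx(brute, abs=1e-9)

    def test_symmetric(self):
        a = Polygon(circle_ring(0, 0, 10, 90))
        b = Polygon(circle_ring(3, 1, 7, 90))
        assert hausdorff(a, b, 0.2) == pytest.approx(hausdorff(b, a, 0.2), abs=1e-12)


class TestAreaDifferences:
    def test_basic_and_one_sided(self):
        assert area_differences(2000.0, 2200.0) == (pytest.approx(2.0), pytest.approx(10.0))
        abs_d, rel_d = area_differences(None, 500.0)
        assert abs_d == pytest.approx(5.0) and rel_d is None
        abs_d, rel_d = area_differences(500.0, None)
        assert abs_d == pytest.approx(-5.0) and rel_d == pytest.approx(-100.0)

    def test_both_absent_rejected(self):
        with pytest.raises(ValueError):
            area_differences(None, None)

    def test_equal_areas_different_shapes_zero_diff_but_dice_below_one(self):
        a = Polygon([(0, 0), (2, 0), (2, 1), (0, 1)])
        b = Polygon([(0, 0), (1, 0), (1, 2), (0, 2)])
        abs_d, rel_d = area_differences(a.area, b.area)
        assert abs_d == 0.0 and rel_d == 0.0
        assert dice(a, b) < 1.0


class TestClassifySlices:
    def _pair(self, expert_range, ai_range):
        e = make_case("c1", "expert", expert_range)
        a = make_case("c1", "ai", ai_range)
        return classify_slices(e, a, "lv_endo", "ED", with_metrics=False)

    def test_basal_false_positive(self):
        comps = self._pair(range(3, 9), range(2, 9))
        by = {(c.slice_index): c for c in comps}
        assert by[2].decision == "false_positive"
        assert by[2].stratum == "basal" and by[2].position == "out_of_scope"
        assert sum(c.decision == "both_present" for c in comps) == 6

    def test_basal_false_negative(self):
        comps = self._pair(range(3, 9), range(4, 9))
        by = {c.slice_index: c for c in comps}
        assert by[3].decision == "false_negative" and by[3].stratum == "basal"

    def test_apical_false_negative(self):
        comps = self._pair(range(3, 9), range(3, 8))
        by = {c.slice_index: c for c in comps}
        assert by[8].decision == "false_negative" and by[8].stratum == "apical"

    def test_positions_follow_expert_range(self):
        comps = self._pair(range(3, 9), range(3, 9))
        pos = {c.slice_index: c.position for c in comps}
        assert pos[3] == "basal" and pos[8] == "apical"
        assert all(pos[i] == "midventricular" for i in range(4, 8))

    def test_single_slice_expert_basal_takes_precedence(self):
        comps = self._pair([5], [5])
        assert len(comps) == 1 and comps[0].position == "basal"

    def test_expert_empty_stratum_excluded(self):
        e = make_case("c1", "expert", [])
        a = make_case("c1", "ai", [3, 4])
        assert classify_slices(e, a, "lv_endo", "ED") == []

    def test_metrics_only_when_both_present(self):
        e = make_case("c1", "expert", range(3, 6))
        a = make_case("c1", "ai", range(4, 6))
        comps = classify_slices(e, a, "lv_endo", "ED", with_metrics=True)
        for c in comps:
            if c.decision == "both_present":
                assert c.dice is not None and c.hd is not None
            else:
                assert c.dice is None and c.hd is None
                assert c.area_diff_abs is not None


class TestDecisionRates:
    def test_constructed_fp_rate(self):
        comps = []
        for i in range(10):
            e = make_case(f"c{i}", "expert", range(3, 9))
            ai_range = range(2, 9) if i < 3 else range(3, 9)
            a = make_case(f"c{i}", "ai", ai_range)
            comps += classify_slices(e, a, "rv_endo", "ED", with_metrics=False)
        rates = decision_rates(comps)
        assert rates["basal"]["fp_rate"] == pytest.approx(30.0)
        assert rates["basal"]["fn_rate"] == pytest.approx(0.0)

    def test_identical_readers_all_zero(self):
        comps = []
        for i in range(5):
            e = make_case(f"c{i}", "expert", range(3, 9))
            comps += classify_slices(e, make_case(f"c{i}", "ai", range(3, 9)),
                                     "lv_endo", "ED", with_metrics=False)
        rates = decision_rates(comps)
        for stratum in rates.values():
            assert stratum["fp_rate"] == 0.0 and stratum["fn_rate"] == 0.0

    def test_midventricular_fn_denominator_is_in_range_slices(self):
        e = make_case("c0", "expert", range(0, 10))
        a = make_case("c0", "ai", [0, 1, 2, 3, 9])  # misses 4..8 (midventricular)
        comps = classify_slices(e, a, "lv_endo", "ED", with_metrics=False)
        rates = decision_rates(comps)
        assert rates["midventricular"]["fn_rate"] == pytest.approx(100 * 5 / 8)


class TestAggregation:
    def test_slice_vs_case_weighting_regression(self):
        # case A: 2 midventricular slices, case B: 1; identical geometry per
        # case but different contour radius, so Dice against a common AI differs
        eA = make_case("A", "expert", range(0, 4), radius=20)
        aA = make_case("A", "ai", range(0, 4), radius=18)
        eB = make_case("B", "expert", range(0, 3), radius=20)
        aB = make_case("B", "ai", range(0, 3), radius=20)
        comps = (classify_slices(eA, aA, "lv_endo", "ED")
                 + classify_slices(eB, aB, "lv_endo", "ED"))
        slice_w = stratum_summary(comps, per_case_first=False)
        case_w = stratum_summary(comps, per_case_first=True)
        mid_slice = slice_w.query("position == 'midventricular'")["dice_pct"].iloc[0]
        mid_case = case_w.query("position == 'midventricular'")["dice_pct"].iloc[0]
        d_imperfect = comps[1].dice * 100  # any case-A midventricular slice
        # slice weighting: 2 imperfect + 1 perfect; case weighting: mean of the two
        assert mid_slice == pytest.approx((2 * d_imperfect + 100) / 3)
        assert mid_case == pytest.approx((d_imperfect + 100) / 2)
        assert mid_case > mid_slice
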