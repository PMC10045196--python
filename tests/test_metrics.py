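"""Hungarian point matching, F1 aggregation, and the tolerance sweep."""

from itertools import permutations

import numpy as np
import pytest

from centriodet.metrics import (evaluate_nuclei, f1_vs_tolerance, match_points,
                                pair_tolerance_px, summarize_reports)
from centriodet.nuclei import NucleiLabels


def brute_force_tp(pred, truth, tolerance):
    """Best achievable true-positive count over all unique assignments:
    enumerate every injective map from the smaller point set."""
    pred, truth = np.asarray(pred, float), np.asarray(truth, float)
    if len(pred) > len(truth):
        pred, truth = truth, pred
    n, m = len(pred), len(truth)
    if n == 0:
        return 0
    best = 0
    for perm in permutations(range(m), n):
        tp = sum(np.hypot(*(pred[i] - truth[j])) <= tolerance
                 for i, j in enumerate(perm))
        best = max(best, tp)
    return best


class TestMatchPoints:
    def test_identical_lists_are_perfect(self, rng):
        pts = rng.uniform(0, 100, size=(9, 2))
        rep = match_points(pts, pts, tolerance=3)
        assert (rep.tp, rep.fp, rep.fn) == (9, 0, 0)
        assert rep.f1 == 1.0

    def test_tolerance_is_inclusive_boundary(self):
        rep = match_points([(0, 0)], [(0, 2.9)], tolerance=3)
        assert rep.tp == 1
        rep = match_points([(0, 0)], [(0, 3.1)], tolerance=3)
        assert (rep.tp, rep.fp, rep.fn) == (0, 1, 1)
        rep = match_points([(0, 0)], [(0, 3.0)], tolerance=3)
        assert rep.tp == 1  # "~300 nm apart" pairs land exactly on 3 px

    def test_both_empty_scores_one(self):
        rep = match_points(np.empty((0, 2)), np.empty((0, 2)), tolerance=3)
        assert rep.precision == rep.recall == rep.f1 == 1.0

    def test_one_side_empty_scores_zero(self):
        assert match_points(np.empty((0, 2)), [(1, 1)], tolerance=3).f1 == 0.0
        assert match_points([(1, 1)], np.empty((0, 2)), tolerance=3).f1 == 0.0

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            match_points([(0, 0)], [(0, 0)], tolerance=-1)

    @pytest.mark.parametrize("seed", range(20))
    def test_equals_exhaustive_permutation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, m = rng.integers(1, 7, size=2)
        pred = rng.uniform(0, 12, size=(n, 2))
        truth = rng.uniform(0, 12, size=(m, 2))
        rep = match_points(pred, truth, tolerance=3)
        assert rep.tp == brute_force_tp(pred, truth, 3)

    def test_duplicate_predictions_yield_one_tp(self):
        rep = match_points([(5, 5), (5.1, 5), (4.9, 5)], [(5, 5)], tolerance=3)
        assert (rep.tp, rep.fp, rep.fn) == (1, 2, 0)

    def test_swap_symmetry(self, rng):
        pred = rng.uniform(0, 30, size=(7, 2))
        truth = rng.uniform(0, 30, size=(5, 2))
        a = match_points(pred, truth, tolerance=4)
        b = match_points(truth, pred, tolerance=4)
        assert a.tp == b.tp
        assert a.precision == pytest.approx(b.recall)
        assert a.recall == pytest.approx(b.precision)
        assert a.f1 == pytest.approx(b.f1)

    def test_saturation_prefers_valid_pair(self):
        """A valid close pair must never be traded to shorten two
        above-tolerance distances."""
        pred = [(0.0, 0.0)]
        truth = [(0.0, 1.0), (0.0, 50.0)]
        rep = match_points(pred, truth, tolerance=3)
        assert rep.tp == 1 and rep.pairs[0][1] == 0


class TestToleranceSweep:
    def test_perfect_curve_is_flat_one(self, rng):
        pts = rng.uniform(0, 50, size=(6, 2))
        curve = f1_vs_tolerance(pts, pts)
        assert list(curve.values()) == [1.0] * 6

    def test_constant_offset_steps_at_the_offset(self):
        truth = np.array([(10.0, 10.0), (30.0, 30.0), (10.0, 40.0)])
        pred = truth + (0.0, 2.0)
        curve = f1_vs_tolerance(pred, truth)
        assert curve[0.0] == 0.0 and curve[1.0] == 0.0
        assert curve[2.0] == 1.0 and curve[5.0] == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_monotone_non_decreasing(self, seed):
        rng = np.random.default_rng(seed)
        pred = rng.uniform(0, 20, size=(rng.integers(0, 10), 2))
        truth = rng.uniform(0, 20, size=(rng.integers(1, 10), 2))
        vals = list(f1_vs_tolerance(pred, truth).values())
        assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))

    def test_consistent_with_match_points(self, rng):
        pred = rng.uniform(0, 20, size=(5, 2))
        truth = rng.uniform(0, 20, size=(6, 2))
        curve = f1_vs_tolerance(pred, truth)
        for tol, f1 in curve.items():
            assert f1 == match_points(pred, truth, tolerance=tol).f1


class TestAggregation:
    def test_mean_and_sample_sd_hand_example(self):
        reports = {
            "a": match_points([(0, 0)], [(0, 0)], 3),          # f1 = 1.0
            "b": match_points([(0, 0), (9, 9)], [(0, 0), (50, 50)], 3),  # f1 = 0.5
        }
        s = summarize_reports(reports, tolerance=3)
        assert s.f1_mean == pytest.approx(0.75)
        assert s.f1_sd == pytest.approx(0.353553, abs=1e-5)

    def test_single_field_sd_is_zero(self):
        s = summarize_reports({"a": match_points([(1, 1)], [(1, 1)], 3)}, 3)
        assert (s.f1_mean, s.f1_sd) == (1.0, 0.0)

    def test_pooled_mode_pools_counts(self):
        reports = {
            "a": match_points([(0, 0)], [(0, 0), (30, 30)], 3),  # tp1 fn1
            "b": match_points([(0, 0), (9, 9)], [(0, 0)], 3),    # tp1 fp1
        }
        s = summarize_reports(reports, 3, pooled=True)
        assert s.pooled["precision"] == pytest.approx(2 / 3)
        assert s.pooled["recall"] == pytest.approx(2 / 3)


class TestNucleusEvaluation:
    @staticmethod
    def _labels(centres, side=256, radius=8):
        grid = np.zeros((side, side), np.int32)
        for i, (r, c) in enumerate(centres, start=1):
            yy, xx = np.mgrid[0:side, 0:side]
            grid[(yy - r) ** 2 + (xx - c) ** 2 <= radius ** 2] = i
        return NucleiLabels.from_labels(grid)

    def test_identical_masks_are_perfect(self):
        lab = self._labels([(50, 50), (150, 150)])
        assert evaluate_nuclei(lab, lab).f1 == 1.0

    def test_forty_px_shift_matches_at_fifty(self):
        truth = self._labels([(100, 100)])
        pred = self._labels([(100, 140)])
        assert evaluate_nuclei(pred, truth, tolerance=50).tp == 1
        assert evaluate_nuclei(pred, truth, tolerance=30).tp == 0

    def test_random_layouts_match_permutation_oracle(self, rng):
        truth_pts = rng.uniform(20, 230, size=(4, 2))
        pred_pts = truth_pts + rng.normal(0, 25, size=(4, 2))
        truth = self._labels([tuple(p) for p in truth_pts])
        pred = self._labels([tuple(p) for p in np.clip(pred_pts, 10, 245)])
        rep = evaluate_nuclei(pred, truth, tolerance=50)
        oracle = brute_force_tp(pred.centroids(), truth.centroids(), 50)
        assert rep.tp == oracle


def test_pair_tolerance_is_three_pixels_at_default_pitch():
    assert pair_tolerance_px(102.5) == 3
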