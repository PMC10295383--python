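"""Evaluation stack: IoU, matching, PR curves, AP, stratification."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from flocksight.metrics import (
    BoundingBox,
    Detection,
    GroundTruth,
    InvalidBoxError,
    PRCurve,
    average_precision,
    iou,
    match_detections,
    mean_ap,
    pr_curve,
    recall_at_precision,
    size_partition,
)

B = BoundingBox


def det(x, y, w, h, score, frame=0):
    return Detection(B(x, y, w, h), score=score, frame_id=frame)


def gt(x, y, w, h, frame=0, crowd=False, gid=0):
    return GroundTruth(B(x, y, w, h), frame_id=frame, crowd=crowd, id=gid)


def rasterized_iou(a: BoundingBox, b: BoundingBox) -> float:
    """Independent pixel-grid oracle for integer boxes: count unit cells."""
    grid_a = {(i, j) for i in range(int(a.x), int(a.x + a.w))
              for j in range(int(a.y), int(a.y + a.h))}
    grid_b = {(i, j) for i in range(int(b.x), int(b.x + b.w))
              for j in range(int(b.y), int(b.y + b.h))}
    return len(grid_a & grid_b) / len(grid_a | grid_b)


class TestIoU:
    def test_identity(self):
        assert iou(B(0, 0, 2, 2), B(0, 0, 2, 2)) == 1.0

    def test_disjoint(self):
        assert iou(B(0, 0, 2, 2), B(10, 10, 2, 2)) == 0.0

    def test_partial_overlap_matches_rasterization(self):
        a, b = B(0, 0, 2, 2), B(1, 1, 2, 2)
        assert iou(a, b) == pytest.approx(1 / 7, abs=1e-12)
        assert iou(a, b) == pytest.approx(rasterized_iou(a, b), abs=1e-12)

    @given(st.integers(0, 30), st.integers(0, 30), st.integers(1, 15),
           st.integers(1, 15), st.integers(0, 30), st.integers(0, 30),
           st.integers(1, 15), st.integers(1, 15))
    def test_matches_rasterization_on_integer_boxes(self, ax, ay, aw, ah,
                                                    bx, by, bw, bh):
        a, b = B(ax, ay, aw, ah), B(bx, by, bw, bh)
        assert iou(a, b) == pytest.approx(rasterized_iou(a, b), abs=1e-12)

    @given(st.floats(0, 50), st.floats(0, 50), st.floats(0.5, 20),
           st.floats(0.5, 20), st.floats(0, 50), st.floats(0, 50),
           st.floats(0.5, 20), st.floats(0.5, 20))
    def test_symmetric_and_bounded(self, ax, ay, aw, ah, bx, by, bw, bh):
        a, b = B(ax, ay, aw, ah), B(bx, by, bw, bh)
        v = iou(a, b)
        assert v == iou(b, a)
        assert 0.0 <= v <= 1.0
        assert iou(a, a) == 1.0

    def test_invalid_box_rejected(self):
        with pytest.raises(InvalidBoxError):
            B(0, 0, 0, 2)
        with pytest.raises(InvalidBoxError):
            B(0, 0, 2, -1)
        with pytest.raises(InvalidBoxError):
            B(np.nan, 0, 2, 2)


class TestMatching:
    def test_exact_match(self):
        r = match_detections([det(0, 0, 10, 10, 0.9)], [gt(0, 0, 10, 10)], 0.5)
        assert (r.tp, r.fp, r.fn) == (1, 0, 0)

    def test_duplicate_detections_highest_score_wins(self):
        dets = [det(0, 0, 10, 10, 0.9), det(1, 0, 10, 10, 0.8)]
        r = match_detections(dets, [gt(0, 0, 10, 10, gid=7)], 0.5)
        assert (r.tp, r.fp, r.fn) == (1, 1, 0)
        assert r.assignment[0] == 7 and r.assignment[1] is None

    def test_no_detections(self):
        r = match_detections([], [gt(0, 0, 5, 5, gid=i) for i in range(3)], 0.5)
        assert (r.tp, r.fp, r.fn) == (0, 0, 3)

    def test_empty_gts_all_fp(self):
        r = match_detections([det(0, 0, 5, 5, 0.5)], [], 0.5)
        assert (r.tp, r.fp, r.fn) == (0, 1, 0)

    def test_crowd_region_ignores_detection(self):
        gts = [gt(0, 0, 20, 20, crowd=True, gid=1)]
        r = match_detections([det(1, 1, 20, 20, 0.9)], gts, 0.5)
        assert (r.tp, r.fp, r.fn) == (0, 0, 0)
        assert r.n_ignored == 1

    @given(st.lists(st.tuples(st.integers(0, 40), st.integers(0, 40),
                              st.integers(2, 15), st.integers(2, 15),
                              st.floats(0.01, 1.0)), max_size=8),
           st.lists(st.tuples(st.integers(0, 40), st.integers(0, 40),
                              st.integers(2, 15), st.integers(2, 15)),
                    max_size=6))
    def test_count_invariants(self, det_specs, gt_specs):
        dets = [det(x, y, w, h, round(s, 3)) for x, y, w, h, s in det_specs]
        gts = [gt(x, y, w, h, gid=i) for i, (x, y, w, h) in enumerate(gt_specs)]
        r = match_detections(dets, gts, 0.5)
        assert r.tp + r.fp == len(dets)
        assert r.tp + r.fn == len(gts)
        matched = [v for v in r.assignment.values() if v is not None]
        assert len(matched) == len(set(matched))  # one-to-one


class TestPRCurve:
    def test_single_true_positive(self):
        c = pr_curve([det(0, 0, 10, 10, 0.9)], [gt(0, 0, 10, 10)], 0.5)
        assert c.precision.tolist() == [1.0]
        assert c.recall.tolist() == [1.0]

    def test_hand_swept_three_point_curve(self):
        dets = [
            det(0, 0, 10, 10, 0.9),        # TP
            det(50, 50, 10, 10, 0.8),      # FP
            det(100, 100, 10, 10, 0.7),    # TP
        ]
        gts = [gt(0, 0, 10, 10, gid=1), gt(100, 100, 10, 10, gid=2)]
        c = pr_curve(dets, gts, 0.5)
        assert c.precision.tolist() == pytest.approx([1.0, 0.5, 2 / 3])
        assert c.recall.tolist() == pytest.approx([0.5, 0.5, 1.0])

    def test_all_false_positives(self):
        c = pr_curve([det(50, 50, 5, 5, 0.8)], [gt(0, 0, 5, 5)], 0.5)
        assert np.all(c.precision == 0.0) and np.all(c.recall == 0.0)

    def test_no_ground_truth_is_error(self):
        with pytest.raises(ValueError):
            pr_curve([det(0, 0, 5, 5, 0.5)], [], 0.5)

    @given(st.lists(st.tuples(st.integers(0, 40), st.integers(0, 40),
                              st.integers(2, 15), st.integers(2, 15),
                              st.floats(0.01, 0.99)), min_size=1, max_size=10),
           st.lists(st.tuples(st.integers(0, 40), st.integers(0, 40),
                              st.integers(2, 15), st.integers(2, 15)),
                    min_size=1, max_size=6))
    def test_recall_non_decreasing(self, det_specs, gt_specs):
        dets = [det(x, y, w, h, round(s, 3)) for x, y, w, h, s in det_specs]
        gts = [gt(x, y, w, h, gid=i) for i, (x, y, w, h) in enumerate(gt_specs)]
        c = pr_curve(dets, gts, 0.5)
        assert np.all(np.diff(c.recall) >= -1e-12)
        assert np.all(np.diff(c.thresholds) <= 1e-12)


def ap_oracle(curve: PRCurve) -> float:
    """Brute-force 101-point interpolation: explicit scan per grid point."""
    total = 0.0
    for k in range(101):
        r = k / 100.0
        best = 0.0
        for p, rec in zip(curve.precision, curve.recall):
            if rec >= r - 1e-12 and p > best:
                best = p
        total += best
    return total / 101.0


class TestAveragePrecision:
    def test_perfect_curve(self):
        c = PRCurve(np.array([0.9]), np.array([1.0]), np.array([1.0]))
        assert average_precision(c) == 1.0

    def test_empty_curve(self):
        c = PRCurve(np.array([]), np.array([]), np.array([]))
        assert average_precision(c) == 0.0

    def test_three_point_curve_matches_oracle(self):
        c = PRCurve(np.array([0.9, 0.8, 0.7]), np.array([1.0, 0.5, 2 / 3]),
                    np.array([0.5, 0.5, 1.0]))
        assert average_precision(c) == pytest.approx(ap_oracle(c), abs=1e-12)

    @given(st.lists(st.tuples(st.integers(0, 60), st.integers(0, 60),
                              st.integers(2, 15), st.integers(2, 15),
                              st.floats(0.01, 0.99)), min_size=1, max_size=20),
           st.lists(st.tuples(st.integers(0, 60), st.integers(0, 60),
                              st.integers(2, 15), st.integers(2, 15)),
                    min_size=1, max_size=8))
    def test_matches_oracle_on_random_instances(self, det_specs, gt_specs):
        dets = [det(x, y, w, h, round(s, 3)) for x, y, w, h, s in det_specs]
        gts = [gt(x, y, w, h, gid=i) for i, (x, y, w, h) in enumerate(gt_specs)]
        c = pr_curve(dets, gts, 0.5)
        assert average_precision(c) == pytest.approx(ap_oracle(c), abs=1e-9)

    def test_trapezoid_mode_close_to_grid_mode(self):
        c = PRCurve(np.array([0.9, 0.7]), np.array([1.0, 0.8]),
                    np.array([0.5, 1.0]))
        grid = average_precision(c, mode="coco101")
        trap = average_precision(c, mode="trapezoid")
        assert abs(grid - trap) < 0.05


class TestMeanAP:
    def test_perfect_detector_scores_one(self):
        gts = [gt(10 * i, 0, 8, 8, gid=i) for i in range(4)]
        dets = [det(10 * i, 0, 8, 8, 1.0) for i in range(4)]
        res = mean_ap(dets, gts)
        assert res.map_value == 1.0
        assert all(v == 1.0 for v in res.ap_per_iou.values())

    def test_single_detection_at_iou_point6(self):
        # det overlaps its gt at IoU exactly 0.6: AP 1 for thresholds <= 0.6
        g = gt(0, 0, 10, 10, gid=1)
        d = det(0, 0, 10, 6, 1.0)  # contained: IoU = 60/100 = 0.6
        assert iou(d.box, g.box) == pytest.approx(0.6)
        res = mean_ap([d], [g])
        assert res.map_value == pytest.approx(0.3)

    def test_no_detections(self):
        assert mean_ap([], [gt(0, 0, 5, 5, gid=1)]).map_value == 0.0

    def test_mean_is_average_of_per_threshold_ap(self):
        gts = [gt(0, 0, 10, 10, gid=1), gt(30, 30, 10, 10, gid=2)]
        dets = [det(1, 1, 10, 10, 0.9), det(55, 55, 5, 5, 0.4)]
        res = mean_ap(dets, gts)
        assert res.map_value == pytest.approx(
            np.mean(list(res.ap_per_iou.values()))
        )


class TestRecallAtPrecision:
    def test_scan_of_discrete_points(self):
        c = PRCurve(np.array([0.9, 0.5]), np.array([0.9, 0.8]),
                    np.array([0.7, 0.9]))
        assert recall_at_precision(c, 0.85) == 0.7

    def test_perfect_detector(self):
        c = PRCurve(np.array([1.0]), np.array([1.0]), np.array([1.0]))
        assert recall_at_precision(c, 0.85) == 1.0

    def test_all_below_target(self):
        c = PRCurve(np.array([0.9]), np.array([0.5]), np.array([0.9]))
        assert recall_at_precision(c, 0.85) == 0.0

    def test_non_increasing_in_target(self):
        c = PRCurve(np.array([0.9, 0.6, 0.3]), np.array([1.0, 0.7, 0.5]),
                    np.array([0.3, 0.6, 0.9]))
        vals = [recall_at_precision(c, t) for t in (0.4, 0.6, 0.8, 0.95)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestSizePartition:
    @pytest.mark.parametrize(
        "w,h,expect_small",
        [(39, 39, True), (40, 40, False), (10, 100, True), (39, 41, True)],
    )
    def test_area_criterion(self, w, h, expect_small):
        small, other = size_partition([B(0, 0, w, h)])
        assert bool(small) is expect_small
        assert bool(other) is not expect_small

    def test_dims_criterion_differs_on_elongated_box(self):
        # 10x100 is small by area (1000 < 1600) but not by dimensions
        box = B(0, 0, 10, 100)
        by_area, _ = size_partition([box], criterion="area")
        _, by_dims_other = size_partition([box], criterion="dims")
        assert by_area == [box] and by_dims_other == [box]

    def test_partition_exhaustive_and_disjoint(self):
        boxes = [B(0, 0, s, s) for s in (5, 20, 39, 40, 80)]
        small, other = size_partition(boxes)
        assert len(small) + len(other) == len(boxes)
        assert set(id(b) for b in small).isdisjoint(id(b) for b in other)
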