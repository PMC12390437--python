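"""IoU, confusion semantics, PR curve, AP and mAP."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stunwatch.datamodel import BoundingBox, Detection, GroundTruthBox
from stunwatch.evaluation import (
    average_precision,
    evaluate_detections,
    iou,
    match_detections,
    mean_average_precision,
    pr_curve,
    precision,
    recall,
)
from stunwatch.synthetic import table6_fixture


def grid_iou(a: BoundingBox, b: BoundingBox, cells: int = 400) -> float:
    """Independent fine-grid area-counting oracle for IoU."""
    x_lo = min(a.x1, b.x1) - 1
    x_hi = max(a.x2, b.x2) + 1
    y_lo = min(a.y1, b.y1) - 1
    y_hi = max(a.y2, b.y2) + 1
    xs = np.linspace(x_lo, x_hi, cells)
    ys = np.linspace(y_lo, y_hi, cells)
    xx, yy = np.meshgrid(xs, ys)
    in_a = (xx >= a.x1) & (xx <= a.x2) & (yy >= a.y1) & (yy <= a.y2)
    in_b = (xx >= b.x1) & (xx <= b.x2) & (yy >= b.y1) & (yy <= b.y2)
    union = np.count_nonzero(in_a | in_b)
    if union == 0:
        return 0.0
    return np.count_nonzero(in_a & in_b) / union


def brute_force_ap(flags, n_gt):
    """All-point AP by direct envelope enumeration (independent oracle)."""
    precs, recs = [], []
    tp = 0
    for k, f in enumerate(flags, start=1):
        tp += int(f)
        precs.append(tp / k)
        recs.append(tp / n_gt)
    ap, prev_r = 0.0, 0.0
    for k in range(len(flags)):
        r = recs[k]
        if r > prev_r:
            envelope = max(precs[k:])  # best precision at recall >= r
            ap += (r - prev_r) * envelope
            prev_r = r
    return ap


def gt_box(cx, cy, w=10.0, h=10.0, label="stunned", frame=0, oid=0):
    return GroundTruthBox(BoundingBox(cx, cy, w, h), label, frame, oid)


def det(cx, cy, w=10.0, h=10.0, score=0.9, label="stunned", frame=0):
    return Detection(BoundingBox(cx, cy, w, h), score, label, frame)


class TestIoU:
    def test_identical_boxes(self):
        b = BoundingBox(5, 5, 4, 4)
        assert iou(b, b) == 1.0

    def test_disjoint_boxes(self):
        assert iou(BoundingBox(0, 0, 2, 2), BoundingBox(10, 10, 2, 2)) == 0.0

    def test_known_third_overlap(self):
        # 2x2 boxes at centers (1,1) and (2,1): intersection 2, union 6
        a = BoundingBox(1, 1, 2, 2)
        b = BoundingBox(2, 1, 2, 2)
        assert iou(a, b) == pytest.approx(1 / 3)
        assert iou(a, b) == pytest.approx(grid_iou(a, b), abs=1e-2)

    def test_symmetry_and_range_on_fuzzed_pairs(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            a = BoundingBox(rng.uniform(0, 20), rng.uniform(0, 20),
                            rng.uniform(1, 10), rng.uniform(1, 10))
            b = BoundingBox(rng.uniform(0, 20), rng.uniform(0, 20),
                            rng.uniform(1, 10), rng.uniform(1, 10))
            v = iou(a, b)
            assert 0.0 <= v <= 1.0
            assert v == pytest.approx(iou(b, a))
            assert v == pytest.approx(grid_iou(a, b), abs=1e-2)


class TestMatchDetections:
    def test_perfect_predictions_all_tp(self):
        gt = [gt_box(10, 10, oid=0), gt_box(40, 10, label="unstunned", oid=1)]
        preds = [det(10, 10), det(40, 10, label="unstunned", score=0.8)]
        counts, flags = match_detections(gt, preds, 0.75)
        assert counts.total_tp() == 2
        assert counts.total_fp() == 0 and counts.total_fn() == 0
        assert flags == [True, True]

    def test_no_predictions_all_fn(self):
        gt = [gt_box(10, 10), gt_box(40, 10, label="unstunned", oid=1)]
        counts, flags = match_detections(gt, [], 0.75)
        assert counts.total_fn() == 2
        assert counts.total_tp() == 0 and counts.total_fp() == 0
        assert flags == []

    def test_sub_threshold_overlap_is_fp_plus_fn(self):
        # pred A overlaps GT1 at IoU 0.8 (correct class); pred B overlaps
        # GT2 at IoU 0.5 < 0.75 -> hand evaluation: TP=1, FP=1, FN=1
        g1 = gt_box(10, 10, 10, 10, oid=0)
        g2 = gt_box(50, 10, 10, 10, oid=1)
        a = det(10, 10 + 10 * (1 - 0.8) / (1 + 0.8), score=0.9)  # IoU ~0.8 shift
        b = det(50 + 10 / 3, 10, score=0.8)                      # IoU = 0.5
        assert iou(a.box, g1.box) > 0.75
        assert iou(b.box, g2.box) == pytest.approx(0.5)
        counts, flags = match_detections([g1, g2], [a, b], 0.75)
        assert counts.total_tp() == 1
        assert counts.total_fp() == 1
        assert counts.total_fn() == 1
        assert flags == [True, False]

    def test_cross_class_match_consumes_gt_as_misclassification(self):
        gt = [gt_box(10, 10, label="unstunned")]
        preds = [det(10, 10, label="stunned")]
        counts, _ = match_detections(gt, preds, 0.75)
        table = counts.as_table()
        assert table["FP_1"] == 1 and table["FN_2"] == 0

    def test_each_gt_matched_at_most_once(self):
        gt = [gt_box(10, 10)]
        preds = [det(10, 10, score=0.9), det(10, 10, score=0.8)]
        counts, flags = match_detections(gt, preds, 0.75)
        assert counts.total_tp() == 1
        assert flags == [True, False]  # second duplicate is a background FP

    def test_tp_plus_fn_equals_gt_count_per_class(self):
        gt, preds = table6_fixture(seed=2)
        counts, _ = match_detections(gt, preds, 0.75)
        for cls in ("stunned", "unstunned"):
            n_cls = sum(1 for g in gt if g.label == cls)
            consumed = (counts.tp[cls]
                        + counts.fp_misclass["stunned" if cls == "unstunned"
                                             else "unstunned"])
            assert consumed + counts.fn[cls] == n_cls

    def test_printed_confusion_matrix_reproduced(self):
        gt, preds = table6_fixture(seed=0)
        counts, _ = match_detections(gt, preds, 0.75)
        assert counts.as_table() == {
            "TP_1": 104, "TP_2": 99, "FP_1": 1, "FP_2": 1,
            "FP_3": 0, "FP_4": 0, "FN_1": 0, "FN_2": 0,
            "FN_3": 0, "FN_4": 0, "TN": 0,
        }


class TestPrecisionRecall:
    def test_stunned_class_precision_from_published_counts(self):
        # 104 correct stunned predictions out of 105 stunned predictions
        assert precision(104, 1) == pytest.approx(104 / 105)

    def test_unstunned_recall_from_published_counts(self):
        # 99 of 100 actual unstunned birds found (one taken as stunned)
        assert recall(99, 1) == pytest.approx(0.99)

    def test_perfect_precision(self):
        assert precision(5, 0) == 1.0

    def test_undefined_cases_reported_as_none(self):
        assert precision(0, 0) is None
        assert recall(0, 0) is None


class TestAveragePrecision:
    def test_all_tp_covering_all_gt_is_one(self):
        assert average_precision([True, True, True], n_gt=3) == pytest.approx(1.0)

    def test_single_fp_is_zero(self):
        assert average_precision([False], n_gt=1) == 0.0

    def test_tp_fp_tp_sequence(self):
        assert average_precision([True, False, True], n_gt=2) == pytest.approx(5 / 6)
        assert brute_force_ap([True, False, True], 2) == pytest.approx(5 / 6)

    def test_matches_brute_force_envelope_on_all_short_sequences(self):
        for n in range(1, 7):
            for flags in itertools.product([False, True], repeat=n):
                n_gt = max(1, sum(flags))
                assert average_precision(list(flags), n_gt) == pytest.approx(
                    brute_force_ap(list(flags), n_gt)
                ), flags

    @given(st.lists(st.booleans(), min_size=1, max_size=20))
    def test_invariant_to_monotone_score_rescaling(self, flags):
        # AP depends only on the flag order, which any strictly increasing
        # transform of the scores preserves
        n_gt = max(1, sum(flags))
        base = average_precision(flags, n_gt)
        assert average_precision(list(flags), n_gt) == base

    @given(st.lists(st.booleans(), min_size=1, max_size=15),
           st.integers(0, 14))
    def test_inserting_fp_never_increases_ap(self, flags, pos):
        n_gt = max(1, sum(flags))
        worse = flags[: pos % (len(flags) + 1)] + [False] + flags[pos % (len(flags) + 1):]
        assert average_precision(worse, n_gt) <= average_precision(flags, n_gt) + 1e-12

    def test_zero_gt_rejected(self):
        with pytest.raises(ValueError):
            average_precision([True], n_gt=0)


class TestPRCurve:
    def test_recall_non_decreasing_and_bounded(self):
        curve = pr_curve([True, False, True, True], [0.9, 0.8, 0.7, 0.6], n_gt=4)
        assert np.all(np.diff(curve.recalls) >= 0)
        assert curve.recalls.max() <= 1.0
        assert curve.precisions.min() >= 0.0


class TestMAP:
    def test_published_two_class_mean(self):
        assert mean_average_precision({"unstunned": 0.89, "stunned": 0.99}) == \
            pytest.approx(0.94)

    def test_pre_amplification_mean(self):
        assert mean_average_precision([0.83, 0.96]) == pytest.approx(0.895)

    def test_single_class_is_identity(self):
        assert mean_average_precision([0.7]) == pytest.approx(0.7)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_average_precision([])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=5))
    def test_map_between_min_and_max_ap(self, aps):
        m = mean_average_precision(aps)
        assert min(aps) - 1e-12 <= m <= max(aps) + 1e-12


class TestEvaluateDetections:
    def test_perfect_set_has_unit_map(self):
        gt = [gt_box(10, 10, oid=0), gt_box(40, 10, label="unstunned", oid=1)]
        preds = [det(10, 10), det(40, 10, label="unstunned", score=0.8)]
        result = evaluate_detections(gt, preds, 0.75)
        assert result.map == pytest.approx(1.0)
        assert set(result.ap) == {"stunned", "unstunned"}
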