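"""Detection scoring: IoU, confusion semantics, PR curves, AP and mAP.

Scoring follows the background-aware confusion convention used for
two-class (stunned / unstunned) bird detection:

* a detection matching a same-class ground-truth box at IoU ≥ threshold is
  a true positive for that class (TP₁ stunned, TP₂ unstunned);
* a detection matching a ground-truth box of the *other* class is a
  misclassification false positive (FP₁: actual unstunned predicted
  stunned, FP₂: actual stunned predicted unstunned) and consumes that
  ground truth;
* a detection with no qualifying ground truth is a background
  hallucination (FP₃ predicted stunned, FP₄ predicted unstunned);
* ground truths left unmatched are false negatives (FN₁ stunned,
  FN₂ unstunned);
* "background correctly not detected" is uncountable in detection, so
  TN ≡ 0.

Matching is greedy in descending confidence; each detection takes the
highest-IoU not-yet-consumed ground truth (same class preferred) with
IoU at or above the threshold, and each ground truth is consumed at most
once.  The working IoU threshold is 0.75.

AP is the area under the precision envelope over recall (all-point
interpolation); mAP is the arithmetic mean of the per-class APs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .datamodel import (
    CLASS_NAMES,
    STUNNED,
    UNSTUNNED,
    BoundingBox,
    Detection,
    GroundTruthBox,
)

__all__ = [
    "DEFAULT_IOU_THRESHOLD",
    "ConfusionCounts",
    "PRCurve",
    "DetectionEvalResult",
    "iou",
    "match_detections",
    "precision",
    "recall",
    "pr_curve",
    "average_precision",
    "mean_average_precision",
    "evaluate_detections",
]

DEFAULT_IOU_THRESHOLD = 0.75


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes: overlap area / union area.

    Symmetric; 1 for identical boxes, 0 for disjoint ones.
    """
    ix = min(a.x2, b.x2) - max(a.x1, b.x1)
    iy = min(a.y2, b.y2) - max(a.y1, b.y1)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    union = a.area + b.area - inter
    return float(inter / union)


@dataclass
class ConfusionCounts:
    """Background-aware confusion counts for the two foreground classes.

    ``fp_misclass[c]`` counts detections of predicted class c that matched a
    ground truth of the other class; ``fp_background[c]`` counts detections
    of class c with no qualifying ground truth.  ``tn`` is identically 0.
    """

    tp: dict[str, int] = field(default_factory=lambda: {c: 0 for c in CLASS_NAMES})
    fp_misclass: dict[str, int] = field(default_factory=lambda: {c: 0 for c in CLASS_NAMES})
    fp_background: dict[str, int] = field(default_factory=lambda: {c: 0 for c in CLASS_NAMES})
    fn: dict[str, int] = field(default_factory=lambda: {c: 0 for c in CLASS_NAMES})
    tn: int = 0

    def fp(self, label: str) -> int:
        return self.fp_misclass[label] + self.fp_background[label]

    def total_tp(self) -> int:
        return sum(self.tp.values())

    def total_fp(self) -> int:
        return sum(self.fp(c) for c in CLASS_NAMES)

    def total_fn(self) -> int:
        return sum(self.fn.values())

    def as_table(self) -> dict[str, int]:
        """The printed confusion-matrix cells (stunned = class 1)."""
        return {
            "TP_1": self.tp[STUNNED],
            "TP_2": self.tp[UNSTUNNED],
            "FP_1": self.fp_misclass[STUNNED],
            "FP_2": self.fp_misclass[UNSTUNNED],
            "FP_3": self.fp_background[STUNNED],
            "FP_4": self.fp_background[UNSTUNNED],
            "FN_1": self.fn[STUNNED],
            "FN_2": self.fn[UNSTUNNED],
            "FN_3": 0,
            "FN_4": 0,
            "TN": self.tn,
        }


def match_detections(
    gt: Sequence[GroundTruthBox],
    preds: Sequence[Detection],
    iou_thr: float = DEFAULT_IOU_THRESHOLD,
) -> tuple[ConfusionCounts, list[bool]]:
    """Match predictions to ground truth frame-by-frame.

    Returns the confusion counts and one TP flag per prediction, ordered by
    descending confidence (ties broken by input order) — the ordering the
    PR curve and AP consume.
    """
    if not 0.0 < iou_thr <= 1.0:
        raise ValueError("iou_thr must lie in (0, 1]")
    order = sorted(range(len(preds)), key=lambda i: (-preds[i].score, i))
    consumed = [False] * len(gt)
    gt_by_frame: dict[int, list[int]] = {}
    for gi, g in enumerate(gt):
        gt_by_frame.setdefault(g.frame, []).append(gi)

    counts = ConfusionCounts()
    flags: list[bool] = []
    for pi in order:
        det = preds[pi]
        candidates = gt_by_frame.get(det.frame, [])
        best_gi, best_iou, best_same = -1, 0.0, False
        for gi in candidates:
            if consumed[gi]:
                continue
            ov = iou(det.box, gt[gi].box)
            if ov < iou_thr:
                continue
            same = gt[gi].label == det.label
            # prefer same-class matches, then higher IoU
            if (same, ov) > (best_same, best_iou):
                best_gi, best_iou, best_same = gi, ov, same
        if best_gi < 0:
            counts.fp_background[det.label] += 1
            flags.append(False)
        elif best_same:
            consumed[best_gi] = True
            counts.tp[det.label] += 1
            flags.append(True)
        else:
            consumed[best_gi] = True
            counts.fp_misclass[det.label] += 1
            flags.append(False)
    for gi, g in enumerate(gt):
        if not consumed[gi]:
            counts.fn[g.label] += 1
    return counts, flags


def precision(tp: int, fp: int) -> float | None:
    """TP / (TP + FP); None when nothing was predicted (undefined)."""
    if tp + fp == 0:
        return None
    return tp / (tp + fp)


def recall(tp: int, fn: int) -> float | None:
    """TP / (TP + FN); None when there are no actual positives."""
    if tp + fn == 0:
        return None
    return tp / (tp + fn)


@dataclass(frozen=True)
class PRCurve:
    """Ordered (recall, precision) points with the generating thresholds.

    Recall is non-decreasing along the curve.  Inside curve construction
    the zero-prediction point uses precision := 1 (the zero-recall limit).
    """

    recalls: np.ndarray
    precisions: np.ndarray
    thresholds: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.recalls, dtype=float)
        p = np.asarray(self.precisions, dtype=float)
        s = np.asarray(self.thresholds, dtype=float)
        object.__setattr__(self, "recalls", r)
        object.__setattr__(self, "precisions", p)
        object.__setattr__(self, "thresholds", s)
        if np.any(np.diff(r) < 0):
            raise ValueError("recall must be non-decreasing along the curve")
        for arr, name in ((r, "recall"), (p, "precision")):
            if arr.size and (arr.min() < 0 or arr.max() > 1):
                raise ValueError(f"{name} values must lie in [0, 1]")


def pr_curve(flags: Sequence[bool], scores: Sequence[float], n_gt: int) -> PRCurve:
    """Precision-recall points from score-ordered TP flags.

    ``flags`` and ``scores`` must be ordered by descending score (the order
    :func:`match_detections` returns).
    """
    if n_gt < 1:
        raise ValueError("n_gt must be >= 1")
    tp_cum = np.cumsum(np.asarray(flags, dtype=float))
    k = np.arange(1, len(tp_cum) + 1)
    prec = tp_cum / k
    rec = tp_cum / n_gt
    return PRCurve(recalls=rec, precisions=prec,
                   thresholds=np.asarray(scores, dtype=float))


def average_precision(flags: Sequence[bool], n_gt: int) -> float:
    """Area under the precision envelope over recall (all-point AP).

    ``flags`` are TP/FP indicators ordered by descending confidence;
    ``n_gt`` is the number of ground-truth boxes of the class.
    """
    if n_gt < 1:
        raise ValueError("n_gt must be >= 1 to define recall")
    if len(flags) == 0:
        return 0.0
    tp_cum = np.cumsum(np.asarray(flags, dtype=float))
    k = np.arange(1, len(flags) + 1)
    prec = tp_cum / k
    rec = tp_cum / n_gt
    # prepend the zero-recall point, append the tail
    mrec = np.concatenate(([0.0], rec, [rec[-1]]))
    mpre = np.concatenate(([1.0], prec, [0.0]))
    # precision envelope: running max from the right
    mpre = np.maximum.accumulate(mpre[::-1])[::-1]
    idx = np.where(mrec[1:] != mrec[:-1])[0]
    return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))


def mean_average_precision(aps: dict[str, float] | Sequence[float]) -> float:
    """Arithmetic mean of the per-class average precisions."""
    values = list(aps.values()) if isinstance(aps, dict) else list(aps)
    if not values:
        raise ValueError("at least one per-class AP is required")
    return float(np.mean(values))


@dataclass(frozen=True)
class DetectionEvalResult:
    """Full evaluation output: confusion counts, per-class PR/AP, and mAP."""

    counts: ConfusionCounts
    ap: dict[str, float]
    map: float
    curves: dict[str, PRCurve]


def evaluate_detections(
    gt: Sequence[GroundTruthBox],
    preds: Sequence[Detection],
    iou_thr: float = DEFAULT_IOU_THRESHOLD,
) -> DetectionEvalResult:
    """Score a detection set against ground truth at one IoU threshold.

    Per-class AP treats the *predicted* class as the detection's class;
    a class with no ground truth contributes AP 0 only if it has
    predictions, otherwise it is skipped.
    """
    counts, _ = match_detections(gt, preds, iou_thr)
    aps: dict[str, float] = {}
    curves: dict[str, PRCurve] = {}
    for cls in CLASS_NAMES:
        cls_idx = [i for i in range(len(preds)) if preds[i].label == cls]
        n_gt = sum(1 for g in gt if g.label == cls)
        if n_gt == 0 and not cls_idx:
            continue
        cls_gt = [g for g in gt if g.label == cls]
        cls_preds = [preds[i] for i in cls_idx]
        # class-restricted matching for the PR curve of this class
        _, flags = match_detections(cls_gt, cls_preds, iou_thr)
        scores = sorted((p.score for p in cls_preds), reverse=True)
        if n_gt == 0:
            aps[cls] = 0.0
            curves[cls] = PRCurve(
                recalls=np.zeros(len(flags)),
                precisions=np.zeros(len(flags)),
                thresholds=np.asarray(scores, dtype=float),
            )
        else:
            aps[cls] = average_precision(flags, n_gt)
            curves[cls] = pr_curve(flags, scores, n_gt)
    return DetectionEvalResult(
        counts=counts,
        ap=aps,
        map=mean_average_precision(aps) if aps else 0.0,
        curves=curves,
    )
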