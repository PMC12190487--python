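"""Detection evaluation: matching, precision/recall, AP and mAP.

Detections are matched to ground truth greedily in descending confidence
order: each detection claims the highest-IOU unclaimed ground-truth box with
IOU at or above the threshold (a true positive), otherwise it counts as a
false positive; unclaimed ground truth are false negatives.  True negatives
are not a meaningful quantity for box detection (the set of "background
boxes" is not enumerable) and are never used.

AP is the area under the precision-recall curve using the monotone
(non-increasing) precision envelope with all-point interpolation; mAP50
averages per-class AP at IOU 0.5, mAP50-95 over thresholds 0.50:0.05:0.95.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .boxes import BoundingBox, iou
from .model import Detection

__all__ = [
    "MatchResult",
    "PRCurve",
    "MetricsReport",
    "MAP_THRESHOLDS",
    "match_detections",
    "precision_recall",
    "pr_curve",
    "average_precision",
    "mean_ap",
    "evaluate_detections",
    "max_f1_point",
]

MAP_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))


@dataclass(frozen=True)
class MatchResult:
    """Per-detection TP flags (in confidence order) against ``n_gt`` boxes."""

    tp_flags: np.ndarray
    scores: np.ndarray
    n_gt: int
    iou_threshold: float

    @property
    def tp(self) -> int:
        return int(self.tp_flags.sum())

    @property
    def fp(self) -> int:
        return int(len(self.tp_flags) - self.tp)

    @property
    def fn(self) -> int:
        return self.n_gt - self.tp


@dataclass(frozen=True)
class PRCurve:
    """Precision over non-decreasing recall, one point per detection."""

    recall_points: np.ndarray
    precision_points: np.ndarray

    def __post_init__(self):
        r, p = np.asarray(self.recall_points), np.asarray(self.precision_points)
        if r.shape != p.shape:
            raise ValueError("recall and precision must have equal length")
        if len(r) > 1 and np.any(np.diff(r) < -1e-12):
            raise ValueError("recall points must be non-decreasing")


@dataclass(frozen=True)
class MetricsReport:
    precision: float
    recall: float
    ap_per_class: dict[int, float]
    map50: float
    map50_95: float
    per_threshold: dict[float, float] = field(default_factory=dict)

    def summary(self) -> str:
        return (f"P={self.precision:.3f} R={self.recall:.3f} "
                f"mAP50={self.map50:.3f} mAP50-95={self.map50_95:.3f}")


def match_detections(dets: Sequence[Detection], gts: Sequence[BoundingBox],
                     iou_threshold: float = 0.5) -> MatchResult:
    """Greedily match detections (descending score) to unclaimed ground truth."""
    if not (0.0 < iou_threshold < 1.0):
        raise ValueError("iou_threshold must lie in (0,1)")
    order = sorted(range(len(dets)), key=lambda k: -dets[k].score)
    claimed = [False] * len(gts)
    flags = np.zeros(len(dets), dtype=bool)
    scores = np.array([dets[k].score for k in order], dtype=np.float64)
    for rank, k in enumerate(order):
        best_iou, best_g = 0.0, -1
        for g, gt in enumerate(gts):
            if claimed[g]:
                continue
            v = iou(dets[k].box, gt)
            if v > best_iou:
                best_iou, best_g = v, g
        if best_g >= 0 and best_iou >= iou_threshold:
            claimed[best_g] = True
            flags[rank] = True
    return MatchResult(tp_flags=flags, scores=scores, n_gt=len(gts),
                       iou_threshold=iou_threshold)


def precision_recall(m: MatchResult) -> tuple[float, float]:
    """Precision TP/(TP+FP) and recall TP/(TP+FN); empty sides give 0 (recall 1
    when there is nothing to find and nothing was missed)."""
    n_det = len(m.tp_flags)
    precision = m.tp / n_det if n_det else 0.0
    recall = m.tp / m.n_gt if m.n_gt else (1.0 if n_det == 0 else 0.0)
    return precision, recall


def pr_curve(m: MatchResult) -> PRCurve:
    """Cumulative precision/recall along the confidence-sorted detections."""
    tp_cum = np.cumsum(m.tp_flags.astype(np.float64))
    ranks = np.arange(1, len(m.tp_flags) + 1, dtype=np.float64)
    precision = tp_cum / ranks
    recall = tp_cum / m.n_gt if m.n_gt else np.zeros_like(tp_cum)
    return PRCurve(recall_points=recall, precision_points=precision)


def average_precision(curve: PRCurve) -> float:
    """Area under the monotone precision envelope (all-point interpolation)."""
    r = np.concatenate([[0.0], np.asarray(curve.recall_points), [1.0]])
    p = np.concatenate([[1.0], np.asarray(curve.precision_points), [0.0]])
    # monotone non-increasing envelope, right to left
    for i in range(len(p) - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    idx = np.nonzero(np.diff(r) > 0)[0]
    return float(np.sum((r[idx + 1] - r[idx]) * p[idx + 1]))


def _pooled_match(dets_per_image, gts_per_image, class_id, threshold):
    """Match per image, then pool TP flags across images in global score order."""
    flags, scores, n_gt = [], [], 0
    for dets, gts in zip(dets_per_image, gts_per_image):
        d = [x for x in dets if x.class_id == class_id]
        g = [b for b, c in gts if c == class_id]
        m = match_detections(d, g, threshold)
        flags.append(m.tp_flags)
        scores.append(m.scores)
        n_gt += len(g)
    flags = np.concatenate(flags) if flags else np.zeros(0, dtype=bool)
    scores = np.concatenate(scores) if scores else np.zeros(0)
    order = np.argsort(-scores, kind="stable")
    return MatchResult(tp_flags=flags[order], scores=scores[order],
                       n_gt=n_gt, iou_threshold=threshold)


def mean_ap(dets_per_image: Sequence[Sequence[Detection]],
            gts_per_image: Sequence[Sequence[tuple[BoundingBox, int]]],
            iou_thresholds: Sequence[float] = MAP_THRESHOLDS,
            conf_threshold: float = 0.25) -> MetricsReport:
    """Dataset-level mAP over classes and IOU thresholds.

    ``gts_per_image`` holds (box, class_id) pairs.  The single-point P and R
    in the report are computed at ``conf_threshold`` and IOU 0.5; AP values
    are threshold-free.
    """
    iou_thresholds = list(iou_thresholds)
    if not iou_thresholds:
        raise ValueError("need at least one IOU threshold")
    classes = sorted({c for gts in gts_per_image for _, c in gts} |
                     {d.class_id for dets in dets_per_image for d in dets})
    if not classes:
        classes = [0]

    ap = {thr: {} for thr in iou_thresholds}
    for thr in iou_thresholds:
        for cid in classes:
            m = _pooled_match(dets_per_image, gts_per_image, cid, thr)
            ap[thr][cid] = average_precision(pr_curve(m))

    thr0 = iou_thresholds[0]
    per_threshold = {thr: float(np.mean(list(ap[thr].values())))
                     for thr in iou_thresholds}
    map50 = per_threshold.get(0.5, per_threshold[thr0])
    map50_95 = float(np.mean(list(per_threshold.values())))

    conf_dets = [[d for d in dets if d.score >= conf_threshold]
                 for dets in dets_per_image]
    tp = fp = fn = 0
    for cid in classes:
        m = _pooled_match(conf_dets, gts_per_image, cid, 0.5)
        tp, fp, fn = tp + m.tp, fp + m.fp, fn + m.fn
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 1.0

    ap50 = ap.get(0.5, ap[thr0])
    return MetricsReport(precision=precision, recall=recall,
                         ap_per_class={c: ap50[c] for c in classes},
                         map50=map50, map50_95=map50_95,
                         per_threshold=per_threshold)


def evaluate_detections(dets_per_image, scenes,
                        iou_thresholds: Sequence[float] = MAP_THRESHOLDS,
                        conf_threshold: float = 0.25) -> MetricsReport:
    """Convenience wrapper taking :class:`~aquadet.scenes.GroundTruthScene` s."""
    gts = [list(zip(sc.boxes, sc.class_ids)) for sc in scenes]
    return mean_ap(dets_per_image, gts, iou_thresholds, conf_threshold)


def max_f1_point(m: MatchResult) -> tuple[float, float, float]:
    """(precision, recall, score threshold) at the maximum-F1 operating point."""
    curve = pr_curve(m)
    p, r = curve.precision_points, curve.recall_points
    if len(p) == 0 or m.n_gt == 0:
        return 0.0, 0.0, 1.0
    f1 = 2 * p * r / np.maximum(p + r, 1e-12)
    k = int(np.argmax(f1))
    return float(p[k]), float(r[k]), float(m.scores[k])
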