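"""Confusion-matrix metrics, Dice coefficient, and detection AP/mAP@0.5.

Detection scoring follows the usual single-class protocol: detections are
processed in descending confidence, each greedily matched to the unmatched
ground-truth box of highest IoU (counted a true positive when IoU >= the
threshold, default 0.5); average precision integrates the precision
envelope over recall (all-point interpolation).  Undefined ratios are
reported as None with a flag rather than silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_annotations import BinaryMask

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "dice_coefficient",
    "confusion_metrics",
    "box_iou",
    "match_detections",
    "average_precision",
    "evaluate_detections",
]


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass
class MetricsReport:
    precision: float | None = None
    recall: float | None = None
    f1: float | None = None
    accuracy: float | None = None
    dice: float | None = None
    map50: float | None = None
    undefined: tuple[str, ...] = ()


def dice_coefficient(a: BinaryMask | np.ndarray, b: BinaryMask | np.ndarray) -> float:
    """2|A n B| / (|A| + |B|); 1.0 when both masks are empty."""
    ga = a.grid if isinstance(a, BinaryMask) else np.asarray(a)
    gb = b.grid if isinstance(b, BinaryMask) else np.asarray(b)
    if ga.shape != gb.shape:
        raise ValueError(f"mask shapes differ: {ga.shape} vs {gb.shape}")
    sa, sb = int(ga.sum()), int(gb.sum())
    if sa + sb == 0:
        return 1.0
    inter = int((ga.astype(bool) & gb.astype(bool)).sum())
    return 2.0 * inter / (sa + sb)


def confusion_metrics(c: ConfusionCounts) -> MetricsReport:
    undefined = []
    precision = recall = f1 = accuracy = None
    if c.tp + c.fp > 0:
        precision = c.tp / (c.tp + c.fp)
    else:
        undefined.append("precision")
    if c.tp + c.fn > 0:
        recall = c.tp / (c.tp + c.fn)
    else:
        undefined.append("recall")
    if precision is not None and recall is not None and precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    elif precision == 0 and recall == 0:
        f1 = 0.0
        undefined.append("f1")
    else:
        undefined.append("f1")
    total = c.tp + c.tn + c.fp + c.fn
    if total > 0:
        accuracy = (c.tp + c.tn) / total
    else:
        undefined.append("accuracy")
    return MetricsReport(precision=precision, recall=recall, f1=f1,
                         accuracy=accuracy, undefined=tuple(undefined))


def box_iou(a, b) -> float:
    """IoU of two half-open axis-aligned boxes (x0, y0, x1, y1)."""
    ax0, ay0, ax1, ay1 = a
    bx0, by0, bx1, by1 = b
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return inter / union


def match_detections(dets, gts, iou_min: float = 0.5):
    """Greedy confidence-ordered matching.

    `dets` are objects with .x0/.y0/.x1/.y1/.confidence (or (box, conf)
    tuples); `gts` are (x0, y0, x1, y1) boxes.  Returns (labels, fn) where
    labels is the confidence-ordered list of True (TP) / False (FP) and fn
    the number of unmatched ground truths.
    """
    def unpack(d):
        if hasattr(d, "x0"):
            return (d.x0, d.y0, d.x1, d.y1), d.confidence
        box, conf = d
        return tuple(box), conf

    items = [unpack(d) for d in dets]
    order = sorted(range(len(items)), key=lambda i: -items[i][1])
    gt_boxes = [tuple(g) for g in gts]
    matched = [False] * len(gt_boxes)
    labels = []
    for i in order:
        box, _ = items[i]
        best_iou, best_j = 0.0, -1
        for j, gb in enumerate(gt_boxes):
            if matched[j]:
                continue
            iou = box_iou(box, gb)
            if iou > best_iou:
                best_iou, best_j = iou, j
        if best_j >= 0 and best_iou >= iou_min:
            matched[best_j] = True
            labels.append(True)
        else:
            labels.append(False)
    fn = matched.count(False)
    return labels, fn


def average_precision(labels, n_gt: int) -> float:
    """All-point-interpolated AP from a confidence-ordered TP/FP sequence."""
    if n_gt < 0:
        raise ValueError("n_gt must be >= 0")
    if n_gt == 0:
        return 1.0 if not labels else 0.0
    labels = np.asarray(labels, dtype=bool)
    if labels.size == 0:
        return 0.0
    tp = np.cumsum(labels)
    fp = np.cumsum(~labels)
    recall = tp / n_gt
    precision = tp / (tp + fp)
    # precision envelope (running max from the right), then rectangle sum
    r = np.concatenate([[0.0], recall])
    p = np.concatenate([[1.0], precision])
    for i in range(len(p) - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    return float(np.sum((r[1:] - r[:-1]) * p[1:]))


def evaluate_detections(dets, gts, iou_min: float = 0.5) -> MetricsReport:
    """Precision/recall/F1 at the operating point plus mAP@iou_min."""
    labels, fn = match_detections(dets, gts, iou_min)
    tp = sum(labels)
    fp = len(labels) - tp
    rep = confusion_metrics(ConfusionCounts(tp=tp, fp=fp, fn=fn))
    rep.map50 = average_precision(labels, len(gts))
    return rep
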