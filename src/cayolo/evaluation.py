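"""Two-level screening evaluation.

Image level: an image is called positive when clue-class box area exceeds
20% (strictly) of the combined clue + epithelial box area; SEN/SPE/ACC
follow from the image-level confusion counts.  Object level: greedy
confidence-ordered one-to-one matching at an IoU threshold yields
precision/recall/F1 (clue class by default).  ROC/PR curves come from a
full threshold sweep.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

POSITIVE, NEGATIVE = "positive", "negative"

__all__ = [
    "ConfusionCounts", "image_level_label", "image_metrics",
    "object_metrics", "aggregate_object_metrics", "curves", "box_iou",
]


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)

    # zero-denominator values are explicit None, never a silent 0
    @property
    def sensitivity(self) -> Optional[float]:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def specificity(self) -> Optional[float]:
        d = self.tn + self.fp
        return self.tn / d if d else None

    @property
    def accuracy(self) -> Optional[float]:
        return (self.tp + self.tn) / self.total if self.total else None

    @property
    def precision(self) -> Optional[float]:
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def recall(self) -> Optional[float]:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def f1(self) -> Optional[float]:
        p, r = self.precision, self.recall
        if p is None or r is None or (p + r) == 0:
            return None
        return 2 * p * r / (p + r)


def _area_by_class(items, clue_class):
    """Total box area per side (clue, other) from detections or label rows."""
    a_clue = a_other = 0.0
    for it in items:
        if hasattr(it, "box"):           # Detection-like, pixel xyxy
            cls = it.class_id
            x1, y1, x2, y2 = it.box
            area = max(0.0, x2 - x1) * max(0.0, y2 - y1)
        else:                            # (cls, cx, cy, w, h) normalized
            cls = int(it[0])
            area = float(it[3]) * float(it[4])
        if cls == clue_class:
            a_clue += area
        else:
            a_other += area
    return a_clue, a_other


def image_level_label(items: Sequence, clue_class: int = 0) -> str:
    """Positive iff clue area / (clue + epithelial area) > 0.20, strictly."""
    a_clue, a_other = _area_by_class(items, clue_class)
    total = a_clue + a_other
    if total == 0:
        return NEGATIVE
    return POSITIVE if a_clue / total > 0.20 else NEGATIVE


def image_metrics(pred_labels: Sequence[str], true_labels: Sequence[str]):
    """Image-level confusion counts and (SEN, SPE, ACC)."""
    if len(pred_labels) != len(true_labels):
        raise ValueError("label vectors must have equal length")
    cc = ConfusionCounts()
    for p, t in zip(pred_labels, true_labels):
        if t == POSITIVE:
            if p == POSITIVE:
                cc.tp += 1
            else:
                cc.fn += 1
        else:
            if p == POSITIVE:
                cc.fp += 1
            else:
                cc.tn += 1
    return cc, {"sen": cc.sensitivity, "spe": cc.specificity,
                "acc": cc.accuracy}


def box_iou(a, b) -> float:
    """IoU of two (x1, y1, x2, y2) boxes."""
    ix1, iy1 = max(a[0], b[0]), max(a[1], b[1])
    ix2, iy2 = min(a[2], b[2]), min(a[3], b[3])
    inter = max(0.0, ix2 - ix1) * max(0.0, iy2 - iy1)
    a1 = (a[2] - a[0]) * (a[3] - a[1])
    a2 = (b[2] - b[0]) * (b[3] - b[1])
    return inter / (a1 + a2 - inter) if inter else 0.0


def object_metrics(detections, gt_boxes, iou_thr: float = 0.5,
                   cls: Optional[int] = 0):
    """Object-level matching on one image.

    detections: Detection-like objects (class_id, confidence, box xyxy);
    gt_boxes: (cls, x1, y1, x2, y2) tuples in the same pixel frame.
    cls selects one class (default clue); None pools all classes
    (macro behaviour is obtained by summing per-class counts).
    Returns (ConfusionCounts, metric dict).
    """
    dets = [d for d in detections if cls is None or d.class_id == cls]
    gts = [g for g in gt_boxes if cls is None or int(g[0]) == cls]
    matched = [False] * len(gts)
    tp = fp = 0
    for det in sorted(dets, key=lambda d: -d.confidence):
        best, best_iou = -1, iou_thr
        for j, g in enumerate(gts):
            if matched[j] or int(g[0]) != det.class_id:
                continue
            iou = box_iou(det.box, g[1:5])
            if iou >= best_iou:
                best, best_iou = j, iou
        if best >= 0:
            matched[best] = True
            tp += 1
        else:
            fp += 1
    fn = matched.count(False)
    cc = ConfusionCounts(tp=tp, fp=fp, fn=fn)
    return cc, {"precision": cc.precision, "recall": cc.recall, "f1": cc.f1}


def aggregate_object_metrics(per_image: Sequence[Tuple], iou_thr: float = 0.5,
                             cls: Optional[int] = 0):
    """Sum object-level counts over (detections, gt_boxes) pairs."""
    cc = ConfusionCounts()
    for dets, gts in per_image:
        c, _ = object_metrics(dets, gts, iou_thr, cls)
        cc = cc + c
    return cc, {"precision": cc.precision, "recall": cc.recall, "f1": cc.f1}


def curves(scores: Sequence[float], labels: Sequence[int]):
    """ROC (trapezoid AUC) and PR (step-wise AUPRC) by threshold sweep."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("curves need at least one positive and one negative")

    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # group ties: cumulative counts at each distinct threshold
    distinct = np.where(np.diff(s))[0]
    idx = np.r_[distinct, len(s) - 1]
    tps = np.cumsum(y)[idx]
    fps = np.cumsum(1 - y)[idx]

    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    auc = float(np.trapezoid(tpr, fpr))

    precision = tps / (tps + fps)
    recall = tps / n_pos
    # step-wise (interpolation-free) area: sum P(k) * dR(k)
    auprc = float(np.sum(precision * np.diff(np.r_[0.0, recall])))
    return {
        "roc": np.stack([fpr, tpr], axis=-1),
        "auc": auc,
        "pr": np.stack([np.r_[0.0, recall], np.r_[1.0, precision]], axis=-1),
        "auprc": auprc,
    }
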