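"""Objective components: BCE, focal, CIoU, DFL and their composition.

The classification term is BCE plus focal loss (not focal replacing BCE);
box regression is CIoU plus distribution focal loss.  Scalar/ndarray
reference implementations are exposed directly; `DetectionLoss` composes
the same formulas on autodiff tensors for training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .nn import tensor as T
from .nn.tensor import Tensor

EPS = 1e-7

__all__ = [
    "FocalParams", "LossBreakdown", "bce_loss", "focal_loss",
    "alpha_from_frequency", "ciou", "ciou_loss", "dfl_loss",
    "DetectionLoss",
]


@dataclass
class FocalParams:
    """Focal-loss hyper-parameters.

    alpha: per-class weights (inverse-frequency, normalized to sum to the
    number of classes).  gamma: focusing exponent, default 1.5.
    focal_only / bce_only: ablation switches dropping the BCE or the focal
    term from the enhanced classification loss.
    """

    alpha: np.ndarray = field(default_factory=lambda: np.ones(2))
    gamma: float = 1.5
    focal_only: bool = False
    bce_only: bool = False

    def __post_init__(self):
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if np.any(self.alpha <= 0):
            raise ValueError("alpha entries must be positive")


def _check_binary(y):
    y = np.asarray(y, dtype=float)
    if not np.all((y == 0) | (y == 1)):
        raise ValueError("ground-truth labels must be in {0, 1}")
    return y


def bce_loss(y, y_hat):
    """Binary cross-entropy -y log p - (1-y) log(1-p), probabilities clamped."""
    y = _check_binary(y)
    p = np.clip(np.asarray(y_hat, dtype=float), EPS, 1.0 - EPS)
    out = -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    return out if out.ndim else float(out)


def focal_loss(y, y_hat, gamma: float = 1.5, alpha_t: float = 1.0):
    """Focal loss -alpha_t (1-pt)^gamma log(pt) with pt the true-class prob."""
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    y = _check_binary(y)
    p = np.clip(np.asarray(y_hat, dtype=float), EPS, 1.0 - EPS)
    pt = np.clip(y * p + (1.0 - y) * (1.0 - p), EPS, 1.0)
    out = -np.asarray(alpha_t, dtype=float) * (1.0 - pt) ** gamma * np.log(pt)
    return out if out.ndim else float(out)


def alpha_from_frequency(class_counts: Sequence[float]) -> np.ndarray:
    """Inverse-frequency class weights, normalized to sum to n_classes."""
    counts = np.asarray(class_counts, dtype=float)
    if np.any(counts <= 0):
        raise ValueError(
            "all class counts must be > 0; add smoothing (e.g. +1) for "
            "classes absent from the training set")
    inv = 1.0 / counts
    return inv / inv.sum() * counts.size


def _validate_box(box):
    box = np.asarray(box, dtype=float)
    if box[2] <= box[0] or box[3] <= box[1]:
        raise ValueError(f"degenerate box {box.tolist()}: needs positive extent")
    return box


def ciou(pred_box, gt_box) -> float:
    """Complete IoU of two (x1, y1, x2, y2) boxes."""
    p = _validate_box(pred_box)
    g = _validate_box(gt_box)
    ix1, iy1 = max(p[0], g[0]), max(p[1], g[1])
    ix2, iy2 = min(p[2], g[2]), min(p[3], g[3])
    inter = max(0.0, ix2 - ix1) * max(0.0, iy2 - iy1)
    area_p = (p[2] - p[0]) * (p[3] - p[1])
    area_g = (g[2] - g[0]) * (g[3] - g[1])
    iou = inter / (area_p + area_g - inter)
    cx1, cy1 = min(p[0], g[0]), min(p[1], g[1])
    cx2, cy2 = max(p[2], g[2]), max(p[3], g[3])
    c2 = (cx2 - cx1) ** 2 + (cy2 - cy1) ** 2 + EPS
    rho2 = ((p[0] + p[2] - g[0] - g[2]) / 2) ** 2 + ((p[1] + p[3] - g[1] - g[3]) / 2) ** 2
    v = (4 / np.pi ** 2) * (np.arctan((g[2] - g[0]) / (g[3] - g[1]))
                            - np.arctan((p[2] - p[0]) / (p[3] - p[1]))) ** 2
    a = v / (1.0 - iou + v + EPS)
    return float(iou - rho2 / c2 - a * v)


def ciou_loss(pred_box, gt_box) -> float:
    """1 - CIoU; zero for identical boxes, bounded by [0, 2]."""
    return 1.0 - ciou(pred_box, gt_box)


def dfl_loss(pred_distribution, target: float) -> float:
    """Distribution focal loss for one side-distance.

    pred_distribution: probabilities over integer bins 0..n-1 (sums to 1);
    target: continuous coordinate inside [0, n-1].  Cross-entropy against
    the two bracketing bins, linearly interpolated.
    """
    p = np.asarray(pred_distribution, dtype=float)
    if not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ValueError("bin distribution must sum to 1")
    n = p.size
    if target < 0 or target > n - 1:
        raise ValueError(f"target {target} outside bin range [0, {n - 1}]")
    lo = int(np.floor(target))
    hi = min(lo + 1, n - 1)
    w_hi = target - lo
    w_lo = 1.0 - w_hi
    out = -w_lo * np.log(max(p[lo], EPS))
    if w_hi > 0:
        out -= w_hi * np.log(max(p[hi], EPS))
    return float(out)


class LossBreakdown:
    """Per-batch loss components with exact additivity identities.

    Components may be floats or autodiff tensors; `l_cls_enhanced`,
    `l_bbox` and `l_total` are always computed as the stated sums.
    """

    def __init__(self, l_bce, l_fl, l_ciou, l_dfl):
        self.l_bce = l_bce
        self.l_fl = l_fl
        self.l_ciou = l_ciou
        self.l_dfl = l_dfl
        self.l_cls_enhanced = l_bce + l_fl
        self.l_bbox = l_ciou + l_dfl
        self.l_total = self.l_cls_enhanced + self.l_bbox

    def to_floats(self) -> "LossBreakdown":
        def f(x):
            return float(x.data) if isinstance(x, Tensor) else float(x)
        return LossBreakdown(f(self.l_bce), f(self.l_fl), f(self.l_ciou),
                             f(self.l_dfl))

    def __repr__(self):
        b = self.to_floats()
        return (f"LossBreakdown(bce={b.l_bce:.4f}, fl={b.l_fl:.4f}, "
                f"ciou={b.l_ciou:.4f}, dfl={b.l_dfl:.4f}, total={b.l_total:.4f})")


# -------------------------------------------------------------------------
# Detector criterion
# -------------------------------------------------------------------------

def _iou_matrix(a, b):
    """IoU between (M,4) and (K,4) xyxy boxes."""
    ix1 = np.maximum(a[:, None, 0], b[None, :, 0])
    iy1 = np.maximum(a[:, None, 1], b[None, :, 1])
    ix2 = np.minimum(a[:, None, 2], b[None, :, 2])
    iy2 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.clip(ix2 - ix1, 0, None) * np.clip(iy2 - iy1, 0, None)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    return inter / (area_a[:, None] + area_b[None, :] - inter + 1e-9)


class DetectionLoss:
    """Composes BCE+focal classification and CIoU+DFL regression.

    Matching uses a task-aligned rule restricted to anchors whose point
    lies inside a ground-truth box: alignment = p_cls^0.5 * IoU^6, top-k
    per target, conflicts resolved by the higher alignment.
    """

    def __init__(self, n_classes: int, reg_max: int = 16,
                 focal: Optional[FocalParams] = None, topk: int = 10,
                 cls_reduction: str = "positives"):
        self.nc = n_classes
        self.reg_max = reg_max
        self.focal = focal or FocalParams(alpha=np.ones(n_classes))
        if self.focal.alpha.size == 1:
            self.focal.alpha = np.full(n_classes, float(self.focal.alpha))
        self.topk = topk
        if cls_reduction not in ("positives", "anchors"):
            raise ValueError("cls_reduction must be 'positives' or 'anchors'")
        self.cls_reduction = cls_reduction

    # -- assignment (no gradients) ------------------------------------
    def assign(self, cls_prob, pred_boxes, anchors, gt_cls, gt_boxes):
        """Return (anchor_idx, gt_idx) arrays of positive matches."""
        if len(gt_cls) == 0:
            return np.zeros(0, dtype=int), np.zeros(0, dtype=int)
        inside = ((anchors[:, 0][:, None] > gt_boxes[None, :, 0])
                  & (anchors[:, 0][:, None] < gt_boxes[None, :, 2])
                  & (anchors[:, 1][:, None] > gt_boxes[None, :, 1])
                  & (anchors[:, 1][:, None] < gt_boxes[None, :, 3]))
        iou = _iou_matrix(pred_boxes, gt_boxes)
        score = cls_prob[:, gt_cls]                       # (A, G)
        metric = (score ** 0.5) * ((iou + 1e-9) ** 6.0)
        metric = np.where(inside, metric, -1.0)
        best_gt = {}
        for g in range(len(gt_cls)):
            cand = np.where(inside[:, g])[0]
            if cand.size == 0:
                # fall back to the closest anchor by center distance
                cx = (gt_boxes[g, 0] + gt_boxes[g, 2]) / 2
                cy = (gt_boxes[g, 1] + gt_boxes[g, 3]) / 2
                d = (anchors[:, 0] - cx) ** 2 + (anchors[:, 1] - cy) ** 2
                cand = np.array([int(d.argmin())])
            order = cand[np.argsort(-metric[cand, g], kind="stable")]
            for a in order[: self.topk]:
                prev = best_gt.get(int(a))
                if prev is None or metric[a, g] > metric[a, prev]:
                    best_gt[int(a)] = g
        if not best_gt:
            return np.zeros(0, dtype=int), np.zeros(0, dtype=int)
        a_idx = np.fromiter(best_gt.keys(), dtype=int)
        g_idx = np.fromiter(best_gt.values(), dtype=int)
        return a_idx, g_idx

    # -- loss -----------------------------------------------------------
    def __call__(self, preds, targets, anchors, strides) -> LossBreakdown:
        """Compute the loss breakdown for one batch.

        preds: (cls_logits, reg_logits) tensors of shapes (N, A, nc) and
            (N, A, 4, reg_max), anchor-major across scales.
        targets: per-image list of (classes (G,), boxes (G,4) xyxy pixels).
        anchors: (A, 2) anchor centers in pixels; strides: (A,) per anchor.
        """
        cls_logits, reg_logits = preds
        n, a_total, nc = cls_logits.shape
        rm = self.reg_max
        bins = np.arange(rm, dtype=cls_logits.data.dtype)

        # decoded boxes for assignment only (no gradient)
        reg_np = reg_logits.data
        prob_np = np.exp(reg_np - reg_np.max(axis=-1, keepdims=True))
        prob_np /= prob_np.sum(axis=-1, keepdims=True)
        dist_np = (prob_np * bins).sum(axis=-1)          # (N, A, 4) stride units
        sxy = strides[:, None]
        px = anchors[None, :, 0]
        py = anchors[None, :, 1]
        dec = np.stack([
            px - dist_np[..., 0] * strides[None, :],
            py - dist_np[..., 1] * strides[None, :],
            px + dist_np[..., 2] * strides[None, :],
            py + dist_np[..., 3] * strides[None, :],
        ], axis=-1)
        from scipy.special import expit
        cls_prob_np = expit(cls_logits.data)

        tcls = np.zeros((n, a_total, nc), dtype=cls_logits.data.dtype)
        fg_n, fg_a, fg_g_boxes, fg_cls = [], [], [], []
        for i, (g_cls, g_boxes) in enumerate(targets):
            g_cls = np.asarray(g_cls, dtype=int)
            g_boxes = np.asarray(g_boxes, dtype=float).reshape(-1, 4)
            a_idx, g_idx = self.assign(cls_prob_np[i], dec[i], anchors,
                                       g_cls, g_boxes)
            if a_idx.size:
                tcls[i, a_idx, g_cls[g_idx]] = 1.0
                fg_n.extend([i] * a_idx.size)
                fg_a.extend(a_idx.tolist())
                fg_g_boxes.append(g_boxes[g_idx])
                fg_cls.extend(g_cls[g_idx].tolist())
        n_fg = len(fg_a)

        # classification: BCE + focal on every anchor/class logit
        z = cls_logits
        y = Tensor(tcls)
        log_p = T.log_sigmoid(z)
        log_1p = T.log_sigmoid(z * -1.0)
        bce_el = -(y * log_p + (1.0 - y) * log_1p)
        # pt = sigmoid((2y-1) z); alpha_t = alpha[c] on positives, 1 on negatives
        sgn = 2.0 * tcls - 1.0
        log_pt = T.log_sigmoid(z * sgn)
        one_minus_pt = T.sigmoid(z * (-sgn))
        alpha_t = np.where(tcls > 0, self.focal.alpha[None, None, :], 1.0)
        fl_el = (one_minus_pt ** self.focal.gamma) * (-1.0 * log_pt) * alpha_t
        denom = float(max(n_fg, 1)) if self.cls_reduction == "positives" \
            else float(n * a_total)
        l_bce = bce_el.sum() * (1.0 / denom)
        l_fl = fl_el.sum() * (1.0 / denom)
        if self.focal.focal_only:
            l_bce = l_bce * 0.0
        if self.focal.bce_only:
            l_fl = l_fl * 0.0

        if n_fg == 0:
            zero = Tensor(np.asarray(0.0, dtype=cls_logits.data.dtype))
            return LossBreakdown(l_bce, l_fl, zero, zero)

        fg_n = np.asarray(fg_n)
        fg_a = np.asarray(fg_a)
        gt_boxes = np.concatenate(fg_g_boxes, axis=0)    # (F, 4) pixels

        reg_fg = reg_logits[(fg_n, fg_a)]                # (F, 4, rm)
        prob = T.softmax(reg_fg, axis=-1)
        dist = (prob * bins).sum(axis=-1)                # (F, 4) stride units
        s = strides[fg_a]
        ax = anchors[fg_a, 0]
        ay = anchors[fg_a, 1]
        x1 = Tensor(ax) - dist[:, 0] * Tensor(s)
        y1 = Tensor(ay) - dist[:, 1] * Tensor(s)
        x2 = Tensor(ax) + dist[:, 2] * Tensor(s)
        y2 = Tensor(ay) + dist[:, 3] * Tensor(s)
        l_ciou = self._ciou_loss_t(x1, y1, x2, y2, gt_boxes).mean()

        # DFL targets: side distances in stride units, clipped into bin range
        t_ltrb = np.stack([
            (ax - gt_boxes[:, 0]) / s, (ay - gt_boxes[:, 1]) / s,
            (gt_boxes[:, 2] - ax) / s, (gt_boxes[:, 3] - ay) / s,
        ], axis=-1)
        t_ltrb = np.clip(t_ltrb, 0.0, rm - 1 - 1e-3)
        lo = np.floor(t_ltrb).astype(int)
        hi = lo + 1
        w_hi = (t_ltrb - lo).astype(cls_logits.data.dtype)
        w_lo = 1.0 - w_hi
        logp = T.log_softmax(reg_fg, axis=-1)
        ce = -(T.gather_last(logp, lo) * Tensor(w_lo)
               + T.gather_last(logp, hi) * Tensor(w_hi))
        l_dfl = ce.mean()

        return LossBreakdown(l_bce, l_fl, l_ciou, l_dfl)

    @staticmethod
    def _ciou_loss_t(x1, y1, x2, y2, gt):
        """Tensor CIoU loss of predicted corners vs constant gt boxes."""
        g1, g2, g3, g4 = (Tensor(gt[:, k]) for k in range(4))
        w = T.maximum(x2 - x1, 1e-6)
        h = T.maximum(y2 - y1, 1e-6)
        gw = Tensor(gt[:, 2] - gt[:, 0])
        gh = Tensor(gt[:, 3] - gt[:, 1])
        ix1 = T.maximum(x1, g1)
        iy1 = T.maximum(y1, g2)
        ix2 = T.minimum(x2, g3)
        iy2 = T.minimum(y2, g4)
        inter = T.maximum(ix2 - ix1, 0.0) * T.maximum(iy2 - iy1, 0.0)
        union = w * h + gw * gh - inter
        iou = inter / (union + EPS)
        cx1 = T.minimum(x1, g1)
        cy1 = T.minimum(y1, g2)
        cx2 = T.maximum(x2, g3)
        cy2 = T.maximum(y2, g4)
        c2 = (cx2 - cx1) ** 2.0 + (cy2 - cy1) ** 2.0 + EPS
        rho2 = ((x1 + x2 - g1 - g3) * 0.5) ** 2.0 + ((y1 + y2 - g2 - g4) * 0.5) ** 2.0
        v = (4.0 / np.pi ** 2) * (T.arctan(gw / gh) - T.arctan(w / h)) ** 2.0
        alpha = Tensor((v.data / (1.0 - iou.data + v.data + EPS)))  # detached
        return 1.0 - (iou - rho2 / c2 - alpha * v)
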