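"""Single-stage detector assembly: backbone, PAN neck, decoupled heads.

The neck exposes three named nodes (P3, P4, P5 at strides 8, 16, 32);
CAM and SGAM blocks are inserted at configured nodes.  Prediction is
anchor-free: each head emits per-anchor class logits and four discrete
side-distance distributions decoded by expectation (DFL-style).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from . import nn
from .attention import CAM, SGAM
from .losses import DetectionLoss, FocalParams
from .nn import tensor as T
from .nn.tensor import Tensor

SGAM_POSITIONS = ("1_layer_P5", "3_layers_P345", "none")
NECK_NODES = ("P3", "P4", "P5")

__all__ = ["ModelConfig", "Detection", "Detector", "build_model", "predict",
           "count_params", "nms", "PRESETS"]

PRESETS = {
    "s": dict(width=0.50, depth=0.33, input_size=512),
    "tiny": dict(width=0.25, depth=0.33, input_size=256),
    "nano": dict(width=0.125, depth=0.33, input_size=128),
}


@dataclass
class ModelConfig:
    input_size: int = 512
    width: float = 0.50
    depth: float = 0.33
    n_classes: int = 2
    sgam_position: str = "1_layer_P5"
    cam_positions: List[str] = field(default_factory=lambda: ["P3", "P4", "P5"])
    attn_ratio: int = 4
    shuffle_groups: int = 2
    reg_max: int = 16
    gamma: float = 1.5
    alpha: Optional[Sequence[float]] = None
    focal_only: bool = False
    bce_only: bool = False
    cls_reduction: str = "positives"
    conf_threshold: float = 0.25
    nms_iou: float = 0.45
    seed: int = 0

    @classmethod
    def preset(cls, name: str, **overrides) -> "ModelConfig":
        if name not in PRESETS:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
        kw = dict(PRESETS[name])
        kw.update(overrides)
        return cls(**kw)

    def validate(self):
        if self.sgam_position not in SGAM_POSITIONS:
            raise ValueError(
                f"unknown sgam_position {self.sgam_position!r}; "
                f"valid labels: {list(SGAM_POSITIONS)}")
        bad = [p for p in self.cam_positions if p not in NECK_NODES]
        if bad:
            raise ValueError(
                f"unknown cam_positions {bad}; valid nodes: {list(NECK_NODES)}")
        if self.input_size % 32 != 0:
            raise ValueError("input_size must be a multiple of 32")
        return self


@dataclass
class Detection:
    class_id: int
    confidence: float
    box: tuple  # (x1, y1, x2, y2) pixels, origin top-left, half-open

    def area(self) -> float:
        return max(0.0, self.box[2] - self.box[0]) * max(0.0, self.box[3] - self.box[1])


def _channels(width: float):
    base = (64, 128, 256, 512, 1024)
    return tuple(max(8, int(round(c * width / 8)) * 8) for c in base)


def _depth(n: int, depth: float) -> int:
    return max(1, round(n * depth))


class _Head(nn.Module):
    """Decoupled classification / regression branches for one scale."""

    def __init__(self, c, nc, reg_max, rng, dtype=np.float32):
        super().__init__()
        self.cls_stem = nn.ConvBNSiLU(c, c, 3, rng=rng, dtype=dtype)
        self.cls_pred = nn.Conv2d(c, nc, 1, rng=rng, dtype=dtype)
        self.reg_stem = nn.ConvBNSiLU(c, c, 3, rng=rng, dtype=dtype)
        self.reg_pred = nn.Conv2d(c, 4 * reg_max, 1, rng=rng, dtype=dtype)
        # rare-object prior on the classification bias
        self.cls_pred.bias.data[:] = -np.log((1 - 0.01) / 0.01)

    def forward(self, x):
        return self.cls_pred(self.cls_stem(x)), self.reg_pred(self.reg_stem(x))


class Detector(nn.Module):
    strides = (8, 16, 32)

    def __init__(self, cfg: ModelConfig, dtype=np.float32):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        c1, c2, c3, c4, c5 = _channels(cfg.width)
        d = cfg.depth
        CBS, C2f = nn.ConvBNSiLU, nn.C2f

        # backbone
        self.stem = CBS(3, c1, 3, 2, rng=rng, dtype=dtype)
        self.down2 = CBS(c1, c2, 3, 2, rng=rng, dtype=dtype)
        self.stage2 = C2f(c2, c2, _depth(3, d), rng=rng, dtype=dtype)
        self.down3 = CBS(c2, c3, 3, 2, rng=rng, dtype=dtype)
        self.stage3 = C2f(c3, c3, _depth(6, d), rng=rng, dtype=dtype)
        self.down4 = CBS(c3, c4, 3, 2, rng=rng, dtype=dtype)
        self.stage4 = C2f(c4, c4, _depth(6, d), rng=rng, dtype=dtype)
        self.down5 = CBS(c4, c5, 3, 2, rng=rng, dtype=dtype)
        self.stage5 = C2f(c5, c5, _depth(3, d), rng=rng, dtype=dtype)
        self.sppf = nn.SPPF(c5, rng=rng, dtype=dtype)

        # PAN neck
        nd = _depth(3, d)
        self.fuse_p4 = C2f(c5 + c4, c4, nd, shortcut=False, rng=rng, dtype=dtype)
        self.fuse_p3 = C2f(c4 + c3, c3, nd, shortcut=False, rng=rng, dtype=dtype)
        self.pan_down3 = CBS(c3, c3, 3, 2, rng=rng, dtype=dtype)
        self.fuse_n4 = C2f(c3 + c4, c4, nd, shortcut=False, rng=rng, dtype=dtype)
        self.pan_down4 = CBS(c4, c4, 3, 2, rng=rng, dtype=dtype)
        self.fuse_n5 = C2f(c4 + c5, c5, nd, shortcut=False, rng=rng, dtype=dtype)

        node_channels = {"P3": c3, "P4": c4, "P5": c5}
        self.cam_blocks = [
            CAM(node_channels[p], ratio=cfg.attn_ratio, rng=rng, dtype=dtype)
            for p in cfg.cam_positions
        ]
        self._cam_map = dict(zip(cfg.cam_positions, self.cam_blocks))
        if cfg.sgam_position == "1_layer_P5":
            sgam_nodes = ["P5"]
        elif cfg.sgam_position == "3_layers_P345":
            sgam_nodes = ["P3", "P4", "P5"]
        else:
            sgam_nodes = []
        self.sgam_blocks = [
            SGAM(node_channels[p], ratio=cfg.attn_ratio,
                 groups=cfg.shuffle_groups, rng=rng, dtype=dtype)
            for p in sgam_nodes
        ]
        self._sgam_map = dict(zip(sgam_nodes, self.sgam_blocks))

        self.heads = [_Head(node_channels[p], cfg.n_classes, cfg.reg_max,
                            rng=rng, dtype=dtype) for p in NECK_NODES]

    # -- forward ---------------------------------------------------------
    def _enhance(self, name, x):
        if name in self._cam_map:
            x = self._cam_map[name](x)
        if name in self._sgam_map:
            x = self._sgam_map[name](x)
        return x

    def forward(self, x):
        x = T.astensor(x)
        b3 = self.stage3(self.down3(self.stage2(self.down2(self.stem(x)))))
        b4 = self.stage4(self.down4(b3))
        b5 = self.sppf(self.stage5(self.down5(b4)))

        t4 = self.fuse_p4(T.concat([T.upsample_nearest2(b5), b4], axis=1))
        p3 = self.fuse_p3(T.concat([T.upsample_nearest2(t4), b3], axis=1))
        p4 = self.fuse_n4(T.concat([self.pan_down3(p3), t4], axis=1))
        p5 = self.fuse_n5(T.concat([self.pan_down4(p4), b5], axis=1))

        feats = [self._enhance(n, f) for n, f in
                 zip(NECK_NODES, (p3, p4, p5))]
        return [self.heads[i](f) for i, f in enumerate(feats)]

    # -- anchors / decoding ----------------------------------------------
    def anchor_grid(self, input_size=None):
        """Anchor centers (A, 2) in pixels and per-anchor strides (A,)."""
        size = input_size or self.cfg.input_size
        pts, strs = [], []
        for s in self.strides:
            n = size // s
            xs = (np.arange(n) + 0.5) * s
            gx, gy = np.meshgrid(xs, xs)
            pts.append(np.stack([gx.ravel(), gy.ravel()], axis=-1))
            strs.append(np.full(n * n, s, dtype=float))
        return np.concatenate(pts), np.concatenate(strs)

    @staticmethod
    def flatten_preds(raw):
        """Per-scale head outputs -> ((N, A, nc), (N, A, 4, reg_max))."""
        cls_flat, reg_flat = [], []
        for cls, reg in raw:
            n, nc, h, w = cls.shape
            cls_flat.append(cls.transpose((0, 2, 3, 1)).reshape((n, h * w, nc)))
            rm4 = reg.shape[1]
            reg_flat.append(reg.transpose((0, 2, 3, 1))
                            .reshape((n, h * w, 4, rm4 // 4)))
        return T.concat(cls_flat, axis=1), T.concat(reg_flat, axis=1)

    def decode(self, cls_flat, reg_flat, anchors, strides):
        """Numpy decode: per-anchor class probabilities and xyxy boxes."""
        from scipy.special import expit

        prob = expit(cls_flat)
        r = reg_flat - reg_flat.max(axis=-1, keepdims=True)
        e = np.exp(r)
        p = e / e.sum(axis=-1, keepdims=True)
        dist = (p * np.arange(p.shape[-1])).sum(axis=-1)
        boxes = np.stack([
            anchors[None, :, 0] - dist[..., 0] * strides[None, :],
            anchors[None, :, 1] - dist[..., 1] * strides[None, :],
            anchors[None, :, 0] + dist[..., 2] * strides[None, :],
            anchors[None, :, 1] + dist[..., 3] * strides[None, :],
        ], axis=-1)
        return prob, boxes

    def detection_loss(self) -> DetectionLoss:
        cfg = self.cfg
        alpha = np.ones(cfg.n_classes) if cfg.alpha is None else np.asarray(cfg.alpha)
        fp = FocalParams(alpha=alpha, gamma=cfg.gamma,
                         focal_only=cfg.focal_only, bce_only=cfg.bce_only)
        return DetectionLoss(cfg.n_classes, cfg.reg_max, fp,
                             cls_reduction=cfg.cls_reduction)

    def save(self, path):
        np.savez(path, **self.state_dict())

    def load(self, path):
        with np.load(path) as data:
            self.load_state_dict({k: data[k] for k in data.files})


def build_model(cfg: ModelConfig, dtype=np.float32) -> Detector:
    """Build a detector; rejects unknown attention position labels."""
    return Detector(cfg, dtype=dtype)


def count_params(detector: Detector) -> int:
    return detector.count_params()


def nms(boxes: np.ndarray, scores: np.ndarray, iou_thr: float) -> np.ndarray:
    """Greedy non-maximum suppression; returns kept indices."""
    order = np.argsort(-scores, kind="stable")
    keep = []
    while order.size:
        i = order[0]
        keep.append(i)
        if order.size == 1:
            break
        rest = order[1:]
        ix1 = np.maximum(boxes[i, 0], boxes[rest, 0])
        iy1 = np.maximum(boxes[i, 1], boxes[rest, 1])
        ix2 = np.minimum(boxes[i, 2], boxes[rest, 2])
        iy2 = np.minimum(boxes[i, 3], boxes[rest, 3])
        inter = np.clip(ix2 - ix1, 0, None) * np.clip(iy2 - iy1, 0, None)
        area_i = (boxes[i, 2] - boxes[i, 0]) * (boxes[i, 3] - boxes[i, 1])
        area_r = (boxes[rest, 2] - boxes[rest, 0]) * (boxes[rest, 3] - boxes[rest, 1])
        iou = inter / (area_i + area_r - inter + 1e-9)
        order = rest[iou < iou_thr]
    return np.asarray(keep, dtype=int)


def _resize_image(img: np.ndarray, size: int) -> np.ndarray:
    from PIL import Image

    if img.shape[0] == size and img.shape[1] == size:
        return img
    pil = Image.fromarray(img.astype(np.uint8))
    return np.asarray(pil.resize((size, size), Image.BILINEAR))


def predict(detector: Detector, image: np.ndarray,
            conf_threshold: Optional[float] = None,
            nms_iou: Optional[float] = None) -> List[Detection]:
    """Run one image through the detector and return thresholded detections."""
    cfg = detector.cfg
    conf_threshold = cfg.conf_threshold if conf_threshold is None else conf_threshold
    nms_iou = cfg.nms_iou if nms_iou is None else nms_iou
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    size = cfg.input_size
    sx = img.shape[1] / size
    sy = img.shape[0] / size
    img = _resize_image(img, size)
    x = (img.astype(np.float32) / 255.0).transpose(2, 0, 1)[None]

    was_training = detector.training
    detector.eval()
    raw = detector.forward(Tensor(x))
    if was_training:
        detector.train()
    cls_flat, reg_flat = detector.flatten_preds(raw)
    anchors, strides = detector.anchor_grid()
    prob, boxes = detector.decode(cls_flat.data, reg_flat.data, anchors, strides)
    prob, boxes = prob[0], boxes[0]

    out: List[Detection] = []
    for c in range(cfg.n_classes):
        mask = prob[:, c] >= conf_threshold
        if not mask.any():
            continue
        b = boxes[mask]
        s = prob[mask, c]
        keep = nms(b, s, nms_iou)
        for k in keep:
            x1 = float(np.clip(b[k, 0], 0, size) * sx)
            y1 = float(np.clip(b[k, 1], 0, size) * sy)
            x2 = float(np.clip(b[k, 2], 0, size) * sx)
            y2 = float(np.clip(b[k, 3], 0, size) * sy)
            if x2 <= x1 or y2 <= y1:
                continue
            out.append(Detection(int(c), float(s[k]), (x1, y1, x2, y2)))
    out.sort(key=lambda d: -d.confidence)
    return out
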