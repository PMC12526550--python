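"""Training protocol: patient-level splits, augmentation, random
hyper-parameter search and the Adam fit loop with early stopping on
validation F1.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .evaluation import aggregate_object_metrics
from .losses import DetectionLoss
from .model import Detection, Detector
from .nn.modules import Adam
from .nn.tensor import Tensor

__all__ = ["SplitSpec", "split_dataset", "SearchSpace", "random_search",
           "AugmentConfig", "augment", "mosaic", "flip_horizontal",
           "TrainConfig", "fit", "evaluate_f1"]


# -------------------------------------------------------------------------
# patient-level splitting
# -------------------------------------------------------------------------

@dataclass
class SplitSpec:
    test_fraction: float = 0.2      # patient-level holdout
    val_fraction: float = 0.3       # within the remaining pool
    seed: int = 0


def split_dataset(images: Sequence, spec: SplitSpec = SplitSpec()):
    """Split by patient id into (train, val, test); patient-disjoint."""
    for im in images:
        if getattr(im, "patient_id", None) is None:
            raise ValueError("every image needs a patient_id for "
                             "patient-level splitting")
    patients = sorted({im.patient_id for im in images})
    rng = np.random.default_rng(spec.seed)
    rng.shuffle(patients)
    n_test = int(round(len(patients) * spec.test_fraction))
    test_p = set(patients[:n_test])
    pool = patients[n_test:]
    n_val = int(round(len(pool) * spec.val_fraction))
    val_p = set(pool[:n_val])
    train = [im for im in images if im.patient_id in set(pool) - val_p]
    val = [im for im in images if im.patient_id in val_p]
    test = [im for im in images if im.patient_id in test_p]
    return train, val, test


# -------------------------------------------------------------------------
# augmentation (normalized cxcywh boxes)
# -------------------------------------------------------------------------

@dataclass
class AugmentConfig:
    hflip_p: float = 0.5
    vflip_p: float = 0.0
    rotation_deg: float = 10.0
    scale: float = 0.2
    translate: float = 0.1
    shear_deg: float = 2.0
    mosaic_p: float = 0.5
    mixup_p: float = 0.1
    copy_paste_p: float = 0.1
    min_box_px: float = 4.0


def flip_horizontal(image: np.ndarray, boxes):
    """Mirror the image; cx -> 1 - cx, everything else unchanged."""
    return image[:, ::-1].copy(), [(c, 1.0 - cx, cy, w, h)
                                   for c, cx, cy, w, h in boxes]


def _boxes_to_corners(boxes, size):
    out = []
    for c, cx, cy, w, h in boxes:
        x1, x2 = (cx - w / 2) * size, (cx + w / 2) * size
        y1, y2 = (cy - h / 2) * size, (cy + h / 2) * size
        out.append((c, x1, y1, x2, y2))
    return out


def _corners_to_boxes(corners, size, min_px):
    out = []
    for c, x1, y1, x2, y2 in corners:
        x1, x2 = np.clip([x1, x2], 0, size)
        y1, y2 = np.clip([y1, y2], 0, size)
        if x2 - x1 >= min_px and y2 - y1 >= min_px:
            out.append((c, (x1 + x2) / 2 / size, (y1 + y2) / 2 / size,
                        (x2 - x1) / size, (y2 - y1) / size))
    return out


def _affine(image, boxes, matrix, cfg):
    """Apply a 2x2 + translation affine about the canvas center.

    matrix is [[a, b, tx], [c, d, ty]] acting on (x, y) points:
    out = M (p - center) + t + center.
    """
    size = image.shape[0]
    center = (size - 1) / 2.0
    swap = np.array([[0.0, 1.0], [1.0, 0.0]])
    a_yx = swap @ np.linalg.inv(matrix[:, :2]) @ swap  # inverse map, (y, x)
    c_yx = np.array([center, center])
    offset = c_yx - a_yx @ (c_yx + matrix[::-1, 2])
    chans = [ndimage.affine_transform(image[..., k].astype(float), a_yx,
                                      offset=offset, order=1,
                                      mode="constant", cval=0.0)
             for k in range(image.shape[2])]
    warped = np.clip(np.stack(chans, axis=-1), 0, 255).astype(image.dtype)
    corners_out = []
    for c, x1, y1, x2, y2 in _boxes_to_corners(boxes, size):
        pts = np.array([[x1, y1], [x2, y1], [x1, y2], [x2, y2]], dtype=float)
        pts -= center
        pts = pts @ matrix[:, :2].T + matrix[:, 2]
        pts += center
        corners_out.append((c, pts[:, 0].min(), pts[:, 1].min(),
                            pts[:, 0].max(), pts[:, 1].max()))
    return warped, _corners_to_boxes(corners_out, size, cfg.min_box_px)


def _random_affine(image, boxes, rng, cfg: AugmentConfig):
    ang = np.deg2rad(rng.uniform(-cfg.rotation_deg, cfg.rotation_deg))
    sc = 1.0 + rng.uniform(-cfg.scale, cfg.scale)
    sh = np.deg2rad(rng.uniform(-cfg.shear_deg, cfg.shear_deg))
    size = image.shape[0]
    tx = rng.uniform(-cfg.translate, cfg.translate) * size
    ty = rng.uniform(-cfg.translate, cfg.translate) * size
    rot = np.array([[np.cos(ang), -np.sin(ang)],
                    [np.sin(ang), np.cos(ang)]])
    shear = np.array([[1.0, np.tan(sh)], [0.0, 1.0]])
    m = np.zeros((2, 3))
    m[:, :2] = sc * rot @ shear
    m[:, 2] = (tx, ty)
    return _affine(image, boxes, m, cfg)


def mosaic(samples, rng, cfg: AugmentConfig = AugmentConfig()):
    """Compose 4 (image, boxes) samples on one canvas around a random center."""
    if len(samples) != 4:
        raise ValueError("mosaic needs exactly 4 source samples")
    from PIL import Image

    size = samples[0][0].shape[0]
    canvas = np.zeros((size, size, 3), dtype=np.uint8)
    cx = int(rng.uniform(0.3, 0.7) * size)
    cy = int(rng.uniform(0.3, 0.7) * size)
    quads = [(0, 0, cx, cy), (cx, 0, size, cy), (0, cy, cx, size),
             (cx, cy, size, size)]
    out_corners = []
    for (img, boxes), (x1, y1, x2, y2) in zip(samples, quads):
        qw, qh = x2 - x1, y2 - y1
        if qw < 2 or qh < 2:
            continue
        pil = Image.fromarray(img)
        patch = np.asarray(pil.resize((qw, qh), Image.BILINEAR))
        canvas[y1:y2, x1:x2] = patch
        sx, sy = qw / img.shape[1], qh / img.shape[0]
        for c, bx1, by1, bx2, by2 in _boxes_to_corners(boxes, img.shape[0]):
            out_corners.append((c, x1 + bx1 * sx, y1 + by1 * sy,
                                x1 + bx2 * sx, y1 + by2 * sy))
    return canvas, _corners_to_boxes(out_corners, size, cfg.min_box_px)


def _mixup(a, b, rng):
    lam = float(rng.beta(8.0, 8.0))
    img = np.clip(lam * a[0].astype(float) + (1 - lam) * b[0].astype(float),
                  0, 255).astype(np.uint8)
    return img, list(a[1]) + list(b[1])


def _copy_paste(image, boxes, donor, rng, cfg):
    """Paste one donor cell (its box region) at a free location."""
    img = image.copy()
    size = img.shape[0]
    donor_boxes = _boxes_to_corners(donor[1], donor[0].shape[0])
    if not donor_boxes:
        return image, boxes
    c, x1, y1, x2, y2 = donor_boxes[rng.integers(0, len(donor_boxes))]
    x1, y1 = int(max(0, x1)), int(max(0, y1))
    x2, y2 = int(min(size, x2)), int(min(size, y2))
    h, w = y2 - y1, x2 - x1
    if h < 4 or w < 4 or h >= size or w >= size:
        return image, boxes
    ty = int(rng.integers(0, size - h))
    tx = int(rng.integers(0, size - w))
    patch = donor[0][y1:y2, x1:x2]
    region = img[ty:ty + h, tx:tx + w]
    img[ty:ty + h, tx:tx + w] = np.maximum(region, patch)
    newbox = (c, (tx + w / 2) / size, (ty + h / 2) / size, w / size, h / size)
    return img, list(boxes) + [newbox]


def augment(image: np.ndarray, boxes, rng,
            cfg: AugmentConfig = AugmentConfig(),
            pool: Optional[Sequence] = None):
    """Full training-time pipeline on one sample.

    pool supplies extra (image, boxes) samples for mosaic / MixUp /
    Copy-paste; with an empty pool the single-image pipeline applies.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    img, bxs = np.asarray(image), list(boxes)
    if pool and rng.random() < cfg.mosaic_p:
        picks = [pool[rng.integers(0, len(pool))] for _ in range(3)]
        img, bxs = mosaic([(img, bxs)] + list(picks), rng, cfg)
    if pool and rng.random() < cfg.mixup_p:
        other = pool[rng.integers(0, len(pool))]
        img, bxs = _mixup((img, bxs), other, rng)
    if pool and rng.random() < cfg.copy_paste_p:
        donor = pool[rng.integers(0, len(pool))]
        img, bxs = _copy_paste(img, bxs, donor, rng, cfg)
    if rng.random() < cfg.hflip_p:
        img, bxs = flip_horizontal(img, bxs)
    if rng.random() < cfg.vflip_p:
        img2, bxs2 = flip_horizontal(img.transpose(1, 0, 2),
                                     [(c, cy, cx, h, w) for c, cx, cy, w, h in bxs])
        img, bxs = img2.transpose(1, 0, 2), [(c, cy, cx, h, w)
                                             for c, cx, cy, w, h in bxs2]
    img, bxs = _random_affine(img, bxs, rng, cfg)
    return img, bxs


# -------------------------------------------------------------------------
# random hyper-parameter search
# -------------------------------------------------------------------------

@dataclass
class SearchSpace:
    learning_rate: Tuple[float, ...] = (0.0001, 0.0005, 0.001, 0.005, 0.01)
    batch_size: Tuple[int, ...] = (16, 32, 64)
    weight_decay: Tuple[float, ...] = (0.0, 0.0005, 1e-5, 1e-4, 1e-3)
    n_trials: int = 20


def random_search(space: SearchSpace, objective: Callable[[dict], float],
                  seed: int = 0):
    """Sample n_trials candidates; return (best candidate, trial log).

    objective maps {learning_rate, batch_size, weight_decay} -> validation
    F1.  Failed trials are logged and skipped; ties break toward the
    earlier trial.
    """
    if not (space.learning_rate and space.batch_size and space.weight_decay):
        raise ValueError("search space must be non-empty")
    rng = np.random.default_rng(seed)
    log = []
    best, best_f1, best_idx = None, -np.inf, None
    for t in range(space.n_trials):
        cand = {
            "learning_rate": float(rng.choice(space.learning_rate)),
            "batch_size": int(rng.choice(space.batch_size)),
            "weight_decay": float(rng.choice(space.weight_decay)),
        }
        entry = dict(trial=t, **cand)
        try:
            f1 = float(objective(cand))
            entry["val_f1"] = f1
            if f1 > best_f1:
                best, best_f1, best_idx = cand, f1, t
        except Exception as exc:  # log and continue
            entry["error"] = str(exc)
        log.append(entry)
    if best is None:
        raise RuntimeError("all search trials failed")
    return {"candidate": best, "val_f1": best_f1, "trial": best_idx}, log


# -------------------------------------------------------------------------
# fit loop
# -------------------------------------------------------------------------

@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 64
    weight_decay: float = 0.0005
    epochs: int = 500
    patience: int = 50
    augment: bool = True
    augment_cfg: AugmentConfig = field(default_factory=AugmentConfig)
    val_conf: float = 0.25
    val_iou: float = 0.5
    seed: int = 0


def _batch_arrays(batch, size):
    """Stack AnnotatedImages into (N,3,S,S) float input + target lists."""
    xs, targets = [], []
    for img, boxes in batch:
        if img.shape[0] != size:
            from PIL import Image as PILImage
            img = np.asarray(PILImage.fromarray(img).resize(
                (size, size), PILImage.BILINEAR))
        xs.append(img.astype(np.float32).transpose(2, 0, 1) / 255.0)
        cls = np.array([b[0] for b in boxes], dtype=int)
        if len(boxes):
            b = np.array([[bx[1], bx[2], bx[3], bx[4]] for bx in boxes])
            xyxy = np.stack([
                (b[:, 0] - b[:, 2] / 2) * size, (b[:, 1] - b[:, 3] / 2) * size,
                (b[:, 0] + b[:, 2] / 2) * size, (b[:, 1] + b[:, 3] / 2) * size,
            ], axis=-1)
        else:
            xyxy = np.zeros((0, 4))
        targets.append((cls, xyxy))
    return np.stack(xs), targets


def evaluate_f1(detector: Detector, images, conf=0.25, iou_thr=0.5,
                cls: Optional[int] = 0, batch_size: int = 16):
    """Object-level F1 over a list of AnnotatedImages (batched forward)."""
    size = detector.cfg.input_size
    anchors, strides = detector.anchor_grid()
    was_training = detector.training
    detector.eval()
    pairs = []
    from .model import nms
    for i0 in range(0, len(images), batch_size):
        chunk = images[i0:i0 + batch_size]
        x, _ = _batch_arrays([(im.image, im.boxes) for im in chunk], size)
        raw = detector.forward(Tensor(x))
        cls_flat, reg_flat = detector.flatten_preds(raw)
        prob, boxes = detector.decode(cls_flat.data, reg_flat.data,
                                      anchors, strides)
        for k, im in enumerate(chunk):
            dets = []
            for c in range(detector.cfg.n_classes):
                m = prob[k, :, c] >= conf
                if m.any():
                    keep = nms(boxes[k][m], prob[k, m, c], detector.cfg.nms_iou)
                    for j in keep:
                        dets.append(Detection(c, float(prob[k, m, c][j]),
                                              tuple(boxes[k][m][j])))
            gt = [(b[0], (b[1] - b[3] / 2) * size, (b[2] - b[4] / 2) * size,
                   (b[1] + b[3] / 2) * size, (b[2] + b[4] / 2) * size)
                  for b in im.boxes]
            pairs.append((dets, gt))
    if was_training:
        detector.train()
    _, metrics = aggregate_object_metrics(pairs, iou_thr, cls)
    return metrics["f1"] if metrics["f1"] is not None else 0.0


def fit(detector: Detector, datasets, config: TrainConfig = TrainConfig()):
    """Adam training with early stopping on validation F1.

    datasets: (train_images, val_images) lists of AnnotatedImage.
    Returns (best_state_dict, history); the checkpoint is the epoch with
    the highest validation F1.
    """
    train_set, val_set = datasets
    if not train_set or not val_set:
        raise ValueError("train and validation sets must be non-empty")
    size = detector.cfg.input_size
    rng = np.random.default_rng(config.seed)
    criterion: DetectionLoss = detector.detection_loss()
    opt = Adam(detector.parameters(), lr=config.learning_rate,
               weight_decay=config.weight_decay)
    anchors, strides = detector.anchor_grid()
    pool = [(im.image, im.boxes) for im in train_set]

    history = []
    best_f1, best_epoch, best_state = -np.inf, -1, None
    for epoch in range(config.epochs):
        detector.train()
        order = rng.permutation(len(train_set))
        losses = []
        for i0 in range(0, len(order), config.batch_size):
            batch = []
            for idx in order[i0:i0 + config.batch_size]:
                im = train_set[idx]
                if config.augment:
                    img, boxes = augment(im.image, im.boxes, rng,
                                         config.augment_cfg, pool=pool)
                else:
                    img, boxes = im.image, im.boxes
                batch.append((img, boxes))
            x, targets = _batch_arrays(batch, size)
            raw = detector.forward(Tensor(x))
            cls_flat, reg_flat = detector.flatten_preds(raw)
            breakdown = criterion((cls_flat, reg_flat), targets,
                                  anchors, strides)
            total = breakdown.l_total
            if not np.isfinite(total.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {breakdown!r}")
            opt.zero_grad()
            total.backward()
            opt.step()
            losses.append(breakdown.to_floats())

        val_f1 = evaluate_f1(detector, val_set, config.val_conf,
                             config.val_iou)
        rec = {
            "epoch": epoch,
            "train_loss": float(np.mean([b.l_total for b in losses])),
            "l_bce": float(np.mean([b.l_bce for b in losses])),
            "l_fl": float(np.mean([b.l_fl for b in losses])),
            "l_ciou": float(np.mean([b.l_ciou for b in losses])),
            "l_dfl": float(np.mean([b.l_dfl for b in losses])),
            "val_f1": float(val_f1),
        }
        history.append(rec)
        if val_f1 > best_f1:
            best_f1, best_epoch = val_f1, epoch
            best_state = copy.deepcopy(detector.state_dict())
        elif epoch - best_epoch > config.patience:
            break
    if best_state is not None:
        detector.load_state_dict(best_state)
    return best_state, {"epochs": history, "best_epoch": best_epoch,
                        "best_val_f1": float(best_f1)}
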