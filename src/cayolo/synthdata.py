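"""Synthetic fluorescence-microscopy scene generator.

Renders dark-background images containing bright elliptical cells of two
classes that share size/shape/intensity distributions and differ only in
edge granularity (band-limited boundary perturbation) and surface punctae
density — plus controllable class imbalance.  Class 0 is the rare rough
"clue" phenotype, class 1 the smooth epithelial majority class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .evaluation import image_level_label

CLUE, EPITHELIAL = 0, 1

__all__ = [
    "SceneSpec", "AnnotatedImage", "render_cell", "render_scene",
    "generate_dataset", "load_dataset", "difficulty_profile",
    "write_yolo_labels", "read_yolo_labels", "CLUE", "EPITHELIAL",
]


@dataclass
class SceneSpec:
    canvas_size: int = 256
    n_cells: Tuple[int, int] = (3, 7)
    clue_fraction: float = 0.3
    cell_radius: Tuple[float, float] = (16.0, 30.0)
    edge_roughness: float = 0.25        # clue class; epithelial is 0
    punctae_density: float = 0.05       # clue punctae per interior pixel
    punctae_density_epi: float = 0.002
    background_noise: float = 6.0
    bacteria_density: float = 3e-4      # free spots per canvas pixel
    overlap_iou: float = 0.3
    intensity: Tuple[float, float] = (120.0, 190.0)


@dataclass
class AnnotatedImage:
    image: np.ndarray                   # (H, W, 3) uint8
    boxes: List[Tuple[int, float, float, float, float]]  # cls, cx, cy, w, h
    label: str                          # "positive" | "negative"
    patient_id: Optional[str] = None
    name: Optional[str] = None


def _boundary_profile(rng, roughness: float, n_theta: int = 720) -> np.ndarray:
    """Band-limited radial perturbation, amplitude `roughness`."""
    if roughness <= 0:
        return np.zeros(n_theta)
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    prof = np.zeros(n_theta)
    for k in rng.integers(6, 17, size=6):
        prof += rng.normal() * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    prof /= max(np.abs(prof).max(), 1e-9)
    return roughness * prof


def render_cell(cell_class: int, spec: SceneSpec, rng,
                radius: Optional[float] = None):
    """Render one cell; returns (bool mask, float RGB patch).

    Epithelial cells get a smooth elliptical boundary and near-uniform
    interior; clue cells get a perturbed boundary and dense bright punctae.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    r0 = radius if radius is not None else rng.uniform(*spec.cell_radius)
    if 2 * r0 * 1.6 >= spec.canvas_size:
        raise ValueError(f"cell radius {r0:.1f} too large for canvas "
                         f"{spec.canvas_size}")
    aspect = rng.uniform(0.7, 1.0)
    a, b = r0, r0 * aspect
    phi = rng.uniform(0, np.pi)
    rough = spec.edge_roughness if cell_class == CLUE else 0.0
    prof = _boundary_profile(rng, rough)

    pad = int(np.ceil(max(a, b) * (1 + abs(rough)) + 3))
    size = 2 * pad + 1
    yy, xx = np.mgrid[-pad:pad + 1, -pad:pad + 1].astype(float)
    u = (xx * np.cos(phi) + yy * np.sin(phi)) / a
    v = (-xx * np.sin(phi) + yy * np.cos(phi)) / b
    dist = np.hypot(u, v)
    theta = np.arctan2(v, u)
    idx = ((theta % (2 * np.pi)) / (2 * np.pi) * len(prof)).astype(int) % len(prof)
    boundary = np.maximum(1.0 + prof[idx], 0.3)
    mask = dist <= boundary

    base = rng.uniform(*spec.intensity)
    interior = base * (1.0 - 0.15 * np.clip(dist, 0, 1.2) ** 2)
    interior += rng.normal(0, 3.0, size=(size, size))

    density = (spec.punctae_density if cell_class == CLUE
               else spec.punctae_density_epi)
    n_punctae = rng.poisson(density * mask.sum())
    inside = np.argwhere(mask)
    if n_punctae and len(inside):
        pick = inside[rng.integers(0, len(inside), size=n_punctae)]
        dot = np.zeros((size, size))
        for (py, px) in pick:
            rad = int(rng.integers(1, 3))
            dot[max(0, py - rad + 1):py + rad, max(0, px - rad + 1):px + rad] = \
                rng.uniform(60, 110)
        interior = np.maximum(interior, base * 0.6 + dot)

    g = np.clip(interior, 0, 255) * mask
    patch = np.stack([0.35 * g, g, 0.45 * g], axis=-1)
    return mask, patch


def _mask_bbox(mask: np.ndarray):
    ys, xs = np.where(mask)
    return xs.min(), ys.min(), xs.max() + 1, ys.max() + 1


def _box_iou(b1, b2):
    ix1, iy1 = max(b1[0], b2[0]), max(b1[1], b2[1])
    ix2, iy2 = min(b1[2], b2[2]), min(b1[3], b2[3])
    inter = max(0, ix2 - ix1) * max(0, iy2 - iy1)
    a1 = (b1[2] - b1[0]) * (b1[3] - b1[1])
    a2 = (b2[2] - b2[0]) * (b2[3] - b2[1])
    return inter / (a1 + a2 - inter + 1e-9)


def render_scene(spec: SceneSpec, rng, force_positive: Optional[bool] = None
                 ) -> AnnotatedImage:
    """Compose one annotated scene from independent cell renders."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    cs = spec.canvas_size
    img = np.clip(rng.normal(10.0, spec.background_noise, size=(cs, cs, 3)),
                  0, 40)
    img[..., 1] *= 1.3

    n_cells = int(rng.integers(spec.n_cells[0], spec.n_cells[1] + 1))
    classes = (rng.random(n_cells) < spec.clue_fraction).astype(int)
    classes = np.where(classes == 1, CLUE, EPITHELIAL)
    if force_positive is True and not np.any(classes == CLUE):
        classes[rng.integers(0, n_cells)] = CLUE
    if force_positive is False:
        classes[:] = EPITHELIAL

    boxes_px: List[Tuple[int, int, int, int, int]] = []
    for cls in classes:
        for _ in range(30):
            mask, patch = render_cell(int(cls), spec, rng)
            ph = mask.shape[0]
            cy = int(rng.integers(ph // 2, cs - ph // 2))
            cx = int(rng.integers(ph // 2, cs - ph // 2))
            x1, y1, x2, y2 = _mask_bbox(mask)
            box = (cx - ph // 2 + x1, cy - ph // 2 + y1,
                   cx - ph // 2 + x2, cy - ph // 2 + y2)
            if all(_box_iou(box, b[1:]) <= spec.overlap_iou for b in boxes_px):
                top, left = cy - ph // 2, cx - ph // 2
                region = img[top:top + ph, left:left + ph]
                region[mask] = np.maximum(region[mask], patch[mask])
                boxes_px.append((int(cls),) + box)
                break

    n_spots = rng.poisson(spec.bacteria_density * cs * cs)
    for _ in range(n_spots):
        sy, sx = rng.integers(0, cs, size=2)
        img[max(0, sy - 1):sy + 1, max(0, sx - 1):sx + 1] = \
            np.array([60, 170, 80]) * rng.uniform(0.6, 1.0)

    boxes = [(c, (x1 + x2) / 2 / cs, (y1 + y2) / 2 / cs,
              (x2 - x1) / cs, (y2 - y1) / cs)
             for c, x1, y1, x2, y2 in boxes_px]
    label = image_level_label(boxes, clue_class=CLUE)
    return AnnotatedImage(np.clip(img, 0, 255).astype(np.uint8), boxes, label)


def write_yolo_labels(path, boxes):
    with open(path, "w") as fh:
        for c, cx, cy, w, h in boxes:
            fh.write(f"{int(c)} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}\n")


def read_yolo_labels(path):
    boxes = []
    for line in Path(path).read_text().split("\n"):
        if line.strip():
            parts = line.split()
            boxes.append((int(parts[0]),) + tuple(float(p) for p in parts[1:5]))
    return boxes


def generate_dataset(n_images: int, spec: SceneSpec, out_dir, seed: int):
    """Write PNG images + YOLO labels + a JSON manifest; reproducible."""
    from PIL import Image

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "labels").mkdir(parents=True, exist_ok=True)
    streams = [np.random.default_rng(s)
               for s in np.random.SeedSequence(seed).spawn(n_images + 1)]
    prng = streams[-1]

    # synthetic patients contribute 2-8 images each
    patient_of = []
    pid = 0
    while len(patient_of) < n_images:
        k = int(prng.integers(2, 9))
        patient_of.extend([f"patient_{pid:04d}"] * k)
        pid += 1
    patient_of = patient_of[:n_images]

    manifest = {"seed": seed, "n_images": n_images, "spec": asdict(spec),
                "images": []}
    counts = {CLUE: 0, EPITHELIAL: 0}
    for i in range(n_images):
        scene = render_scene(spec, streams[i])
        name = f"img_{i:05d}"
        Image.fromarray(scene.image).save(out / "images" / f"{name}.png")
        write_yolo_labels(out / "labels" / f"{name}.txt", scene.boxes)
        for b in scene.boxes:
            counts[b[0]] += 1
        manifest["images"].append({
            "name": name, "patient_id": patient_of[i], "label": scene.label,
            "n_clue": sum(1 for b in scene.boxes if b[0] == CLUE),
            "n_epithelial": sum(1 for b in scene.boxes if b[0] == EPITHELIAL),
        })
    manifest["class_counts"] = {"clue": counts[CLUE],
                                "epithelial": counts[EPITHELIAL]}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def load_dataset(root) -> List[AnnotatedImage]:
    from PIL import Image

    root = Path(root)
    manifest = json.loads((root / "manifest.json").read_text())
    out = []
    for entry in manifest["images"]:
        img = np.asarray(Image.open(root / "images" / f"{entry['name']}.png"))
        boxes = read_yolo_labels(root / "labels" / f"{entry['name']}.txt")
        out.append(AnnotatedImage(img, boxes, entry["label"],
                                  entry["patient_id"], entry["name"]))
    return out


# -- separability certification ------------------------------------------

def _edge_statistic(mask: np.ndarray, patch: np.ndarray) -> float:
    """High-frequency energy in a 5-px boundary band of the green channel."""
    band = mask & ~ndimage.binary_erosion(mask, iterations=5)
    if not band.any():
        band = mask
    g = patch[..., 1]
    lap = ndimage.laplace(g)
    return float(np.abs(lap[band]).mean())


def _auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Mann-Whitney AUC of pos vs neg scores."""
    from scipy.stats import rankdata

    scores = np.concatenate([pos, neg])
    ranks = rankdata(scores)
    n1, n2 = len(pos), len(neg)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n2))


def difficulty_profile(spec: SceneSpec, n_pairs: int = 200, seed: int = 0):
    """Certify that size/intensity do not separate classes but edges do.

    Renders matched clue/epithelial pairs (shared radius draw) and reports
    the between-class AUC of size, mean intensity and the boundary
    high-frequency statistic, plus a distributional-overlap score
    1 - 2|AUC - 1/2| for each.
    """
    rng = np.random.default_rng(seed)
    feats = {CLUE: {"size": [], "intensity": [], "edge": []},
             EPITHELIAL: {"size": [], "intensity": [], "edge": []}}
    for _ in range(n_pairs):
        radius = rng.uniform(*spec.cell_radius)
        for cls in (CLUE, EPITHELIAL):
            mask, patch = render_cell(cls, spec, rng, radius=radius)
            feats[cls]["size"].append(mask.sum())
            feats[cls]["intensity"].append(patch[..., 1][mask].mean())
            feats[cls]["edge"].append(_edge_statistic(mask, patch))
    report = {}
    for key in ("size", "intensity", "edge"):
        pos = np.asarray(feats[CLUE][key], dtype=float)
        neg = np.asarray(feats[EPITHELIAL][key], dtype=float)
        auc = _auc(pos, neg)
        report[f"auc_{key}"] = auc
        report[f"overlap_{key}"] = 1.0 - 2.0 * abs(auc - 0.5)
    return report
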