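"""Synthetic pest-image datasets and feature-stack fixtures.

Real field-collected pest photos are small targets on cluttered
backgrounds, with a fraction of mislabeled images, target-absent frames,
and blurred or low-resolution shots.  The generator reproduces exactly
those pathologies at desk scale: each class is a distinct textured blob
shape (ellipse / rectangle / cross / ring / triangle, with a
class-specific texture frequency and color) planted at a random location
on a cluttered background; configurable fractions of images get a
shuffled (wrong) label, no target at all, or Gaussian blur.  Ground truth
(true label, assigned label, target presence, pixel box) is recorded so
tests can measure localization and corruption handling directly.

`generate_feature_stack_fixture` plants a hot rectangular region directly
in feature space, returning the stack together with the analytically
expected threshold mask and bounding box — direct test vectors for the
localization equations that bypass any CNN.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image
from scipy.ndimage import gaussian_filter

from .backbone import FeatureBlock, FeatureStack
from .eflm import BoundingBox, MaskMap

__all__ = ["SyntheticSpec", "GroundTruthRecord", "generate_dataset",
           "generate_feature_stack_fixture"]

_SHAPES = ("ellipse", "rect", "cross", "ring", "triangle")


@dataclass
class SyntheticSpec:
    n_classes: int = 5
    images_per_class: int = 58
    image_side: int = 64
    clutter_density: float = 0.5
    label_error_rate: float = 0.1
    no_target_rate: float = 0.1
    blur_rate: float = 0.1
    train_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self):
        for name in ("clutter_density", "label_error_rate", "no_target_rate",
                     "blur_rate", "train_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_classes < 1 or self.images_per_class < 1:
            raise ValueError("n_classes and images_per_class must be >= 1")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("n_classes", "images_per_class", "image_side",
                 "clutter_density", "label_error_rate", "no_target_rate",
                 "blur_rate", "train_fraction", "seed")}


@dataclass
class GroundTruthRecord:
    path: str
    true_label: int
    assigned_label: int
    target_present: bool
    box: tuple[int, int, int, int]   # (r0, r1, c0, c1); all zero iff absent
    split: str = "train"


def _class_style(cls: int, n_classes: int, rng: np.random.Generator) -> dict:
    """Deterministic per-class blob style: shape, color, texture frequency."""
    hues = np.linspace(0.0, 1.0, n_classes, endpoint=False)
    hue = hues[cls]
    # simple hue -> saturated RGB
    k = hue * 6.0
    rgb = np.clip([abs(k - 3) - 1, 2 - abs(k - 2), 2 - abs(k - 4)], 0, 1)
    return {"shape": _SHAPES[cls % len(_SHAPES)],
            "color": 0.35 + 0.6 * rgb,
            "freq": 2.0 + 1.5 * (cls // len(_SHAPES)) + 0.7 * cls}


def _shape_mask(shape: str, size: int) -> np.ndarray:
    r = np.arange(size)
    yy, xx = np.meshgrid(r, r, indexing="ij")
    c = (size - 1) / 2.0
    u, v = (yy - c) / (size / 2.0), (xx - c) / (size / 2.0)
    if shape == "ellipse":
        return (u ** 2 / 0.9 + v ** 2 / 0.5) <= 1.0
    if shape == "rect":
        return (np.abs(u) <= 0.85) & (np.abs(v) <= 0.55)
    if shape == "cross":
        return (np.abs(u) <= 0.3) | (np.abs(v) <= 0.3)
    if shape == "ring":
        rad = np.sqrt(u ** 2 + v ** 2)
        return (rad <= 0.95) & (rad >= 0.45)
    if shape == "triangle":
        return (u >= -0.8) & (np.abs(v) <= 0.55 * (u + 0.9))
    raise ValueError(f"unknown shape {shape!r}")


def _render(spec: SyntheticSpec, style: dict, rng: np.random.Generator,
            with_target: bool) -> tuple[np.ndarray, tuple[int, int, int, int]]:
    s = spec.image_side
    img = np.empty((s, s, 3))
    img[...] = rng.uniform(0.25, 0.45, size=3)
    # clutter: random gray-green distractor rectangles and dots
    n_clutter = int(round(spec.clutter_density * 12))
    for _ in range(n_clutter):
        ch, cw = rng.integers(3, s // 4, size=2)
        r0 = int(rng.integers(0, s - ch))
        c0 = int(rng.integers(0, s - cw))
        img[r0:r0 + ch, c0:c0 + cw] = rng.uniform(0.15, 0.6, size=3)
    img += rng.normal(0.0, 0.03, img.shape)
    box = (0, 0, 0, 0)
    if with_target:
        size = int(rng.integers(s // 4, s // 2))
        mask = _shape_mask(style["shape"], size)
        r0 = int(rng.integers(0, s - size))
        c0 = int(rng.integers(0, s - size))
        yy, xx = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
        texture = 0.75 + 0.25 * np.sin(2 * np.pi * style["freq"] * (yy + xx) / size)
        patch = style["color"][None, None, :] * texture[:, :, None]
        region = img[r0:r0 + size, c0:c0 + size]
        region[mask] = patch[mask]
        rows, cols = np.nonzero(mask)
        box = (r0 + int(rows.min()), r0 + int(rows.max()) + 1,
               c0 + int(cols.min()), c0 + int(cols.max()) + 1)
    return np.clip(img, 0.0, 1.0), box


def generate_dataset(spec: SyntheticSpec, out_dir) -> tuple[Path, Path]:
    """Write PNGs, a `manifest.csv` (path,label,split) and ground truth.

    Returns (manifest_path, ground_truth_path).  Fully reproducible from
    (spec, spec.seed): the same call yields byte-identical images.
    """
    out = Path(out_dir)
    try:
        (out / "images").mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc
    rng = np.random.default_rng(spec.seed)
    records: list[GroundTruthRecord] = []
    n_train = int(spec.images_per_class * spec.train_fraction)
    for cls in range(spec.n_classes):
        style = _class_style(cls, spec.n_classes, rng=rng)
        cls_dir = out / "images" / f"class_{cls:02d}"
        cls_dir.mkdir(exist_ok=True)
        for i in range(spec.images_per_class):
            no_target = rng.random() < spec.no_target_rate
            label_err = rng.random() < spec.label_error_rate
            blur = rng.random() < spec.blur_rate
            img, box = _render(spec, style, rng, with_target=not no_target)
            if blur:
                img = gaussian_filter(img, sigma=(1.2, 1.2, 0.0))
            assigned = cls
            if label_err and spec.n_classes > 1:
                assigned = int((cls + rng.integers(1, spec.n_classes))
                               % spec.n_classes)
            path = cls_dir / f"img_{i:04d}.png"
            Image.fromarray((img * 255).astype(np.uint8)).save(path)
            records.append(GroundTruthRecord(
                str(path.relative_to(out)), cls, assigned,
                target_present=not no_target, box=box,
                split="train" if i < n_train else "test"))
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["path", "label", "split"])
        for r in records:
            w.writerow([r.path, r.assigned_label, r.split])
    gt_path = out / "ground_truth.csv"
    with open(gt_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["path", "true_label", "assigned_label", "target_present",
                    "box_r0", "box_r1", "box_c0", "box_c1", "split"])
        for r in records:
            w.writerow([r.path, r.true_label, r.assigned_label,
                        int(r.target_present), *r.box, r.split])
    with open(out / "spec.yaml", "w") as fh:
        yaml.safe_dump(spec.to_dict(), fh)
    return manifest, gt_path


def generate_feature_stack_fixture(
        h: int, w: int, blocks: int, blob_box, hot_value: float,
        background_value: float, seed: int, noise_sigma: float = 0.0,
        channels: int = 4, lam: float = 0.5,
) -> tuple[FeatureStack, MaskMap, BoundingBox]:
    """Plant a hot region directly in feature space; return expectations.

    `blob_box` is one (r0, r1, c0, c1) tuple, or a list of one per block
    (disjoint per-block boxes make the expected intersection empty).  The
    expected mask/box are evaluated analytically from the noiseless
    construction: activation = channel sum, threshold lam * mean, strict
    inequality, intersection over blocks, minimal box with whole-map
    fallback.
    """
    if hot_value < background_value or background_value < 0:
        raise ValueError("need hot_value >= background_value >= 0")
    boxes = blob_box if isinstance(blob_box, list) else [blob_box] * blocks
    if len(boxes) != blocks:
        raise ValueError("need one blob box per block")
    rng = np.random.default_rng(seed)
    stack_blocks = []
    expected = np.ones((h, w), dtype=np.uint8)
    for b, (r0, r1, c0, c1) in enumerate(boxes):
        if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
            raise ValueError(f"blob box {boxes[b]} outside ({h}, {w})")
        base = np.full((h, w), background_value)
        base[r0:r1, c0:c1] = hot_value
        values = base[None, :, :] + np.zeros((channels, 1, 1))
        if noise_sigma > 0:
            values = values + rng.normal(0.0, noise_sigma, values.shape)
            values = np.maximum(values, 0.0)
        stack_blocks.append(FeatureBlock(values, block_id=b))
        activation = channels * base
        expected &= (activation > lam * activation.mean()).astype(np.uint8)
    rows, cols = np.nonzero(expected)
    if rows.size == 0:
        box = BoundingBox(0, h, 0, w)
    else:
        box = BoundingBox(int(rows.min()), int(rows.max()) + 1,
                          int(cols.min()), int(cols.max()) + 1)
    return FeatureStack(stack_blocks), MaskMap(expected), box
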