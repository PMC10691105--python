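"""Feature localization by activation thresholding and mask intersection.

The target region of an image is found entirely in feature space: each
last-stage block's maps are summed over channels into an activation map
A, thresholded at lambda * mean(A) (strict inequality; ties drop out),
the per-block binary masks are intersected, and the minimal bounding box
of the surviving positions is cropped from every block and bilinearly
resized back to (h, w).  An empty intersection falls back to the
whole-map box, so localization can never lose the image.

The threshold multiplier lambda is scheduled: during training it rises
linearly from 0 at the first epoch to 1 at the last, so early epochs keep
everything and later epochs localize aggressively; at test time lambda is
fixed at its median value 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, interp2d
from .backbone import FeatureBlock, FeatureStack

__all__ = ["ActivationMap", "LambdaSchedule", "MaskMap", "BoundingBox",
           "aggregate_channels", "lambda_at", "threshold_mask",
           "intersect_masks", "mask_to_bbox", "crop_and_upsample", "localize",
           "boxes_to_csv"]


@dataclass
class ActivationMap:
    values: np.ndarray
    mean_value: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("ActivationMap must be 2-D")


@dataclass(frozen=True)
class LambdaSchedule:
    """Linear 0 -> 1 ramp over `epochs`; fixed `test_value` at test time."""

    epochs: int
    test_value: float = 0.5

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class MaskMap:
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("MaskMap entries must be 0 or 1")
        self.values = self.values.astype(np.uint8)


@dataclass(frozen=True)
class BoundingBox:
    """0-based, half-open [start, stop) on both axes."""

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int

    def __post_init__(self):
        if not (0 <= self.row_start < self.row_stop
                and 0 <= self.col_start < self.col_stop):
            raise ValueError(f"degenerate bounding box {self}")

    @property
    def height(self) -> int:
        return self.row_stop - self.row_start

    @property
    def width(self) -> int:
        return self.col_stop - self.col_start

    def scaled(self, stride: int) -> "BoundingBox":
        """Back-project feature coordinates to image pixels."""
        return BoundingBox(self.row_start * stride, self.row_stop * stride,
                           self.col_start * stride, self.col_stop * stride)


def aggregate_channels(block: FeatureBlock) -> ActivationMap:
    """Sum the feature maps over channels; cache the spatial mean."""
    a = block.values.sum(axis=0)
    return ActivationMap(a, float(a.mean()))


def lambda_at(schedule: LambdaSchedule, epoch: int, phase: str = "train") -> float:
    """Threshold multiplier at `epoch` (0-based) for a train/val/test phase."""
    if phase == "test":
        return schedule.test_value
    if phase not in ("train", "val"):
        raise ValueError(f"unknown phase {phase!r}")
    if not 0 <= epoch < schedule.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {schedule.epochs})")
    if schedule.epochs == 1:
        return 1.0
    return epoch / (schedule.epochs - 1)


def threshold_mask(a: ActivationMap, lam: float) -> MaskMap:
    """Keep positions strictly above lam * mean; ties and below drop to 0."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    return MaskMap((a.values > lam * a.mean_value).astype(np.uint8))


def intersect_masks(masks: list[MaskMap]) -> MaskMap:
    if not masks:
        raise ValueError("need at least one mask")
    shape = masks[0].values.shape
    for m in masks[1:]:
        if m.values.shape != shape:
            raise ValueError("mask shape mismatch")
    stacked = np.stack([m.values for m in masks])
    return MaskMap((stacked.sum(axis=0) == len(masks)).astype(np.uint8))


def mask_to_bbox(mf: MaskMap) -> BoundingBox:
    """Minimal box covering all 1-entries; whole map if the mask is empty."""
    h, w = mf.values.shape
    rows, cols = np.nonzero(mf.values)
    if rows.size == 0:
        return BoundingBox(0, h, 0, w)
    return BoundingBox(int(rows.min()), int(rows.max()) + 1,
                       int(cols.min()), int(cols.max()) + 1)


def crop_and_upsample(stack: FeatureStack, box: BoundingBox) -> FeatureStack:
    """Crop every block to `box` and bilinearly resize back to (h, w).

    Corner-anchored sampling makes a full-map crop an exact identity.
    """
    h, w = stack.spatial
    if box.row_stop > h or box.col_stop > w:
        raise ValueError(f"box {box} exceeds feature size {(h, w)}")
    out = []
    for blk in stack.blocks:
        crop = blk.values[:, box.row_start:box.row_stop,
                          box.col_start:box.col_stop]
        resized = interp2d(Tensor(crop), h, w).data
        out.append(FeatureBlock(resized, block_id=blk.block_id))
    return FeatureStack(out)


def localize(stack: FeatureStack, lam: float,
             num_blocks: int | None = None) -> tuple[FeatureStack, BoundingBox]:
    """Full localization: per-block masks, intersection, box, crop+resize.

    `num_blocks` intersects only the last k blocks (ablation); default all.
    """
    blocks = stack.blocks
    if num_blocks is not None:
        if not 1 <= num_blocks <= len(blocks):
            raise ValueError(f"num_blocks must be in [1, {len(blocks)}]")
        blocks = blocks[-num_blocks:]
    masks = [threshold_mask(aggregate_channels(b), lam) for b in blocks]
    box = mask_to_bbox(intersect_masks(masks))
    return crop_and_upsample(stack, box), box


def boxes_to_csv(image_ids, boxes, lam: float, path, stride: int = 1) -> None:
    """Export per-image boxes; `stride` back-projects to image pixels."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["image_id", "row_start", "row_stop",
                    "col_start", "col_stop", "lambda"])
        for img_id, box in zip(image_ids, boxes):
            b = box.scaled(stride) if stride != 1 else box
            w.writerow([img_id, b.row_start, b.row_stop,
                        b.col_start, b.col_stop, lam])
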