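"""Backbone adapter: expose the last-stage feature blocks of a CNN.

The localization stage needs the output of *every* block in the deepest
convolutional stage (the conv_5a/b/c analogue of a ResNet), all sharing
one spatial size.  Any backbone can participate through the adapter
contract — ``list_stage_blocks()`` naming the hook points and
``forward_with_hooks(images)`` returning one feature tensor per block —
and the package ships a small three-stage reference CNN whose last stage
has exactly three blocks, so the three-way mask intersection is
exercised without any pretrained weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, no_grad
from .nn import Conv2d, Module

__all__ = ["FeatureBlock", "FeatureStack", "Embedding", "TinyBackbone",
           "BackboneConfigError", "build_backbone", "extract_last_stage",
           "pool_embedding", "apply_embedding_dropout"]


class BackboneConfigError(ValueError):
    """Raised when a backbone lacks an identifiable multi-block last stage."""


@dataclass
class FeatureBlock:
    """One block's output feature map, channels-first ``(c, h, w)``."""

    values: np.ndarray
    block_id: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("FeatureBlock expects a (c, h, w) array")
        if min(self.values.shape) < 1:
            raise ValueError("FeatureBlock dimensions must all be >= 1")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("FeatureBlock values must be finite")

    @property
    def channels(self) -> int:
        return self.values.shape[0]

    @property
    def spatial(self) -> tuple[int, int]:
        return self.values.shape[1], self.values.shape[2]


@dataclass
class FeatureStack:
    """Ordered last-stage blocks for one image; all share (h, w)."""

    blocks: list[FeatureBlock] = field(default_factory=list)

    def __post_init__(self):
        if len(self.blocks) < 1:
            raise ValueError("FeatureStack needs at least one block")
        h, w = self.blocks[0].spatial
        for b in self.blocks:
            if b.spatial != (h, w):
                raise ValueError("all blocks in a stack must share (h, w)")

    @property
    def spatial(self) -> tuple[int, int]:
        return self.blocks[0].spatial


@dataclass
class Embedding:
    vector: np.ndarray

    def __post_init__(self):
        self.vector = np.asarray(self.vector, dtype=np.float64).ravel()
        if not np.all(np.isfinite(self.vector)):
            raise ValueError("Embedding must be finite")


class TinyBackbone(Module):
    """Three-stage reference CNN; the last stage holds 3 same-size blocks.

    Strided 3x3 stem and two strided stages reduce a square input by 8x;
    the last stage is three stride-1 3x3 conv blocks at 32 channels, each
    followed by ReLU, so every hooked feature map is nonnegative.
    """

    STAGE_BLOCKS = ("stage3.block0", "stage3.block1", "stage3.block2")

    def __init__(self, channels: int = 32, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        c = channels
        self.stem = Conv2d(3, c // 4, 3, stride=2, padding=1, rng=rng)
        self.down1 = Conv2d(c // 4, c // 2, 3, stride=2, padding=1, rng=rng)
        self.down2 = Conv2d(c // 2, c, 3, stride=2, padding=1, rng=rng)
        self.blocks = [Conv2d(c, c, 3, stride=1, padding=1, rng=rng)
                       for _ in range(3)]
        self.embed_dim = c

    def list_stage_blocks(self) -> list[str]:
        return list(self.STAGE_BLOCKS)

    def forward_with_hooks(self, images: Tensor) -> list[Tensor]:
        """Return the post-ReLU output of each last-stage block, NCHW."""
        x = self.stem.forward(images).relu()
        x = self.down1.forward(x).relu()
        x = self.down2.forward(x).relu()
        outs = []
        for blk in self.blocks:
            x = blk.forward(x).relu()
            outs.append(x)
        return outs


_BACKBONES = {"tiny": TinyBackbone}


def build_backbone(name: str, rng: np.random.Generator | None = None) -> Module:
    try:
        cls = _BACKBONES[name]
    except KeyError:
        raise BackboneConfigError(
            f"unknown backbone {name!r}; a backbone must provide "
            "list_stage_blocks() and forward_with_hooks() exposing every "
            "block of its last convolutional stage "
            f"(registered: {sorted(_BACKBONES)})") from None
    return cls(rng=rng)


def extract_last_stage(backbone, images: np.ndarray) -> list[FeatureStack]:
    """Run `images` (N, 3, H, W) through the backbone; one stack per image."""
    if not (hasattr(backbone, "list_stage_blocks")
            and hasattr(backbone, "forward_with_hooks")):
        raise BackboneConfigError(
            "backbone does not satisfy the adapter contract: needs "
            "list_stage_blocks() and forward_with_hooks(images)")
    names = backbone.list_stage_blocks()
    if len(names) < 1:
        raise BackboneConfigError("backbone reports an empty last stage")
    with no_grad():
        outs = backbone.forward_with_hooks(Tensor(images))
    stacks = []
    for i in range(images.shape[0]):
        blocks = [FeatureBlock(out.data[i], block_id=b)
                  for b, out in enumerate(outs)]
        stacks.append(FeatureStack(blocks))
    return stacks


def pool_embedding(block: FeatureBlock) -> Embedding:
    """Global average pooling: entry k is the spatial mean of channel k."""
    return Embedding(block.values.mean(axis=(1, 2)))


def apply_embedding_dropout(e: Embedding, rate: float, training: bool,
                            seed: int) -> Embedding:
    """Inverted dropout on an embedding vector; identity at inference."""
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
    if not training or rate == 0.0:
        return Embedding(e.vector.copy())
    rng = np.random.default_rng(seed)
    mask = (rng.random(e.vector.shape) >= rate) / (1.0 - rate)
    return Embedding(e.vector * mask)
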