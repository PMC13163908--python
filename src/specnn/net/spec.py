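"""Declarative network descriptions and the adaptive channel-attention kernel rule.

A :class:`NetworkSpec` fully determines an architecture (given a seed for
initialisation) and round-trips through JSON, so ablation variants can be
compared structurally before any training happens.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

__all__ = [
    "eca_kernel_size",
    "BlockSpec",
    "NetworkSpec",
    "build_ecnn1d",
    "build_cnn1d",
    "build_vgg1d",
    "build_resnet1d",
]


def eca_kernel_size(channels: int) -> int:
    """Adaptive attention kernel size from the channel count.

    ``k`` is the odd integer nearest to ``(log2(C) + 1) / 2``; a value
    falling exactly between candidates is resolved upward (half-up rounding,
    with even results bumped to the next odd).  Examples: C=16 or 32 -> 3,
    C=64 -> 5.
    """
    if not isinstance(channels, (int,)) or channels < 1:
        raise ValueError(f"channel count must be a positive integer, got {channels!r}")
    v = (math.log2(channels) + 1.0) / 2.0
    k = math.floor(v + 0.5)  # round half up
    if k % 2 == 0:
        k += 1
    return max(k, 1)


@dataclass
class BlockSpec:
    """One convolutional block of a 1D network."""

    out_channels: int
    kernel_size: int = 3
    pool_size: int = 2
    n_convs: int = 1
    eca: bool = False
    eca_kernel: int = 0  # 0 means "derive adaptively from out_channels"
    dropout: float = 0.0
    residual: bool = False

    def effective_eca_kernel(self) -> int:
        if not self.eca:
            return 0
        return self.eca_kernel or eca_kernel_size(self.out_channels)


@dataclass
class NetworkSpec:
    """Declarative description of a 1D conv classifier."""

    architecture: str
    n_bands: int
    n_classes: int
    blocks: list[BlockSpec]
    head_pool: str = "gap"  # 'gap' (global average pool) or 'flatten'
    head_hidden: int = 0    # 0 = single fully connected layer
    head_dropout: float = 0.0

    def __post_init__(self) -> None:
        self.blocks = [b if isinstance(b, BlockSpec) else BlockSpec(**b) for b in self.blocks]
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.head_pool not in ("gap", "flatten"):
            raise ValueError(f"unknown head pooling {self.head_pool!r}")
        if any(b.out_channels < 1 for b in self.blocks):
            raise ValueError("block channel counts must be positive")
        L = self.n_bands
        for b in self.blocks:
            L //= b.pool_size
        if L < 1:
            raise ValueError(
                f"n_bands={self.n_bands} too small for {len(self.blocks)} pooling stages"
            )

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "NetworkSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def with_eca(self, enabled: bool) -> "NetworkSpec":
        """Copy of this spec with every block's attention flag set."""
        d = self.to_dict()
        for b in d["blocks"]:
            b["eca"] = enabled
            b["eca_kernel"] = 0
        return NetworkSpec.from_dict(d)


# ----------------------------------------------------------------------
# Builders
# ----------------------------------------------------------------------

def build_ecnn1d(n_bands: int, n_classes: int,
                 channels: tuple[int, ...] = (16, 32, 64)) -> NetworkSpec:
    """Attention-enhanced 1D CNN: per block Conv1d(k=3) -> BN -> ReLU ->
    channel attention -> MaxPool(2); head is global average pooling into a
    single fully connected classifier.  Channel widths must be non-decreasing
    (feature channels expand with depth)."""
    if n_bands < 2 ** len(channels):
        raise ValueError(f"n_bands={n_bands} too small for {len(channels)} halvings")
    if any(b < a for a, b in zip(channels, channels[1:])):
        raise ValueError(f"channel widths must be non-decreasing, got {channels}")
    blocks = [BlockSpec(out_channels=c, kernel_size=3, pool_size=2, eca=True)
              for c in channels]
    return NetworkSpec("ecnn1d", n_bands, n_classes, blocks, head_pool="gap")


def build_cnn1d(n_bands: int, n_classes: int,
                channels: tuple[int, ...] = (16, 32, 64)) -> NetworkSpec:
    """Plain 1D CNN: the attention-enhanced network with every attention
    stage removed (the ablation baseline)."""
    spec = build_ecnn1d(n_bands, n_classes, channels)
    spec = spec.with_eca(False)
    spec.architecture = "cnn1d"
    return spec


def build_vgg1d(n_bands: int, n_classes: int, eca: bool = False,
                channels: tuple[int, ...] = (32, 64, 128),
                dropout: float = 0.3, hidden: int = 128) -> NetworkSpec:
    """VGG-style 1D CNN: three blocks of two Conv1d(k=3) layers with batch
    norm and max pooling, dropout after each block; flattened features feed a
    hidden fully connected layer.  ``eca=True`` appends one channel-attention
    stage per block."""
    if n_bands < 2 ** len(channels):
        raise ValueError(f"n_bands={n_bands} too small for {len(channels)} halvings")
    blocks = [
        BlockSpec(out_channels=c, kernel_size=3, pool_size=2, n_convs=2,
                  eca=eca, dropout=dropout)
        for c in channels
    ]
    return NetworkSpec("vgg1d" + ("_eca" if eca else ""), n_bands, n_classes, blocks,
                       head_pool="flatten", head_hidden=hidden, head_dropout=dropout)


def build_resnet1d(n_bands: int, n_classes: int, eca: bool = False,
                   channels: tuple[int, ...] = (16, 32, 64)) -> NetworkSpec:
    """Lightweight residual 1D network: residual blocks (two convs each,
    1x1 projection when channel counts change) separated by stride-2 pooling,
    global average pooling head.  ``eca=True`` inserts channel attention
    inside each block before the residual sum."""
    if n_bands < 2 ** len(channels):
        raise ValueError(f"n_bands={n_bands} too small for {len(channels)} halvings")
    blocks = [
        BlockSpec(out_channels=c, kernel_size=3, pool_size=2, eca=eca, residual=True)
        for c in channels
    ]
    return NetworkSpec("resnet1d" + ("_eca" if eca else ""), n_bands, n_classes,
                       blocks, head_pool="gap")
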