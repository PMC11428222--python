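"""Backbone registry: small from-scratch CNN feature extractors.

Each entry maps a name to a factory building the convolutional trunk that
turns a slice batch (S, 3, H, W) into feature maps (S, C', H', W').  The
trunks are deliberately desk-scale (thousands to tens of thousands of
parameters) so that training on synthetic exams runs in seconds on one CPU;
all start with a fixed 2x2 average-pooling stem that halves the input
resolution before the first convolution.

``tiny`` is the default test backbone (3 conv blocks, ~6k parameters);
``tiny-wide`` is the same topology at double width; ``vgg-mini`` uses paired
3x3 convolutions per block in the VGG style.
"""

from __future__ import annotations

import numpy as np

from .nn import AvgPool2d, Conv2d, MaxPool2d, ReLU, Sequential

__all__ = ["BACKBONES", "build_backbone", "backbone_names"]


def _tiny(rng, dtype, widths=(8, 16, 32)):
    w1, w2, w3 = widths
    return Sequential(
        AvgPool2d(2),
        Conv2d(3, w1, rng=rng, dtype=dtype), ReLU(), MaxPool2d(),
        Conv2d(w1, w2, rng=rng, dtype=dtype), ReLU(), MaxPool2d(),
        Conv2d(w2, w3, rng=rng, dtype=dtype), ReLU(), MaxPool2d(),
    )


def _vgg_mini(rng, dtype):
    return Sequential(
        AvgPool2d(2),
        Conv2d(3, 8, rng=rng, dtype=dtype), ReLU(),
        Conv2d(8, 8, rng=rng, dtype=dtype), ReLU(), MaxPool2d(),
        Conv2d(8, 16, rng=rng, dtype=dtype), ReLU(),
        Conv2d(16, 16, rng=rng, dtype=dtype), ReLU(), MaxPool2d(),
        Conv2d(16, 32, rng=rng, dtype=dtype), ReLU(), MaxPool2d(),
    )


# name -> (factory(rng, dtype) -> Sequential, output channels C',
#          total spatial downsampling factor)
BACKBONES = {
    "tiny": (lambda rng, dtype: _tiny(rng, dtype), 32, 16),
    "tiny-wide": (lambda rng, dtype: _tiny(rng, dtype, widths=(16, 32, 64)), 64, 16),
    "vgg-mini": (_vgg_mini, 32, 16),
}


def backbone_names() -> list[str]:
    return sorted(BACKBONES)


def build_backbone(name: str, rng=None, dtype=np.float32):
    """Build a registered backbone; returns (trunk, C', downsample factor)."""
    if name not in BACKBONES:
        raise ValueError(f"unknown backbone {name!r}; available: {backbone_names()}")
    factory, cout, down = BACKBONES[name]
    rng = rng or np.random.default_rng()
    return factory(rng, dtype), cout, down
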