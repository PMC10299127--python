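"""Backbone registry: feature-map geometry for the seven classic ImageNet
architectures plus a trainable desk-scale surrogate ("TinyConv").

Each named architecture is described by its exact chain of spatial
down-sampling operations (kernel, stride, padding) from input to the last
convolutional stage, so the final feature-map side can be computed for any
input side without weights.  The surrogate is a real 3-block conv-pool
network implemented on the numpy kernels in :mod:`.nn`; it is the only
backbone whose features can be extracted offline (pretrained ImageNet
weights are not shippable in this artifact — see the registry entries'
``weights`` field).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import nn

__all__ = [
    "BackboneSpec",
    "BACKBONES",
    "get_backbone_spec",
    "feature_geometry",
    "TinyConvBackbone",
]


class BackboneError(ValueError):
    pass


# one spatial op: (kernel, stride, padding) with padding in {"same", "valid"}
_Op = tuple[int, int, str]


def _out_side(side: int, op: _Op) -> int:
    k, s, pad = op
    if pad == "same":
        return math.ceil(side / s)
    return (side - k) // s + 1


def _downsample_chain(ops: list[_Op], side: int) -> int:
    for op in ops:
        side = _out_side(side, op)
        if side < 1:
            raise BackboneError(f"input side too small: collapsed at op {op}")
    return side


# Spatial programs: only ops with stride > 1 or valid padding change the side,
# so stride-1 same-padding convolutions are omitted.
_VGG = [(2, 2, "valid")] * 5                       # five 2x2 max pools
_RESNET = [(7, 2, "same"), (3, 2, "same"),          # stem conv + pool
           (1, 2, "same"), (1, 2, "same"), (1, 2, "same")]  # stage strides
_INCEPTION_V3 = [
    (3, 2, "valid"), (3, 1, "valid"),               # stem convs (3rd is same)
    (3, 2, "valid"),                                # pool
    (3, 1, "valid"),                                # conv after 1x1
    (3, 2, "valid"),                                # pool -> 35-grid
    (3, 2, "valid"),                                # reduction A -> 17-grid
    (3, 2, "valid"),                                # reduction B -> 8-grid
]
_INCEPTION_RESNET_V2 = list(_INCEPTION_V3)          # identical spatial program
_XCEPTION = [
    (3, 2, "valid"), (3, 1, "valid"),               # entry stem
    (3, 2, "same"), (3, 2, "same"), (3, 2, "same"), # entry-flow pools
    (3, 2, "same"),                                 # exit-flow pool
]
_TINY = [(2, 2, "valid")] * 3                       # three 2x2 max pools


@dataclass(frozen=True)
class BackboneSpec:
    """Registry entry for a feature-extraction backbone."""

    name: str
    weights: str = "imagenet"  # "imagenet" | "random"
    min_input_side: int = 32
    frozen: bool = True
    out_channels: int = 0
    ops: tuple = field(default=(), repr=False)

    def __post_init__(self) -> None:
        if self.name not in _REGISTRY_DEFS:
            raise BackboneError(
                f"unknown backbone {self.name!r}; registered: {sorted(_REGISTRY_DEFS)}"
            )
        if self.name == "TinyConv" and self.weights == "imagenet":
            raise BackboneError("TinyConv has no ImageNet weights")


_REGISTRY_DEFS: dict[str, tuple[list[_Op], int, int]] = {
    # name -> (spatial ops, out_channels, min_input_side)
    "VGG16": (_VGG, 512, 32),
    "VGG19": (_VGG, 512, 32),
    "ResNet50": (_RESNET, 2048, 32),
    "ResNet152V2": (_RESNET, 2048, 32),
    "InceptionV3": (_INCEPTION_V3, 2048, 75),
    "InceptionResNetV2": (_INCEPTION_RESNET_V2, 1536, 75),
    "Xception": (_XCEPTION, 2048, 71),
    "TinyConv": (_TINY, 32, 8),
}


def get_backbone_spec(name: str, weights: str | None = None) -> BackboneSpec:
    if name not in _REGISTRY_DEFS:
        raise BackboneError(
            f"unknown backbone {name!r}; registered: {sorted(_REGISTRY_DEFS)}"
        )
    ops, channels, min_side = _REGISTRY_DEFS[name]
    if weights is None:
        weights = "random" if name == "TinyConv" else "imagenet"
    return BackboneSpec(
        name=name,
        weights=weights,
        min_input_side=min_side,
        out_channels=channels,
        ops=tuple(ops),
    )


BACKBONES: tuple[str, ...] = tuple(n for n in _REGISTRY_DEFS if n != "TinyConv")


def feature_geometry(name: str, input_side: int) -> tuple[int, int]:
    """(spatial side, channels) of the final convolutional feature map."""
    spec = get_backbone_spec(name)
    if input_side < spec.min_input_side:
        raise BackboneError(
            f"{name} requires input side >= {spec.min_input_side}, got {input_side}"
        )
    side = _downsample_chain(list(spec.ops), input_side)
    return side, spec.out_channels


class TinyConvBackbone:
    """Three conv(3x3)-relu-maxpool blocks with channels 8 -> 16 -> 32.

    Random He-initialized weights, deterministic in ``seed``.  Supports full
    backward for end-to-end fine-tuning.
    """

    CHANNELS = (8, 16, 32)

    def __init__(self, in_channels: int = 3, seed: int = 0) -> None:
        rng = np.random.default_rng(seed)
        self.params: list[np.ndarray] = []
        c_prev = in_channels
        for c in self.CHANNELS:
            scale = math.sqrt(2.0 / (9 * c_prev))
            self.params.append(rng.standard_normal((3, 3, c_prev, c)) * scale)
            self.params.append(np.zeros(c))
            c_prev = c

    def copy_params(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def feature_shape(self, side: int) -> tuple[int, int, int]:
        s, c = feature_geometry("TinyConv", side)
        return (s, s, c)

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """x: (B, H, W, C_in) -> features (B, h, w, 32)."""
        caches = []
        out = x
        for blk in range(3):
            W, b = self.params[2 * blk], self.params[2 * blk + 1]
            out, c_conv = nn.conv2d_forward(out, W, b)
            out, c_relu = nn.relu_forward(out)
            out, c_pool = nn.maxpool2_forward(out)
            caches.append((c_conv, c_relu, c_pool))
        if want_cache:
            return out, caches
        return out

    def backward(self, dout: np.ndarray, caches) -> list[np.ndarray]:
        grads: list[np.ndarray] = [None] * len(self.params)
        for blk in reversed(range(3)):
            c_conv, c_relu, c_pool = caches[blk]
            dout = nn.maxpool2_backward(dout, c_pool)
            dout = nn.relu_backward(dout, c_relu)
            dout, dW, db = nn.conv2d_backward(dout, self.params[2 * blk], c_conv)
            grads[2 * blk] = dW
            grads[2 * blk + 1] = db
        return grads
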