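"""The attention-fusion hashing network.

Architecture, in forward order:

1. A pluggable convolutional **backbone** exposes two feature maps from
   one pass: the final map ``f_backbone`` and an intermediate "tap" map
   ``f_tap`` taken at a named block (penultimate block by default).
2. **CBAM** — channel attention then spatial attention — reweights the
   tap map.
3. The **fusion head** concatenates globally pooled CBAM and backbone
   descriptors, passes them through a first linear map whose output
   feeds (a) a softmax classifier and (b), concatenated with the raw
   flattened CBAM map, a second linear map of width L (the hash length).
4. The **learnable quantizer** squashes that pre-code through
   ``tanh(alpha * x + b)`` with a learnable steepness ``alpha > 1``
   (guaranteed by the reparameterization ``alpha = 1 + softplus(a)``),
   yielding a continuous code in (-1, 1)^L whose elementwise sign is the
   binary hash code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, avg_pool2d, concat
from ._nn import Conv2d, Linear, Module, Parameter

__all__ = [
    "FeaturePair",
    "HashOutput",
    "TinyBackbone",
    "ChannelAttention",
    "SpatialAttention",
    "CBAM",
    "DAFHNet",
    "ptanh",
    "binarize",
    "ALPHA_INIT",
]

ALPHA_INIT = 1.1  # starting steepness of the quantizer


@dataclass
class FeaturePair:
    """Final and intermediate feature maps from one backbone pass."""

    f_backbone: Tensor  # (N, C_b, h_b, w_b)
    f_tap: Tensor       # (N, C_t, h_t, w_t)


@dataclass
class HashOutput:
    """Per-image code and classification outputs for a batch."""

    code_cont: Tensor   # (N, L), values in (-1, 1)
    code_bin: np.ndarray  # (N, L), values in {-1, +1}
    logits: Tensor      # (N, C)
    probs: Tensor       # (N, C), rows sum to 1

    def select(self, indices) -> "HashOutput":
        """View of a subset of rows, sharing the autodiff graph."""
        idx = np.asarray(indices, dtype=np.intp)
        return HashOutput(
            code_cont=self.code_cont.take(idx),
            code_bin=self.code_bin[idx],
            logits=self.logits.take(idx),
            probs=self.probs.take(idx),
        )


def binarize(code_cont: np.ndarray | Tensor) -> np.ndarray:
    """Elementwise sign with the tie rule sign(0) = +1."""
    data = code_cont.data if isinstance(code_cont, Tensor) else np.asarray(code_cont)
    return np.where(data >= 0.0, 1.0, -1.0)


def ptanh(x: Tensor | np.ndarray, alpha: float | Tensor, b: float | Tensor = 0.0) -> Tensor:
    """Parameterized tanh quantizer ``tanh(alpha * x + b)``; requires alpha > 1."""
    a_val = alpha.data if isinstance(alpha, Tensor) else alpha
    if not np.all(np.asarray(a_val) > 1.0):
        raise ValueError(f"quantizer steepness must satisfy alpha > 1, got {a_val}")
    if not isinstance(x, Tensor):
        x = Tensor(x)
    alpha = alpha if isinstance(alpha, Tensor) else Tensor(alpha)
    b = b if isinstance(b, Tensor) else Tensor(b)
    return (alpha * x + b).tanh()


class TinyBackbone(Module):
    """Four conv/ReLU/avg-pool blocks; CPU-sized stand-in feature extractor.

    Any module exposing ``__call__(x) -> FeaturePair`` and the attributes
    ``out_channels`` / ``tap_channels`` / ``tap_spatial(side)`` plugs into
    :class:`DAFHNet` in its place; the tap defaults to the penultimate block.
    """

    CHANNELS = (8, 16, 32, 32)

    def __init__(self, rng: np.random.Generator, in_channels: int = 1,
                 tap_block: int = -2):
        chans = (in_channels,) + self.CHANNELS
        self.blocks = [Conv2d(chans[i], chans[i + 1], 3, rng) for i in range(4)]
        self.tap_block = tap_block % 4
        self.out_channels = self.CHANNELS[-1]
        self.tap_channels = self.CHANNELS[self.tap_block]

    def tap_spatial(self, side: int) -> int:
        return side // (2 ** (self.tap_block + 1))

    def __call__(self, x: Tensor) -> FeaturePair:
        f_tap = None
        for i, block in enumerate(self.blocks):
            x = avg_pool2d(block(x).relu(), 2)
            if i == self.tap_block:
                f_tap = x
        return FeaturePair(f_backbone=x, f_tap=f_tap)


class ChannelAttention(Module):
    """Shared two-layer bottleneck over average- and max-pooled descriptors."""

    def __init__(self, channels: int, rng: np.random.Generator, reduction: int = 4):
        hidden = max(1, channels // reduction)
        bound1 = np.sqrt(6.0 / (channels + hidden))
        bound2 = np.sqrt(6.0 / (hidden + channels))
        self.w1 = Parameter(rng.uniform(-bound1, bound1, size=(channels, hidden)))
        self.w2 = Parameter(rng.uniform(-bound2, bound2, size=(hidden, channels)))

    def __call__(self, f: Tensor) -> Tensor:
        n, c = f.shape[0], f.shape[1]
        avg = f.mean(axis=3).mean(axis=2)              # (N, C)
        mx = f.max(axis=3).max(axis=2)                 # (N, C)
        shared = ((avg @ self.w1).relu() @ self.w2) + ((mx @ self.w1).relu() @ self.w2)
        return shared.sigmoid().reshape(n, c, 1, 1)


class SpatialAttention(Module):
    """k x k convolution over channelwise mean and max maps (default k=7)."""

    def __init__(self, rng: np.random.Generator, kernel: int = 7):
        self.conv = Conv2d(2, 1, kernel, rng)

    def __call__(self, f: Tensor) -> Tensor:
        mean_map = f.mean(axis=1, keepdims=True)       # (N, 1, H, W)
        max_map = f.max(axis=1, keepdims=True)         # (N, 1, H, W)
        stacked = concat([mean_map, max_map], axis=1)  # (N, 2, H, W)
        return self.conv(stacked).sigmoid()


class CBAM(Module):
    """Channel attention followed by spatial attention, both multiplicative."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 reduction: int = 4, spatial_kernel: int = 7):
        self.channel = ChannelAttention(channels, rng, reduction)
        self.spatial = SpatialAttention(rng, spatial_kernel)

    def __call__(self, f: Tensor) -> Tensor:
        f_c = self.channel(f) * f
        return self.spatial(f_c) * f_c


def _gap(f: Tensor) -> Tensor:
    """Global average pooling to a per-channel descriptor."""
    return f.mean(axis=3).mean(axis=2)


class DAFHNet(Module):
    """Backbone + CBAM + inter-layer fusion + classifier + learnable quantizer."""

    def __init__(self, hash_length: int = 32, n_classes: int = 10,
                 image_side: int = 64, in_channels: int = 1,
                 hidden_dim: int = 64, seed: int = 0, backbone: Module | None = None,
                 classifier_relu: bool = False, separate_quantizer_bias: bool = False):
        if hash_length < 1:
            raise ValueError(f"hash length must be positive, got {hash_length}")
        rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
        self.hash_length = hash_length
        self.n_classes = n_classes
        self.image_side = image_side
        self.in_channels = in_channels
        self.classifier_relu = classifier_relu
        self.separate_quantizer_bias = separate_quantizer_bias
        self.backbone = backbone if backbone is not None else TinyBackbone(rng, in_channels)
        self.cbam = CBAM(self.backbone.tap_channels, rng)
        tap_side = self.backbone.tap_spatial(image_side)
        self.flat_dim = self.backbone.tap_channels * tap_side * tap_side
        concat_dim = self.backbone.tap_channels + self.backbone.out_channels
        self.linear1 = Linear(concat_dim, hidden_dim, rng)
        self.classifier = Linear(hidden_dim, n_classes, rng)
        self.linear2 = Linear(hidden_dim + self.flat_dim, hash_length, rng)
        # alpha = 1 + softplus(a_raw) > 1 by construction
        self.alpha_raw = Parameter(np.log(np.expm1(ALPHA_INIT - 1.0)))
        self.quantizer_bias = (Parameter(np.zeros(hash_length))
                               if separate_quantizer_bias else None)

    @property
    def alpha(self) -> Tensor:
        return self.alpha_raw.softplus() + 1.0

    @property
    def alpha_value(self) -> float:
        return float(1.0 + np.logaddexp(0.0, self.alpha_raw.data))

    def _as_input(self, images: np.ndarray) -> Tensor:
        """Accept (N, H, W) or (N, C, H, W); replicate gray to C channels."""
        arr = np.asarray(images, dtype=np.float64)
        if arr.ndim == 3:
            arr = arr[:, None, :, :]
        if arr.shape[1] == 1 and self.in_channels > 1:
            arr = np.repeat(arr, self.in_channels, axis=1)
        if arr.shape[1] != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channel(s), got {arr.shape[1]}")
        return Tensor(arr)

    def __call__(self, images: np.ndarray | Tensor) -> HashOutput:
        x = images if isinstance(images, Tensor) else self._as_input(images)
        pair = self.backbone(x)
        f_cbam = self.cbam(pair.f_tap)
        fused = concat([_gap(f_cbam), _gap(pair.f_backbone)], axis=1)
        f_lin1 = self.linear1(fused)
        cls_in = f_lin1.relu() if self.classifier_relu else f_lin1
        logits = self.classifier(cls_in)
        probs = logits.softmax(axis=1)
        f_flat = f_cbam.reshape(f_cbam.shape[0], self.flat_dim)
        concat_hash = concat([f_lin1, f_flat], axis=1)
        pre = concat_hash @ self.linear2.weight + self.linear2.bias
        qbias = (self.quantizer_bias if self.separate_quantizer_bias
                 else self.linear2.bias)
        code_cont = (self.alpha * pre + qbias).tanh()
        return HashOutput(code_cont=code_cont, code_bin=binarize(code_cont),
                          logits=logits, probs=probs)

    # convenience for batch encoding without keeping graphs around
    def encode(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        arr = np.asarray(images, dtype=np.float64)
        codes = []
        for start in range(0, arr.shape[0], batch_size):
            out = self(arr[start:start + batch_size])
            codes.append(out.code_cont.data.copy())
        return np.concatenate(codes, axis=0)

    def config_dict(self) -> dict:
        return {
            "hash_length": self.hash_length,
            "n_classes": self.n_classes,
            "image_side": self.image_side,
            "in_channels": self.in_channels,
            "backbone": type(self.backbone).__name__,
            "tap_block": getattr(self.backbone, "tap_block", None),
            "classifier_relu": self.classifier_relu,
            "separate_quantizer_bias": self.separate_quantizer_bias,
            "alpha": self.alpha_value,
        }
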