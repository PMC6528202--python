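"""Generator and discriminator architectures for mask-to-fundus translation.

Four generator families are provided:

* ``unet`` — encoder/decoder with skip connections at every resolution
  level; downsampling by stride-2 convolutions, upsampling by
  nearest-neighbour interpolation followed by a convolution.
* ``resnet6`` / ``resnet9`` — fully convolutional encode - (6 or 9
  residual blocks) - decode, two downsampling levels.
* ``resunet`` — the U-net skeleton with each per-level convolution group
  replaced by 1-3 residual blocks (conv-norm-ReLU x2 branch with an
  additive identity skip), channel widths identical to the base U-net.

Each residual block computes x_{l+1} = x_l + F(x_l, W_l): zeroing every
branch parameter makes the block an exact identity map.

The discriminator is a fully convolutional patch classifier: stride-2
conv/norm/LeakyReLU stack over the channel-concatenation of conditioning
input and candidate image, ending in a sigmoid, so it emits a spatial
map of patch-level real/fake likelihoods strictly inside (0, 1).

All builders take a seedable ``numpy.random.Generator``; weights are
zero-mean Gaussian (std 0.02) and biases zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from . import nd
from .errors import ConfigurationError, InvalidParameterError
from .nd import Module, Tensor

Family = Literal["unet", "resnet6", "resnet9", "resunet"]

MAX_WIDTH_MULT = 8  # channel widths double per level, capped at 8x base_width


@dataclass(frozen=True)
class GeneratorSpec:
    family: Family = "resunet"
    in_channels: int = 3
    out_channels: int = 3
    base_width: int = 32
    depth: int = 4  # down/up-sampling levels (unet/resunet); resnet uses 2
    n_res_blocks: int = 1  # resunet only; 6 or 9 implied by resnet families
    norm: bool = True

    def __post_init__(self):
        if self.family not in ("unet", "resnet6", "resnet9", "resunet"):
            raise InvalidParameterError(f"unknown generator family {self.family!r}")
        if self.in_channels not in (1, 3):
            raise InvalidParameterError("in_channels must be 1 or 3")
        if self.family == "resunet" and self.n_res_blocks not in (1, 2, 3):
            raise InvalidParameterError("resunet n_res_blocks must be in {1, 2, 3}")
        if self.base_width < 1 or self.depth < 1:
            raise InvalidParameterError("base_width and depth must be positive")

    @property
    def divisor(self) -> int:
        """Input H and W must be divisible by this power of two."""
        return 4 if self.family.startswith("resnet") else 2 ** self.depth


@dataclass(frozen=True)
class DiscriminatorSpec:
    in_channels: int = 6  # conditioning channels + 3 image channels
    n_layers: int = 4
    base_width: int = 64

    def __post_init__(self):
        if self.in_channels < 1 or self.n_layers < 1 or self.base_width < 1:
            raise InvalidParameterError("discriminator spec fields must be positive")


def suggested_depth(image_size: int) -> int:
    """Levels giving a 1 x 1 bottleneck: log2(image_size)."""
    d = int(round(math.log2(image_size)))
    if 2 ** d != image_size:
        raise InvalidParameterError("image_size must be a power of two for suggested_depth")
    return d


def _check_divisible(x: Tensor, divisor: int) -> None:
    h, w = x.data.shape[2], x.data.shape[3]
    if h % divisor or w % divisor:
        raise ConfigurationError(
            f"input spatial size {h}x{w} must be divisible by 2^levels = {divisor}"
        )


# ---------------------------------------------------------------------------
# U-net / ResU-net
# ---------------------------------------------------------------------------

class _UnetGenerator(Module):
    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        w = spec.base_width
        widths = [min(w * 2 ** i, w * MAX_WIDTH_MULT) for i in range(spec.depth + 1)]
        use_res = spec.family == "resunet"
        norm = spec.norm

        self.stem = nd.Conv2d(spec.in_channels, widths[0], 3, rng, pad=1)
        self.stem_blocks = self._level_blocks(widths[0], rng, use_res, norm)
        self.down_convs, self.down_norms, self.down_blocks = [], [], []
        for i in range(spec.depth):
            self.down_convs.append(nd.Conv2d(widths[i], widths[i + 1], 4, rng, stride=2, pad=1))
            self.down_norms.append(nd.Norm2d(widths[i + 1]) if norm else None)
            self.down_blocks.append(self._level_blocks(widths[i + 1], rng, use_res, norm))
        self.up_convs, self.up_norms, self.up_blocks = [], [], []
        for i in reversed(range(spec.depth)):
            # input: upsampled deeper features + skip from encoder level i
            self.up_convs.append(nd.Conv2d(widths[i + 1] + widths[i], widths[i], 3, rng, pad=1))
            self.up_norms.append(nd.Norm2d(widths[i]) if norm else None)
            self.up_blocks.append(self._level_blocks(widths[i], rng, use_res, norm))
        self.head = nd.Conv2d(widths[0], spec.out_channels, 3, rng, pad=1)

    @staticmethod
    def _level_blocks(channels, rng, use_res, norm):
        if not use_res:
            return []
        return []  # placeholder, overridden below for resunet

    def forward(self, x: Tensor) -> Tensor:
        _check_divisible(x, self.spec.divisor)
        h = nd.relu(self.stem(x))
        for blk in self.stem_blocks:
            h = blk(h)
        skips = [h]
        for conv, norm, blocks in zip(self.down_convs, self.down_norms, self.down_blocks):
            h = conv(h)
            if norm is not None:
                h = norm(h)
            h = nd.leaky_relu(h, 0.2)
            for blk in blocks:
                h = blk(h)
            skips.append(h)
        for k, (conv, norm, blocks) in enumerate(zip(self.up_convs, self.up_norms, self.up_blocks)):
            h = nd.upsample_nearest2(h)
            h = nd.concat_channels(h, skips[-(k + 2)])
            h = conv(h)
            if norm is not None:
                h = norm(h)
            h = nd.relu(h)
            for blk in blocks:
                h = blk(h)
        return nd.tanh(self.head(h))


class _ResUnetGenerator(_UnetGenerator):
    @staticmethod
    def _level_blocks(channels, rng, use_res, norm):
        return []  # filled in __init__ via _make_blocks

    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator):
        self._rng_for_blocks = rng
        super().__init__(spec, rng)
        # replace each per-level convolution group with n_res_blocks residual blocks
        w = spec.base_width
        widths = [min(w * 2 ** i, w * MAX_WIDTH_MULT) for i in range(spec.depth + 1)]
        self.stem_blocks = self._make_blocks(widths[0], rng, spec)
        self.down_blocks = [self._make_blocks(widths[i + 1], rng, spec) for i in range(spec.depth)]
        self.up_blocks = [self._make_blocks(widths[i], rng, spec)
                          for i in reversed(range(spec.depth))]

    @staticmethod
    def _make_blocks(channels, rng, spec):
        return [nd.ResidualBlock(channels, rng, norm=spec.norm)
                for _ in range(spec.n_res_blocks)]


# ---------------------------------------------------------------------------
# ResNet-6 / ResNet-9
# ---------------------------------------------------------------------------

class _ResnetGenerator(Module):
    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        w = spec.base_width
        n_blocks = 6 if spec.family == "resnet6" else 9
        norm = spec.norm
        self.stem = nd.Conv2d(spec.in_channels, w, 7, rng, pad=3)
        self.stem_norm = nd.Norm2d(w) if norm else None
        self.down1 = nd.Conv2d(w, 2 * w, 3, rng, stride=2, pad=1)
        self.down1_norm = nd.Norm2d(2 * w) if norm else None
        self.down2 = nd.Conv2d(2 * w, 4 * w, 3, rng, stride=2, pad=1)
        self.down2_norm = nd.Norm2d(4 * w) if norm else None
        self.blocks = [nd.ResidualBlock(4 * w, rng, norm=norm) for _ in range(n_blocks)]
        self.up1 = nd.Conv2d(4 * w, 2 * w, 3, rng, pad=1)
        self.up1_norm = nd.Norm2d(2 * w) if norm else None
        self.up2 = nd.Conv2d(2 * w, w, 3, rng, pad=1)
        self.up2_norm = nd.Norm2d(w) if norm else None
        self.head = nd.Conv2d(w, spec.out_channels, 7, rng, pad=3)

    def forward(self, x: Tensor) -> Tensor:
        _check_divisible(x, self.spec.divisor)

        def _nrelu(h, norm):
            if norm is not None:
                h = norm(h)
            return nd.relu(h)

        h = _nrelu(self.stem(x), self.stem_norm)
        h = _nrelu(self.down1(h), self.down1_norm)
        h = _nrelu(self.down2(h), self.down2_norm)
        for blk in self.blocks:
            h = blk(h)
        h = _nrelu(self.up1(nd.upsample_nearest2(h)), self.up1_norm)
        h = _nrelu(self.up2(nd.upsample_nearest2(h)), self.up2_norm)
        return nd.tanh(self.head(h))


# ---------------------------------------------------------------------------
# discriminator
# ---------------------------------------------------------------------------

class PatchDiscriminator(Module):
    """Conditional patch classifier; forward takes (conditioning, image)."""

    def __init__(self, spec: DiscriminatorSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        w = spec.base_width
        widths = [min(w * 2 ** i, w * 8) for i in range(spec.n_layers)]
        self.convs, self.norms = [], []
        cin = spec.in_channels
        for i, cout in enumerate(widths):
            self.convs.append(nd.Conv2d(cin, cout, 4, rng, stride=2, pad=1))
            self.norms.append(nd.Norm2d(cout) if i > 0 else None)
            cin = cout
        self.head = nd.Conv2d(cin, 1, 3, rng, pad=1)

    def forward(self, conditioning: Tensor, image: Tensor | None = None) -> Tensor:
        x = conditioning if image is None else nd.concat_channels(conditioning, image)
        if x.data.shape[1] != self.spec.in_channels:
            raise ConfigurationError(
                f"discriminator expects {self.spec.in_channels} input channels, "
                f"got {x.data.shape[1]}"
            )
        for conv, norm in zip(self.convs, self.norms):
            x = conv(x)
            if norm is not None:
                x = norm(x)
            x = nd.leaky_relu(x, 0.2)
        return nd.sigmoid(self.head(x))


# ---------------------------------------------------------------------------
# builders & utilities
# ---------------------------------------------------------------------------

def build_generator(spec: GeneratorSpec, rng: np.random.Generator | int = 0) -> Module:
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    if spec.family in ("resnet6", "resnet9"):
        return _ResnetGenerator(spec, rng)
    if spec.family == "resunet":
        return _ResUnetGenerator(spec, rng)
    return _UnetGenerator(spec, rng)


def build_discriminator(spec: DiscriminatorSpec, rng: np.random.Generator | int = 0) -> PatchDiscriminator:
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    return PatchDiscriminator(spec, rng)


def residual_block_forward(x: Tensor | np.ndarray, residual_fn) -> Tensor:
    """x_{l+1} = x_l + F(x_l): the defining computation of a residual block."""
    xt = nd.as_tensor(x)
    fx = residual_fn(xt)
    fx = nd.as_tensor(fx)
    if fx.data.shape != xt.data.shape:
        raise InvalidParameterError(
            f"residual branch output shape {fx.data.shape} != input {xt.data.shape}"
        )
    return nd.add(xt, fx)


def count_parameters(model: Module) -> int:
    """Total trainable scalar parameters."""
    return sum(p.data.size for p in model.parameters() if p.requires_grad)


def zero_parameters(model: Module) -> None:
    """Set every trainable parameter to zero (used for identity/0.5-output checks)."""
    for p in model.parameters():
        p.data[...] = 0.0
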