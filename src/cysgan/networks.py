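"""Volumetric generators and patch discriminators.

Each domain has one encoder-decoder generator that maps a single-channel
image crop to a translated image (1 channel, tanh) *and* the BCD instance
representations (3 channels: sigmoid B, sigmoid C, tanh D) from a shared
final feature map - translation and segmentation share all weights except
their 1x1x1 output heads. The translation head can be stripped after
training without changing the segmentation output.

Discriminators follow the PatchGAN design: a stack of strided convolutions
(kernel 4, pad 1, strides 2...1), batch norm except on the first layer,
leaky ReLU 0.2, and a final single-channel map of unbounded patch realness
scores for the least-squares GAN objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .errors import ShapeError
from .nn import Tensor, core

__all__ = ["GeneratorConfig", "DiscriminatorConfig", "GeneratorOutput",
           "UNetGenerator", "StrippedGenerator", "PatchDiscriminator",
           "generator_forward", "discriminator_forward",
           "strip_translation_head"]


@dataclass(frozen=True)
class GeneratorConfig:
    depth: int = 2            # number of 2x downsampling stages
    width: int = 8            # channels at full resolution
    seg_channels: int = 3     # 2 in the BC ablation

    @property
    def divisor(self) -> int:
        return 2 ** self.depth


@dataclass(frozen=True)
class DiscriminatorConfig:
    """``n_layers`` counts all convolutions including the final
    single-channel score layer; the full-scale preset uses 5
    (strides 2,2,2,1,1), the desk preset 3 so that 16-voxel crops still
    yield a multi-patch score map."""

    in_channels: int = 1
    n_layers: int = 4
    base_width: int = 32

    def feature_strides(self) -> tuple[int, ...]:
        # stride 2 for the first three feature layers, then stride 1
        return tuple(2 if i < 3 else 1 for i in range(self.n_layers - 1))


@dataclass
class GeneratorOutput:
    """One forward pass: translated image + segmentation representations."""

    image: Tensor     # (N, 1, z, y, x) in [-1, 1]
    seg: Tensor       # (N, seg_channels, z, y, x); B,C in [0,1], D in [-1,1]

    def seg_maps(self, sample: int = 0):
        """Detached numpy (B, C[, D]) stack for one batch element."""
        from .representations import BCDMaps
        s = self.seg.data[sample]
        return BCDMaps.from_stack(np.asarray(s))


class _ConvBlock(nn.Module):
    def __init__(self, cin, cout, rng, stride=1):
        super().__init__()
        self.conv = nn.Conv3d(cin, cout, 3, stride=stride, rng=rng)
        self.norm = nn.InstanceNorm3d(cout)
        self.act = nn.LeakyReLU(0.2)

    def forward(self, x):
        return self.act(self.norm(self.conv(x)))


class UNetGenerator(nn.Module):
    """3D U-Net trunk with separate 1x1x1 image and segmentation heads."""

    def __init__(self, config: GeneratorConfig = GeneratorConfig(),
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.config = config
        w, depth = config.width, config.depth
        widths = [w * 2**i for i in range(depth + 1)]

        self.stem = nn.Sequential(_ConvBlock(1, w, rng), _ConvBlock(w, w, rng))
        self.down = [nn.Sequential(
            _ConvBlock(widths[i], widths[i + 1], rng, stride=2),
            _ConvBlock(widths[i + 1], widths[i + 1], rng))
            for i in range(depth)]
        self.up_reduce = [nn.Conv3d(widths[i + 1], widths[i], 3, rng=rng)
                          for i in reversed(range(depth))]
        self.up_fuse = [_ConvBlock(2 * widths[i], widths[i], rng)
                        for i in reversed(range(depth))]
        self.upsample = nn.UpsampleNearest2()
        self.head_image = nn.Conv3d(w, 1, 1, padding=0, rng=rng)
        self.head_seg = nn.Conv3d(w, config.seg_channels, 1, padding=0,
                                  rng=rng)

    def _check_shape(self, x: Tensor) -> None:
        div = self.config.divisor
        if any(s % div for s in x.data.shape[2:]):
            raise ShapeError(
                f"generator input spatial dims {x.data.shape[2:]} must be "
                f"divisible by {div} (depth {self.config.depth})")

    def features(self, x: Tensor) -> Tensor:
        """Shared final decoder features feeding both heads."""
        self._check_shape(x)
        skips = []
        h = self.stem(x)
        for blk in self.down:
            skips.append(h)
            h = blk(h)
        for reduce, fuse, skip in zip(self.up_reduce, self.up_fuse,
                                      reversed(skips)):
            h = reduce(self.upsample(h))
            h = fuse(core.concat([h, skip], axis=1))
        return h

    def forward(self, x: Tensor) -> GeneratorOutput:
        h = self.features(x)
        image = core.tanh(self.head_image(h))
        seg_logits = self.head_seg(h)
        nc = self.config.seg_channels
        parts = []
        for ch in range(nc):
            sl = _slice_channel(seg_logits, ch)
            parts.append(core.tanh(sl) if ch == 2 else core.sigmoid(sl))
        seg = core.concat(parts, axis=1)
        return GeneratorOutput(image=image, seg=seg)


def _slice_channel(t: Tensor, ch: int) -> Tensor:
    data = t.data[:, ch:ch + 1]

    def bwd(g):
        if t.requires_grad:
            full = np.zeros_like(t.data)
            full[:, ch:ch + 1] = g
            t._accumulate(full)

    return Tensor(data, parents=(t,), backward=bwd)


class StrippedGenerator(nn.Module):
    """A trained generator with the translation head removed.

    Shares the trunk and segmentation-head parameter storage with the
    source generator, so its outputs are bit-identical; its parameter list
    simply no longer contains the image head.
    """

    def __init__(self, gen: UNetGenerator):
        super().__init__()
        self.config = gen.config
        self.stem = gen.stem
        self.down = gen.down
        self.up_reduce = gen.up_reduce
        self.up_fuse = gen.up_fuse
        self.upsample = gen.upsample
        self.head_seg = gen.head_seg
        self._features = gen.features

    def forward(self, x: Tensor) -> Tensor:
        h = self._features(x)
        seg_logits = self.head_seg(h)
        nc = self.config.seg_channels
        parts = [core.tanh(_slice_channel(seg_logits, ch)) if ch == 2
                 else core.sigmoid(_slice_channel(seg_logits, ch))
                 for ch in range(nc)]
        return core.concat(parts, axis=1)


def strip_translation_head(gen: UNetGenerator) -> StrippedGenerator:
    """Remove the image-translation output layer; segmentation unchanged."""
    return StrippedGenerator(gen)


class PatchDiscriminator(nn.Module):
    """Strided-convolution patch classifier (LSGAN scores, unbounded)."""

    def __init__(self, config: DiscriminatorConfig = DiscriminatorConfig(),
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.config = config
        mods: list[nn.Module] = []
        cin = config.in_channels
        width = config.base_width
        for i, stride in enumerate(config.feature_strides()):
            mods.append(nn.Conv3d(cin, width, 4, stride=stride, padding=1,
                                  rng=rng))
            if i > 0:  # first layer without normalisation
                mods.append(nn.BatchNorm3d(width))
            mods.append(nn.LeakyReLU(0.2))
            cin, width = width, min(width * 2, config.base_width * 8)
        mods.append(nn.Conv3d(cin, 1, 4, stride=1, padding=1, rng=rng))
        self.body = nn.Sequential(*mods)

    def forward(self, x: Tensor) -> Tensor:
        if x.data.shape[1] != self.config.in_channels:
            raise ShapeError(
                f"discriminator expects {self.config.in_channels} channels, "
                f"got {x.data.shape[1]}")
        return self.body(x)


def generator_forward(gen: UNetGenerator, volume_crop) -> GeneratorOutput:
    """Functional wrapper: numpy crop (z,y,x) or (N,1,z,y,x) -> outputs."""
    x = _as_batch(volume_crop)
    return gen(Tensor(x))


def discriminator_forward(disc: PatchDiscriminator, channels) -> Tensor:
    """Functional wrapper returning the patch score map tensor."""
    arr = np.asarray(channels.data if isinstance(channels, Tensor)
                     else channels, dtype=np.float32)
    if arr.ndim == 3:
        arr = arr[None, None]
    elif arr.ndim == 4:
        arr = arr[None]
    if isinstance(channels, Tensor):
        return disc(channels)
    return disc(Tensor(arr))


def _as_batch(crop) -> np.ndarray:
    arr = np.asarray(crop.data if isinstance(crop, Tensor) else crop,
                     dtype=np.float32)
    if arr.ndim == 3:
        arr = arr[None, None]
    elif arr.ndim == 4:
        arr = arr[None]
    if arr.ndim != 5:
        raise ShapeError(f"expected 3D crop or 5D batch, got {arr.ndim}D")
    return arr
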