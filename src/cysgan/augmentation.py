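"""Corrupting augmentations and the dual clean/augmented sample stream.

Training crops are streamed in two forms: a *clean* crop and an *augmented*
crop carrying simulated acquisition defects (missing regions, local blur,
local noise). The cycle-consistency objective reconstructs toward the clean
crop, so the generators learn to restore corrupted regions from 3D context
instead of reproducing the defects in the translated image (which would
hand the discriminator an easy cue).

Geometric augmentations (axis flips, xy transpose) apply identically to the
clean crop, the augmented crop and the label maps. Corruptions never touch
the labels. Flipping commutes with the distance transform, so the encoded
D channel is flipped directly instead of being re-encoded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .representations import BCDMaps

__all__ = ["AugmentConfig", "AppliedAug", "TrainSample", "augment",
           "cycle_target"]


@dataclass(frozen=True)
class AugmentConfig:
    p_missing: float = 0.5
    p_blur: float = 0.5
    p_noise: float = 0.5
    p_flip: float = 0.5            # per spatial axis
    p_transpose: float = 0.5       # swap y and x
    p_full_slice: float = 0.3      # a missing region is a full z-slab
    fill_value: float = -1.0
    cuboid_frac: tuple[float, float] = (1.0 / 8.0, 1.0 / 3.0)
    blur_sigma: tuple[float, float] = (1.0, 3.0)
    noise_std: tuple[float, float] = (0.05, 0.2)
    min_corruption_size: int = 1

    def disabled(self) -> "AugmentConfig":
        """The no-augmentation ablation: identity corruption, no geometry."""
        return AugmentConfig(p_missing=0.0, p_blur=0.0, p_noise=0.0,
                             p_flip=0.0, p_transpose=0.0)


@dataclass
class AppliedAug:
    kind: str                       # flip | transpose | missing | blur | noise
    region: tuple[slice, ...] | None = None
    params: dict = field(default_factory=dict)


@dataclass
class TrainSample:
    """Paired clean/augmented crops from one domain (labels if source)."""

    clean: np.ndarray
    augmented: np.ndarray
    labels: BCDMaps | None
    domain_tag: str
    applied: list[AppliedAug] = field(default_factory=list)

    def corruption_mask(self) -> np.ndarray:
        """Boolean mask of voxels inside any recorded corruption region."""
        mask = np.zeros(self.clean.shape, dtype=bool)
        for a in self.applied:
            if a.region is not None:
                mask[a.region] = True
        return mask


def _rand_cuboid(shape, frac_range, rng: np.random.Generator,
                 full_slice: bool = False) -> tuple[slice, ...] | None:
    sizes = []
    starts = []
    for i, n in enumerate(shape):
        if full_slice and i > 0:
            size = n
        else:
            lo = max(int(np.floor(frac_range[0] * n)), 1)
            hi = max(int(np.ceil(frac_range[1] * n)), lo)
            size = int(rng.integers(lo, hi + 1))
        if size < 1 or size > n:
            return None
        sizes.append(size)
        starts.append(int(rng.integers(0, n - size + 1)))
    return tuple(slice(s, s + sz) for s, sz in zip(starts, sizes))


def augment(crop: np.ndarray, labels: BCDMaps | None,
            config: AugmentConfig,
            rng: np.random.Generator,
            domain_tag: str = "source") -> TrainSample:
    """Build a :class:`TrainSample` from one image crop.

    Order of operations: geometric flips/transpose on image and labels,
    then per-type corruption of the augmented copy only, each applied with
    its configured probability. Output clipped to [-1, 1].
    """
    crop = np.asarray(crop, dtype=np.float32)
    applied: list[AppliedAug] = []

    b = labels.B if labels is not None else None
    c = labels.C if labels is not None else None
    d = labels.D if labels is not None else None

    for axis in range(3):
        if rng.random() < config.p_flip:
            crop = np.flip(crop, axis=axis)
            if labels is not None:
                b = np.flip(b, axis=axis)
                c = np.flip(c, axis=axis)
                d = np.flip(d, axis=axis) if d is not None else None
            applied.append(AppliedAug("flip", params={"axis": axis}))
    if rng.random() < config.p_transpose:
        crop = crop.swapaxes(1, 2)
        if labels is not None:
            b = b.swapaxes(1, 2)
            c = c.swapaxes(1, 2)
            d = d.swapaxes(1, 2) if d is not None else None
        applied.append(AppliedAug("transpose", params={"axes": (1, 2)}))

    clean = np.ascontiguousarray(crop)
    augmented = clean.copy()
    shape = clean.shape
    big_enough = min(shape) >= config.min_corruption_size

    if big_enough and rng.random() < config.p_missing:
        full = rng.random() < config.p_full_slice
        region = _rand_cuboid(shape, config.cuboid_frac, rng,
                              full_slice=full)
        if region is not None:
            augmented[region] = config.fill_value
            applied.append(AppliedAug("missing", region=region,
                                      params={"fill": config.fill_value,
                                              "full_slice": full}))
    if big_enough and rng.random() < config.p_blur:
        region = _rand_cuboid(shape, config.cuboid_frac, rng)
        if region is not None:
            sigma = float(rng.uniform(*config.blur_sigma))
            augmented[region] = ndimage.gaussian_filter(
                augmented[region], sigma=sigma)
            applied.append(AppliedAug("blur", region=region,
                                      params={"sigma": sigma}))
    if big_enough and rng.random() < config.p_noise:
        region = _rand_cuboid(shape, config.cuboid_frac, rng)
        if region is not None:
            std = float(rng.uniform(*config.noise_std))
            noise = rng.normal(0.0, std,
                               size=augmented[region].shape)
            augmented[region] = augmented[region] + noise.astype(np.float32)
            applied.append(AppliedAug("noise", region=region,
                                      params={"std": std}))

    augmented = np.clip(augmented, -1.0, 1.0)
    out_labels = None
    if labels is not None:
        out_labels = BCDMaps(B=np.ascontiguousarray(b),
                             C=np.ascontiguousarray(c),
                             D=(np.ascontiguousarray(d)
                                if d is not None else None))
    return TrainSample(clean=clean, augmented=augmented, labels=out_labels,
                       domain_tag=domain_tag, applied=applied)


def cycle_target(sample: TrainSample) -> np.ndarray:
    """Reconstruction target for cycle consistency: the clean crop."""
    return sample.clean
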