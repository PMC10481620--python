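"""Instance-mask <-> BCD representation codecs.

Instance labels are encoded into three aligned per-voxel targets that a
network can regress:

* **B** - binary foreground mask,
* **C** - instance contour map: voxels within ``contour_radius`` (Chebyshev)
  of an inter-instance or instance-background interface,
* **D** - signed, clipped, normalised distance transform: inside an
  instance, the Euclidean distance to the instance's own boundary-voxel set
  (boundary voxels, i.e. instance voxels with a 6-neighbour of a different
  label, get 0); on background, minus the Euclidean distance to the nearest
  foreground voxel. Both sides are clipped and divided by their clip so
  D lies in [-1, 1].

Because inside distances are computed per instance, touching instances both
fall to D = 0 at their shared interface, which is what lets a watershed on
-D split them. Predicted (continuous) maps are decoded back to instances by
marker-controlled watershed in :func:`decode_bcd`.

Distances are Euclidean in voxel units by default; pass ``sampling`` to
weight axes by physical voxel size instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
from scipy import ndimage
from skimage.segmentation import watershed

from .errors import ShapeError, UsageError
from .volumes_io import InstanceLabels

__all__ = ["BCDMaps", "encode_bcd", "encode_bc", "decode_bcd",
           "DEFAULT_D_CLIP_IN", "DEFAULT_D_CLIP_OUT"]

DEFAULT_D_CLIP_IN = 8.0
DEFAULT_D_CLIP_OUT = 16.0


@dataclass
class BCDMaps:
    """Aligned foreground (B), contour (C) and signed distance (D) grids.

    ``D`` is ``None`` in the two-channel (BC) ablation. Encoded maps have
    binary B and C; predicted maps are continuous in the same ranges.
    """

    B: np.ndarray
    C: np.ndarray
    D: np.ndarray | None = None

    def __post_init__(self):
        if self.B.shape != self.C.shape:
            raise ShapeError("B and C shapes differ")
        if self.D is not None and self.D.shape != self.B.shape:
            raise ShapeError("D shape differs from B")

    @property
    def shape(self):
        return self.B.shape

    @property
    def n_channels(self) -> int:
        return 2 if self.D is None else 3

    def stack(self) -> np.ndarray:
        """(channel, z, y, x) array in (B, C, D) order."""
        chans = [self.B, self.C] + ([] if self.D is None else [self.D])
        return np.stack([c.astype(np.float32) for c in chans])

    @classmethod
    def from_stack(cls, arr: np.ndarray) -> "BCDMaps":
        if arr.ndim != 4 or arr.shape[0] not in (2, 3):
            raise ShapeError(f"expected (2|3, z, y, x), got {arr.shape}")
        d = arr[2] if arr.shape[0] == 3 else None
        return cls(B=arr[0], C=arr[1], D=d)

    def save(self, path: str, dataset_key: str = "main") -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset(dataset_key, data=self.stack(),
                             track_times=False)

    @classmethod
    def load(cls, path: str, dataset_key: str = "main") -> "BCDMaps":
        with h5py.File(path, "r") as f:
            return cls.from_stack(f[dataset_key][...])


def _interface_mask(lbl: np.ndarray) -> np.ndarray:
    """Voxels with an in-volume 6-neighbour carrying a different label."""
    out = np.zeros(lbl.shape, dtype=bool)
    for axis in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(None, -1)
        hi[axis] = slice(1, None)
        diff = lbl[tuple(lo)] != lbl[tuple(hi)]
        out[tuple(lo)] |= diff
        out[tuple(hi)] |= diff
    return out


def _contour(lbl: np.ndarray, contour_radius: int) -> np.ndarray:
    c = _interface_mask(lbl)
    if contour_radius > 1 and c.any():
        size = 2 * (contour_radius - 1) + 1
        c = ndimage.binary_dilation(c, structure=np.ones((size,) * 3,
                                                         dtype=bool))
    return c


def encode_bcd(labels: InstanceLabels, contour_radius: int = 1,
               d_clip_in: float = DEFAULT_D_CLIP_IN,
               d_clip_out: float = DEFAULT_D_CLIP_OUT,
               sampling=None) -> BCDMaps:
    """Encode instance labels as (B, C, D) training targets."""
    if contour_radius < 1:
        raise ValueError("contour_radius must be >= 1")
    if d_clip_in <= 0 or d_clip_out <= 0:
        raise ValueError("distance clips must be positive")
    lbl = labels.data
    fg = lbl > 0
    b = fg.astype(np.float32)
    c = _contour(lbl, contour_radius).astype(np.float32)

    d = np.empty(lbl.shape, dtype=np.float64)
    bg = ~fg
    if fg.any():
        dist_bg = ndimage.distance_transform_edt(bg, sampling=sampling)
        d[bg] = -np.minimum(dist_bg[bg], d_clip_out) / d_clip_out
    else:
        d[:] = -1.0
        return BCDMaps(B=b, C=c, D=d)

    boundary = _interface_mask(lbl) & fg
    for idx, sl in enumerate(ndimage.find_objects(lbl), start=1):
        if sl is None:
            continue
        inst = lbl[sl] == idx
        bnd = boundary[sl] & inst
        if not bnd.any():
            # instance has no in-volume boundary (fills the grid): far clip
            d[sl][inst] = 1.0
            continue
        dist = ndimage.distance_transform_edt(~bnd, sampling=sampling)
        win = d[sl]
        win[inst] = np.minimum(dist[inst], d_clip_in) / d_clip_in
        d[sl] = win
    return BCDMaps(B=b, C=c, D=d)


def encode_bc(labels: InstanceLabels, contour_radius: int = 1) -> BCDMaps:
    """Two-channel (B, C) encoding used by the no-distance ablation."""
    lbl = labels.data
    return BCDMaps(B=(lbl > 0).astype(np.float32),
                   C=_contour(lbl, contour_radius).astype(np.float32),
                   D=None)


def _relabel_consecutive(lbl: np.ndarray) -> np.ndarray:
    """Renumber surviving positive labels to 1..K preserving their order.

    Watershed output inherits marker IDs, and markers are numbered in
    raster-scan order of seed discovery, so ascending renumbering keeps
    the deterministic seed order."""
    ids = np.unique(lbl)
    ids = ids[ids > 0]
    mapping = np.zeros(int(lbl.max()) + 1, dtype=lbl.dtype)
    mapping[ids] = np.arange(1, ids.size + 1, dtype=lbl.dtype)
    return mapping[lbl]


def decode_bcd(maps: BCDMaps, theta_fg: float = 0.6,
               theta_contour: float = 0.8, theta_seed: float = 0.9,
               min_seed_size: int = 8,
               min_instance_size: int = 27) -> InstanceLabels:
    """Marker-controlled watershed decoding of predicted BCD maps.

    Seeds are connected components (6-connectivity) of high-confidence
    interiors ``{B > theta_seed, C < theta_contour, D > 0}`` of at least
    ``min_seed_size`` voxels; the watershed floods ``-D`` restricted to the
    foreground ``{B > theta_fg}``. In the BC ablation (``maps.D is None``)
    seeds drop the D condition and the flooding surface is ``-B``.
    Instances below ``min_instance_size`` voxels are removed and the
    surviving IDs renumbered consecutively in seed raster order.
    """
    b, c = np.asarray(maps.B), np.asarray(maps.C)
    seed_mask = (b > theta_seed) & (c < theta_contour)
    if maps.D is not None:
        seed_mask &= np.asarray(maps.D) > 0
        surface = -np.asarray(maps.D)
    else:
        surface = -b
    markers, n = ndimage.label(seed_mask)
    if n:
        sizes = np.bincount(markers.ravel(), minlength=n + 1)
        small = np.flatnonzero(sizes < min_seed_size)
        markers[np.isin(markers, small[small > 0])] = 0
    fg_mask = b > theta_fg
    if not n or not markers.any() or not fg_mask.any():
        return InstanceLabels(np.zeros(b.shape, dtype=np.int32))
    lbl = watershed(surface.astype(np.float64), markers=markers,
                    mask=fg_mask)
    if min_instance_size > 0 and lbl.max() > 0:
        sizes = np.bincount(lbl.ravel(), minlength=int(lbl.max()) + 1)
        small = np.flatnonzero(sizes < min_instance_size)
        lbl[np.isin(lbl, small[small > 0])] = 0
    return InstanceLabels(_relabel_consecutive(lbl).astype(np.int32))
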