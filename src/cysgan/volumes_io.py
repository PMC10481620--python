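"""Volume and label I/O plus resolution-matching preprocessing.

Volumes are dense 3D grayscale grids in ``(z, y, x)`` axis order with
per-axis physical voxel size in micrometres. Intensities are min-max
normalised to ``[-1, 1]`` at read time, which matches the bounded symmetric
output of the translation head. Supported containers are HDF5 (one dataset
per volume, default key ``"main"``) and multipage TIFF.

Two modalities commonly need resolution matching before adaptation: an
anisotropic light-microscopy stack acquired on expanded tissue (where the
physical expansion factor divides the nominal voxel size) and an isotropic
EM volume that must be resampled so that instance sizes match across
domains. :func:`resample`, :func:`smooth_upsampled_masks` and
:func:`effective_resolution` implement those steps.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import h5py
import numpy as np
import tifffile
from scipy import ndimage

from .errors import ShapeError, UsageError, VolumeIOError

DEFAULT_DATASET_KEY = "main"

__all__ = [
    "Volume", "InstanceLabels", "read_volume", "write_volume",
    "read_labels", "write_labels", "resample", "smooth_upsampled_masks",
    "effective_resolution",
]


@dataclass
class Volume:
    """3D grayscale grid, intensities in [-1, 1], axes (z, y, x)."""

    data: np.ndarray
    resolution: tuple[float, float, float] = (1.0, 1.0, 1.0)
    domain_tag: str = "source"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ShapeError(f"volume must be 3D, got {self.data.ndim}D")
        if any(r <= 0 for r in self.resolution):
            raise ValueError("resolution must be strictly positive")
        self.resolution = tuple(float(r) for r in self.resolution)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class InstanceLabels:
    """3D grid of non-negative integer instance IDs; 0 is background."""

    data: np.ndarray
    resolution: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ShapeError(f"labels must be 3D, got {self.data.ndim}D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise UsageError("instance labels must be an integer array")
        if self.data.size and self.data.min() < 0:
            raise ValueError("instance IDs must be non-negative")
        self.resolution = tuple(float(r) for r in self.resolution)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def ids(self) -> np.ndarray:
        """Sorted positive instance IDs present in the grid."""
        u = np.unique(self.data)
        return u[u > 0]


def _normalize(data: np.ndarray) -> np.ndarray:
    data = data.astype(np.float32)
    lo, hi = float(data.min()), float(data.max())
    if hi <= lo:  # constant volume: degenerate range maps to the lower bound
        return np.full_like(data, -1.0)
    return (data - lo) / (hi - lo) * 2.0 - 1.0


def _is_hdf5(path: str) -> bool:
    return os.path.splitext(path)[1].lower() in (".h5", ".hdf5", ".hdf")


def _read_array(path: str, dataset_key: str) -> tuple[np.ndarray, dict]:
    if not os.path.exists(path):
        raise VolumeIOError(f"no such file: {path}")
    attrs: dict = {}
    try:
        if _is_hdf5(path):
            with h5py.File(path, "r") as f:
                if dataset_key not in f:
                    raise VolumeIOError(
                        f"dataset {dataset_key!r} not in {path}")
                ds = f[dataset_key]
                arr = ds[...]
                attrs = dict(ds.attrs)
        else:
            arr = tifffile.imread(path)
    except (OSError, tifffile.TiffFileError) as exc:
        raise VolumeIOError(f"cannot read {path}: {exc}") from exc
    if arr.ndim != 3:
        raise ShapeError(f"{path}: expected a 3D array, got shape {arr.shape}")
    return arr, attrs


def _resolution_from_attrs(attrs: dict) -> tuple[float, float, float]:
    res = attrs.get("resolution_zyx")
    if res is None:
        return (1.0, 1.0, 1.0)
    return tuple(float(r) for r in res)


def read_volume(path: str, dataset_key: str = DEFAULT_DATASET_KEY) -> Volume:
    """Read a 3D image and min-max rescale its intensities to [-1, 1]."""
    arr, attrs = _read_array(path, dataset_key)
    tag = attrs.get("domain_tag", "source")
    if isinstance(tag, bytes):
        tag = tag.decode()
    return Volume(_normalize(arr), resolution=_resolution_from_attrs(attrs),
                  domain_tag=str(tag))


def write_volume(vol: Volume, path: str,
                 dataset_key: str = DEFAULT_DATASET_KEY) -> None:
    """Write a volume; HDF5 carries resolution/domain metadata as attrs."""
    if _is_hdf5(path):
        with h5py.File(path, "w") as f:
            ds = f.create_dataset(dataset_key,
                                  data=vol.data.astype(np.float32),
                                  track_times=False)
            ds.attrs["resolution_zyx"] = np.asarray(vol.resolution)
            ds.attrs["domain_tag"] = vol.domain_tag
    else:
        tifffile.imwrite(path, vol.data.astype(np.float32))


def read_labels(path: str,
                dataset_key: str = DEFAULT_DATASET_KEY) -> InstanceLabels:
    arr, attrs = _read_array(path, dataset_key)
    if not np.issubdtype(arr.dtype, np.integer):
        raise UsageError(f"{path}: labels must be integer-typed")
    return InstanceLabels(arr, resolution=_resolution_from_attrs(attrs))


def write_labels(labels: InstanceLabels, path: str,
                 dataset_key: str = DEFAULT_DATASET_KEY) -> None:
    if _is_hdf5(path):
        with h5py.File(path, "w") as f:
            ds = f.create_dataset(dataset_key,
                                  data=labels.data.astype(np.int32),
                                  track_times=False)
            ds.attrs["resolution_zyx"] = np.asarray(labels.resolution)
    else:
        tifffile.imwrite(path, labels.data.astype(np.int32))


def _resample_grid(data: np.ndarray, factors, order: int) -> np.ndarray:
    """Half-pixel-centred resampling; output shape = round(shape * factor)."""
    out_shape = tuple(int(round(s * f)) for s, f in zip(data.shape, factors))
    if min(out_shape) < 1:
        raise ShapeError(f"resample factors {factors} collapse shape "
                         f"{data.shape}")
    coords = np.meshgrid(
        *[(np.arange(n) + 0.5) * (s / n) - 0.5
          for n, s in zip(out_shape, data.shape)],
        indexing="ij")
    return ndimage.map_coordinates(data, np.stack(coords), order=order,
                                   mode="nearest")


def resample(vol_or_labels, factors, mode: str | None = None):
    """Resample a volume (linear) or labels (nearest) by per-axis factors.

    ``factors`` are output/input size ratios per (z, y, x) axis; resolution
    metadata is divided by the factors. Nearest-neighbour is mandatory for
    labels so that no new instance IDs can be created.
    """
    factors = tuple(float(f) for f in np.broadcast_to(factors, 3))
    if any(f <= 0 for f in factors):
        raise ValueError("resample factors must be positive")
    new_res = tuple(r / f for r, f in
                    zip(vol_or_labels.resolution, factors))
    if isinstance(vol_or_labels, InstanceLabels):
        if mode not in (None, "nearest"):
            raise UsageError("instance labels support only nearest-neighbor "
                             "resampling")
        out = _resample_grid(vol_or_labels.data, factors, order=0)
        return InstanceLabels(out.astype(vol_or_labels.data.dtype),
                              resolution=new_res)
    if mode is None:
        mode = "linear"
    if mode == "nearest":
        order = 0
    elif mode == "linear":
        order = 1
    else:
        raise UsageError(f"unknown resampling mode {mode!r}")
    out = _resample_grid(vol_or_labels.data.astype(np.float32), factors,
                         order=order)
    if order > 0:
        out = np.clip(out, -1.0, 1.0)
    return Volume(out, resolution=new_res,
                  domain_tag=vol_or_labels.domain_tag)


def smooth_upsampled_masks(labels: InstanceLabels, sigma: float,
                           threshold: float = 0.5) -> InstanceLabels:
    """Gaussian-smooth each instance mask and re-threshold it.

    Removes the blocky staircase boundaries left by nearest-neighbour
    upsampling. Voxels claimed by several smoothed instances go to the
    instance with the larger blurred value (deterministic, order-free:
    ties broken toward the smaller ID via strict-inequality update).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    if sigma == 0 or labels.data.max() == 0:
        return InstanceLabels(labels.data.copy(),
                              resolution=labels.resolution)
    out = np.zeros_like(labels.data)
    best = np.zeros(labels.data.shape, dtype=np.float32)
    pad = int(np.ceil(4 * sigma)) + 1
    objects = ndimage.find_objects(labels.data)
    for idx, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        grown = tuple(
            slice(max(s.start - pad, 0), min(s.stop + pad, dim))
            for s, dim in zip(sl, labels.data.shape))
        mask = (labels.data[grown] == idx).astype(np.float32)
        blurred = ndimage.gaussian_filter(mask, sigma=sigma)
        claim = blurred > threshold
        win_best = best[grown]
        take = claim & (blurred > win_best)
        win_out = out[grown]
        win_out[take] = idx
        win_best[take] = blurred[take]
        out[grown] = win_out
        best[grown] = win_best
    return InstanceLabels(out, resolution=labels.resolution)


def effective_resolution(resolution, expansion_ratio: float
                         ) -> tuple[float, float, float]:
    """Physical voxel size after dividing out a tissue expansion factor."""
    if expansion_ratio <= 0:
        raise ValueError("expansion ratio must be positive")
    return tuple(float(r) / expansion_ratio for r in resolution)
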