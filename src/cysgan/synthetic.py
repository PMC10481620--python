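"""Seeded two-domain 3D nuclei phantoms.

Generates dense ellipsoidal "nuclei" label volumes plus domain-styled
renderings that emulate the situation the method targets: two imaging
modalities whose instance-size and nearest-neighbour-distance statistics
match, while foreground/background intensity and contrast differ strongly
(here the built-in presets invert the contrast between domains: bright
nuclei on dark background in the source, dark nuclei on bright background
in the target). Every stage of the pipeline is therefore trainable and
testable from a single master seed with no external data.

The target-domain ground truth produced by :func:`make_benchmark` exists on
disk but is quarantined: the trainer refuses to load it, only evaluation
may (see :mod:`cysgan.trainer`).
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import yaml
from scipy import ndimage

from .errors import GenerationError, UsageError
from .volumes_io import InstanceLabels, Volume, write_labels, write_volume

__all__ = ["DomainStyle", "PhantomSpec", "SOURCE_STYLE", "TARGET_STYLE",
           "sample_instances", "render_domain", "make_benchmark",
           "default_spec_pair"]


@dataclass(frozen=True)
class DomainStyle:
    """Appearance parameters of one imaging domain (intensities in [-1,1])."""

    fg_mean: float
    bg_mean: float
    fg_std: float = 0.10
    bg_std: float = 0.10
    texture_amp: float = 0.08
    texture_corr_len: float = 3.0
    z_blur_sigma: float = 0.6


# EM-like source: bright nuclei on dark background, mild anisotropic blur.
SOURCE_STYLE = DomainStyle(fg_mean=0.50, bg_mean=-0.50, fg_std=0.10,
                           bg_std=0.10, texture_amp=0.08,
                           texture_corr_len=3.0, z_blur_sigma=0.5)
# ExM-like target: inverted contrast (dark nuclei on bright background),
# noisier, stronger axial blur.
TARGET_STYLE = DomainStyle(fg_mean=-0.40, bg_mean=0.45, fg_std=0.12,
                           bg_std=0.12, texture_amp=0.10,
                           texture_corr_len=4.0, z_blur_sigma=1.0)

_STYLES = {"source": SOURCE_STYLE, "target": TARGET_STYLE}


@dataclass
class PhantomSpec:
    """Geometry + appearance specification of one phantom volume."""

    shape: tuple[int, int, int] = (64, 64, 64)
    n_instances: int = 35                # densely packed, like brain nuclei
    radius_range: tuple[float, float] = (4.5, 7.0)   # ~4 um nuclei at the
    z_radius_scale: float = 1.0          # working resolution
    min_spacing: float = 12.0            # minimum centre-to-centre distance
    styles: dict[str, DomainStyle] = field(
        default_factory=lambda: dict(_STYLES))
    seed: int = 0
    max_tries_per_instance: int = 200

    def __post_init__(self):
        if self.radius_range[0] < 1:
            raise ValueError("radii must be >= 1 voxel")
        if self.min_spacing < 0:
            raise ValueError("spacing must be >= 0")
        for style in self.styles.values():
            if not (-1 <= style.fg_mean <= 1 and -1 <= style.bg_mean <= 1):
                raise ValueError("style means must lie in [-1, 1]")

    def spec_hash(self) -> str:
        payload = repr(sorted(asdict(self).items())).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3D rotation via QR decomposition."""
    a = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def sample_instances(spec: PhantomSpec) -> InstanceLabels:
    """Place randomly rotated ellipsoids by dart throwing.

    Centres are rejected below ``spec.min_spacing``; voxels claimed by
    several ellipsoids go to the nearest centre. Raises
    :class:`GenerationError` if fewer than 90% of the requested instances
    can be placed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x1]))
    shape = np.asarray(spec.shape)
    lbl = np.zeros(spec.shape, dtype=np.int32)
    if spec.n_instances == 0:
        return InstanceLabels(lbl)
    best_dist = np.full(spec.shape, np.inf, dtype=np.float32)
    centers: list[np.ndarray] = []
    r_lo, r_hi = spec.radius_range
    placed = 0
    tries_left = spec.max_tries_per_instance * spec.n_instances
    while placed < spec.n_instances and tries_left > 0:
        tries_left -= 1
        margin = r_lo  # allow partial clipping at the border, like real crops
        center = rng.uniform(margin, shape - margin)
        if centers and np.min(np.linalg.norm(
                np.asarray(centers) - center, axis=1)) < spec.min_spacing:
            continue
        radii = rng.uniform(r_lo, r_hi, size=3)
        radii[0] *= spec.z_radius_scale
        rot = _random_rotation(rng)
        placed += 1
        centers.append(center)
        # rasterize within a conservative bounding box
        rmax = float(radii.max())
        lo = np.maximum(np.floor(center - rmax - 1).astype(int), 0)
        hi = np.minimum(np.ceil(center + rmax + 2).astype(int), shape)
        grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)],
                            indexing="ij")
        pts = np.stack(grids, axis=-1).astype(np.float64) - center
        local = pts @ rot.T
        inside = np.sum((local / radii) ** 2, axis=-1) <= 1.0
        dist = np.linalg.norm(pts, axis=-1).astype(np.float32)
        box = tuple(slice(l, h) for l, h in zip(lo, hi))
        lbl_win, dist_win = lbl[box], best_dist[box]
        take = inside & (dist < dist_win)
        lbl_win[take] = placed
        dist_win[take] = dist[take]
        lbl[box], best_dist[box] = lbl_win, dist_win
    # instances may be fully overwritten only in pathological overlaps;
    # count what survived rasterization
    survived = np.unique(lbl)
    n_alive = int((survived > 0).sum())
    if n_alive < int(np.ceil(0.9 * spec.n_instances)):
        raise GenerationError(
            f"could only place {n_alive}/{spec.n_instances} instances in "
            f"shape {spec.shape} at min_spacing={spec.min_spacing}; "
            "lower the density or the spacing")
    return InstanceLabels(lbl)


def _correlated_texture(shape, amp: float, corr_len: float,
                        rng: np.random.Generator) -> np.ndarray:
    if amp == 0:
        return np.zeros(shape, dtype=np.float32)
    noise = rng.normal(size=shape).astype(np.float32)
    smooth = ndimage.gaussian_filter(noise, sigma=corr_len)
    sd = smooth.std()
    if sd > 0:
        smooth *= amp / sd
    return smooth


def render_domain(labels: InstanceLabels, spec: PhantomSpec,
                  domain_tag: str) -> Volume:
    """Render a label volume in one domain's appearance.

    Intensity = domain fg/bg mean + i.i.d. Gaussian noise + smooth
    correlated texture, followed by an anisotropic z blur and clipping to
    [-1, 1]. Deterministic given ``spec.seed`` and ``domain_tag``.
    """
    if domain_tag not in spec.styles:
        raise UsageError(f"unknown domain_tag {domain_tag!r}; "
                         f"have {sorted(spec.styles)}")
    style = spec.styles[domain_tag]
    salt = int.from_bytes(domain_tag.encode(), "little") % (2**31)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x2, salt]))
    fg = labels.data > 0
    img = np.where(fg, style.fg_mean, style.bg_mean).astype(np.float32)
    std = np.where(fg, style.fg_std, style.bg_std).astype(np.float32)
    if style.fg_std > 0 or style.bg_std > 0:
        img += std * rng.normal(size=img.shape).astype(np.float32)
    img += _correlated_texture(img.shape, style.texture_amp,
                               style.texture_corr_len, rng)
    if style.z_blur_sigma > 0:
        img = ndimage.gaussian_filter1d(img, sigma=style.z_blur_sigma, axis=0)
    return Volume(np.clip(img, -1.0, 1.0), domain_tag=domain_tag)


def default_spec_pair(master_seed: int = 0, shape=(64, 64, 64),
                      n_instances: int = 35) -> tuple[PhantomSpec,
                                                      PhantomSpec]:
    """Source/target geometric specs drawn from the same distribution."""
    src = PhantomSpec(shape=tuple(shape), n_instances=n_instances,
                      seed=master_seed)
    tgt = PhantomSpec(shape=tuple(shape), n_instances=n_instances,
                      seed=master_seed + 1)
    return src, tgt


def make_benchmark(spec_pair: tuple[PhantomSpec, PhantomSpec],
                   n_train: int, n_val: int, out_dir: str,
                   overwrite: bool = False) -> str:
    """Write a two-domain benchmark to ``out_dir``; returns manifest path.

    Layout: ``n_train`` labelled source volumes, ``n_train`` unlabelled
    target volumes (labels withheld from disk for the train role), and
    ``n_val`` held-out target volumes *with* labels for evaluation only.
    All per-volume geometry is independently sampled from the same specs by
    deriving per-file seeds from the spec seeds.
    """
    src_spec, tgt_spec = spec_pair
    if os.path.isdir(out_dir) and os.listdir(out_dir) and not overwrite:
        raise UsageError(f"output dir {out_dir} is not empty "
                         "(pass overwrite=True)")
    os.makedirs(out_dir, exist_ok=True)
    entries = []

    def _emit(spec: PhantomSpec, seed: int, domain: str, role: str,
              stem: str, with_labels: bool):
        s = replace(spec, seed=seed)
        labels = sample_instances(s)
        vol = render_domain(labels, s, domain)
        img_path = os.path.join(out_dir, f"{stem}_im.h5")
        write_volume(vol, img_path)
        entry = {"role": role, "image": os.path.basename(img_path),
                 "seed": int(seed), "spec_hash": s.spec_hash(),
                 "domain": domain}
        if with_labels:
            lab_path = os.path.join(out_dir, f"{stem}_label.h5")
            write_labels(labels, lab_path)
            entry["labels"] = os.path.basename(lab_path)
        entries.append(entry)

    for i in range(n_train):
        _emit(src_spec, src_spec.seed + 1000 + i, "source", "source_train",
              f"source_train_{i:02d}", with_labels=True)
    for i in range(n_train):
        _emit(tgt_spec, tgt_spec.seed + 2000 + i, "target", "target_train",
              f"target_train_{i:02d}", with_labels=False)
    for i in range(n_val):
        _emit(tgt_spec, tgt_spec.seed + 3000 + i, "target", "target_val",
              f"target_val_{i:02d}", with_labels=True)

    manifest_path = os.path.join(out_dir, "manifest.yaml")
    with open(manifest_path, "w") as f:
        yaml.safe_dump({"volumes": entries}, f, sort_keys=True)
    return manifest_path
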