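"""Optimisation loop, checkpointing and whole-volume inference.

One training iteration consumes one augmented/clean crop pair from each
domain simultaneously:

1. ``F`` maps the source crop to a synthesized target-style image plus the
   source segmentation prediction; ``G`` maps the target crop back the other
   way. Re-applying the opposite generator to each synthesized image yields
   the cycle reconstructions, compared against the *clean* crops.
2. The three discriminators (target image, source image, source
   segmentation) are updated on real data versus detached fakes.
3. ``F`` and ``G`` are updated jointly on the uniform-weight sum of
   adversarial, cycle, supervised-segmentation, structural-consistency and
   segmentation-adversarial terms.

Synthesized images are detached before any segmentation loss touches them,
so segmentation objectives never steer the translation output. Target-domain
labels are quarantined: the training data loader refuses to read them in any
mode; only evaluation may (``allow_target_labels=True``).

The desk-scale preset (crop 16^3, generator depth 2 / width 8, 3-layer
discriminators, batch 1) is the configuration the test-suite exercises; a
full-scale preset (depth 4 / width 32, 5-layer discriminators, 10^6
iterations, batch 8) ships but is not run by tests.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import yaml

from . import objectives as obj
from .augmentation import AugmentConfig, TrainSample, augment
from .errors import QuarantineError, ShapeError, TrainingError, UsageError
from .networks import (DiscriminatorConfig, GeneratorConfig, GeneratorOutput,
                       PatchDiscriminator, UNetGenerator,
                       strip_translation_head)
from .nn import AdamW, Tensor, cosine_annealed_lr
from .representations import (BCDMaps, decode_bcd, encode_bc, encode_bcd)
from .volumes_io import InstanceLabels, Volume, read_labels, read_volume

__all__ = ["TrainConfig", "DecodeConfig", "TilingConfig", "Networks",
           "DatasetBundle", "train_step", "fit", "infer", "load_checkpoint",
           "save_checkpoint", "PRESETS"]


@dataclass(frozen=True)
class DecodeConfig:
    theta_fg: float = 0.6
    theta_contour: float = 0.8
    theta_seed: float = 0.9
    min_seed_size: int = 8
    min_instance_size: int = 27


@dataclass
class TrainConfig:
    iterations: int = 400
    batch_size: int = 1
    crop_size: tuple[int, int, int] = (16, 16, 16)
    lr: float = 2e-3
    weight_decay: float = 1e-4
    seed: int = 0
    mode: str = "cysgan"              # cysgan | source_only_baseline
    no_augmentation: bool = False
    no_semisup: bool = False
    bc_only: bool = False
    lsgan_fake_label: float = 0.0     # -1.0 matches the printed LSGAN form
    gen_depth: int = 2
    gen_width: int = 8
    disc_layers: int = 3   # 3^3 patch map on 16^3 crops: local feedback
    disc_width: int = 32
    contour_radius: int = 1
    d_clip_in: float = 8.0
    d_clip_out: float = 16.0
    checkpoint_every: int = 0         # 0: only final
    log_every: int = 20
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    decode: DecodeConfig = field(default_factory=DecodeConfig)

    def __post_init__(self):
        self.crop_size = tuple(int(c) for c in self.crop_size)
        div = 2 ** self.gen_depth
        if any(c % div for c in self.crop_size):
            raise UsageError(f"crop size {self.crop_size} must be divisible "
                             f"by 2^depth = {div}")
        if self.mode not in ("cysgan", "source_only_baseline"):
            raise UsageError(f"unknown mode {self.mode!r}")

    @property
    def seg_channels(self) -> int:
        return 2 if self.bc_only else 3

    def effective_augment(self) -> AugmentConfig:
        return self.augment.disabled() if self.no_augmentation \
            else self.augment

    def arch_hash(self) -> str:
        arch = (self.gen_depth, self.gen_width, self.disc_layers,
                self.disc_width, self.seg_channels, self.mode)
        return hashlib.sha256(repr(arch).encode()).hexdigest()[:16]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["crop_size"] = list(self.crop_size)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        if "augment" in d and isinstance(d["augment"], dict):
            a = dict(d["augment"])
            for k in ("cuboid_frac", "blur_sigma", "noise_std"):
                if k in a:
                    a[k] = tuple(a[k])
            d["augment"] = AugmentConfig(**a)
        if "decode" in d and isinstance(d["decode"], dict):
            d["decode"] = DecodeConfig(**d["decode"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "TrainConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})


PRESETS = {
    "desk": TrainConfig(),
    "full": TrainConfig(iterations=10**6, batch_size=8,
                        crop_size=(64, 64, 64), gen_depth=4, gen_width=32,
                        disc_layers=5, disc_width=64),
}


# ---------------------------------------------------------------------------
# data handling
# ---------------------------------------------------------------------------

@dataclass
class _Record:
    role: str
    image_path: str
    label_path: str | None
    domain: str


class DatasetBundle:
    """Volumes loaded from a benchmark manifest.

    Training contexts construct this with ``allow_target_labels=False``
    (the default); any attempt to touch labels of a target-role record then
    raises :class:`QuarantineError`.
    """

    def __init__(self, manifest_path: str, allow_target_labels: bool = False):
        base = os.path.dirname(os.path.abspath(manifest_path))
        with open(manifest_path) as f:
            manifest = yaml.safe_load(f)
        self.allow_target_labels = allow_target_labels
        self.records: list[_Record] = []
        for e in manifest["volumes"]:
            self.records.append(_Record(
                role=e["role"],
                image_path=os.path.join(base, e["image"]),
                label_path=(os.path.join(base, e["labels"])
                            if "labels" in e else None),
                domain=e.get("domain",
                             "source" if e["role"].startswith("source")
                             else "target")))

    def roles(self, role: str) -> list[_Record]:
        return [r for r in self.records if r.role == role]

    def image(self, rec: _Record) -> Volume:
        return read_volume(rec.image_path)

    def labels(self, rec: _Record) -> InstanceLabels:
        if rec.domain == "target" and not self.allow_target_labels:
            raise QuarantineError(
                f"target-domain labels are quarantined during training "
                f"({rec.image_path})")
        if rec.label_path is None:
            raise UsageError(f"no labels recorded for {rec.image_path}")
        return read_labels(rec.label_path)


class _CropSampler:
    """Random crop + augmentation stream over preloaded volumes."""

    def __init__(self, images: list[np.ndarray],
                 maps: list[BCDMaps] | None,
                 crop_size, aug: AugmentConfig, domain_tag: str,
                 rng: np.random.Generator):
        if not images:
            raise UsageError(f"no volumes for domain {domain_tag!r}")
        self.images = images
        self.maps = maps
        self.crop_size = crop_size
        self.aug = aug
        self.domain_tag = domain_tag
        self.rng = rng

    def sample(self) -> TrainSample:
        i = int(self.rng.integers(len(self.images)))
        img = self.images[i]
        cz, cy, cx = self.crop_size
        if any(c > s for c, s in zip(self.crop_size, img.shape)):
            raise ShapeError(f"crop {self.crop_size} exceeds volume "
                             f"{img.shape}")
        z = int(self.rng.integers(img.shape[0] - cz + 1))
        y = int(self.rng.integers(img.shape[1] - cy + 1))
        x = int(self.rng.integers(img.shape[2] - cx + 1))
        sl = (slice(z, z + cz), slice(y, y + cy), slice(x, x + cx))
        crop = img[sl]
        maps = None
        if self.maps is not None:
            m = self.maps[i]
            maps = BCDMaps(B=m.B[sl], C=m.C[sl],
                           D=None if m.D is None else m.D[sl])
        return augment(crop, maps, self.aug, self.rng,
                       domain_tag=self.domain_tag)

    def batch(self, n: int) -> list[TrainSample]:
        return [self.sample() for _ in range(n)]


def _stack_images(samples: list[TrainSample], which: str) -> np.ndarray:
    return np.stack([getattr(s, which) for s in samples])[:, None]


def _stack_maps(samples: list[TrainSample]) -> np.ndarray:
    return np.stack([s.labels.stack() for s in samples])


# ---------------------------------------------------------------------------
# networks bundle and checkpointing
# ---------------------------------------------------------------------------

class Networks:
    """The two generators, three discriminators and their optimisers."""

    def __init__(self, config: TrainConfig):
        self.config = config
        ss = np.random.SeedSequence([config.seed, 0x10])
        rngs = [np.random.default_rng(s) for s in ss.spawn(5)]
        gcfg = GeneratorConfig(depth=config.gen_depth, width=config.gen_width,
                               seg_channels=config.seg_channels)
        self.F = UNetGenerator(gcfg, rng=rngs[0])
        self.G = UNetGenerator(gcfg, rng=rngs[1])
        dcfg_img = DiscriminatorConfig(in_channels=1,
                                       n_layers=config.disc_layers,
                                       base_width=config.disc_width)
        dcfg_seg = replace(dcfg_img, in_channels=config.seg_channels)
        self.D_Y_img = PatchDiscriminator(dcfg_img, rng=rngs[2])
        self.D_X_img = PatchDiscriminator(dcfg_img, rng=rngs[3])
        self.D_X_seg = PatchDiscriminator(dcfg_seg, rng=rngs[4])
        self.opt_gen = AdamW(self.F.parameters() + self.G.parameters(),
                             lr=config.lr, weight_decay=config.weight_decay)
        self.opt_disc = AdamW(self.D_Y_img.parameters() +
                              self.D_X_img.parameters() +
                              self.D_X_seg.parameters(),
                              lr=config.lr, weight_decay=config.weight_decay)

    def named(self) -> dict[str, object]:
        return {"F": self.F, "G": self.G, "D_Y_img": self.D_Y_img,
                "D_X_img": self.D_X_img, "D_X_seg": self.D_X_seg}


def save_checkpoint(path: str, nets: Networks, iteration: int,
                    rng_state: dict | None = None) -> None:
    arrays: dict[str, np.ndarray] = {}
    for prefix, mod in nets.named().items():
        for k, v in mod.state_dict().items():
            arrays[f"{prefix}/{k}"] = v
    for prefix, opt in (("opt_gen", nets.opt_gen),
                        ("opt_disc", nets.opt_disc)):
        for k, v in opt.state_dict().items():
            arrays[f"{prefix}/{k}"] = v
    meta = {"iteration": int(iteration),
            "config": nets.config.to_dict(),
            "arch_hash": nets.config.arch_hash(),
            "rng_state": rng_state}
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str) -> tuple[Networks, int, dict | None]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        config = TrainConfig.from_dict(meta["config"])
        if config.arch_hash() != meta["arch_hash"]:
            raise UsageError("checkpoint arch hash mismatch")
        nets = Networks(config)
        for prefix, mod in nets.named().items():
            state = {k[len(prefix) + 1:]: data[k] for k in data.files
                     if k.startswith(prefix + "/")}
            mod.load_state_dict(state)
        for prefix, opt in (("opt_gen", nets.opt_gen),
                            ("opt_disc", nets.opt_disc)):
            state = {k[len(prefix) + 1:]: data[k] for k in data.files
                     if k.startswith(prefix + "/")}
            if state:
                opt.load_state_dict(state)
    return nets, int(meta["iteration"]), meta.get("rng_state")


def resume_compatible(path: str, config: TrainConfig) -> None:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
    if meta["arch_hash"] != config.arch_hash():
        raise UsageError("cannot resume: checkpoint was trained with an "
                         "incompatible architecture config")


# ---------------------------------------------------------------------------
# one optimisation step
# ---------------------------------------------------------------------------

def train_step(batch_x: list[TrainSample], batch_y: list[TrainSample] | None,
               nets: Networks, lr: float | None = None) -> obj.LossReport:
    """One iteration of the full objective (or the supervised baseline).

    ``batch_x`` carries source samples with encoded labels; ``batch_y``
    target samples without labels (may be ``None`` in baseline mode).
    """
    cfg = nets.config
    x_aug = Tensor(_stack_images(batch_x, "augmented"))
    x_clean = _stack_images(batch_x, "clean")
    x_bcd = _stack_maps(batch_x)

    if cfg.mode == "source_only_baseline":
        out_f = nets.F(x_aug)
        seg_f = obj.seg_supervised_loss(out_f.seg, x_bcd)
        total, report = obj.total_objective({"seg_F": seg_f})
        nets.opt_gen.zero_grad()
        total.backward()
        nets.opt_gen.step(lr=lr)
        return report

    if batch_y is None:
        raise UsageError("cysgan mode needs target-domain samples")
    y_aug = Tensor(_stack_images(batch_y, "augmented"))
    y_clean = _stack_images(batch_y, "clean")

    # ---- generator forwards -------------------------------------------
    out_f = nets.F(x_aug)                    # (y_hat_img, x_hat_seg)
    y_hat_img = out_f.image
    y_hat_det = y_hat_img.detach()
    out_g_cycle = nets.G(y_hat_img)          # cycle path, grads reach F
    out_g_sup = nets.G(y_hat_det)            # supervised path, F shielded

    out_g = nets.G(y_aug)                    # (x_hat_img, G(y)[S])
    x_hat_img = out_g.image
    x_hat_det = x_hat_img.detach()
    out_f_cycle = nets.F(x_hat_img)
    out_f_sc = nets.F(x_hat_det)             # seg of translated target crop

    # ---- discriminator update (real vs detached fakes) ----------------
    d_y_real = nets.D_Y_img(Tensor(y_clean))
    d_y_fake = nets.D_Y_img(Tensor(y_hat_img.data))
    d_x_real = nets.D_X_img(Tensor(x_clean))
    d_x_fake = nets.D_X_img(Tensor(x_hat_img.data))
    d_losses = {
        "disc_Y_img": obj.lsgan_d_loss(d_y_real, d_y_fake,
                                       fake_label=cfg.lsgan_fake_label),
        "disc_X_img": obj.lsgan_d_loss(d_x_real, d_x_fake,
                                       fake_label=cfg.lsgan_fake_label),
    }
    if not cfg.no_semisup:
        # two fake streams: G's segmentation of the real target crop (the
        # inference-time output) and F's segmentation of its back-translation
        d_s_real = nets.D_X_seg(Tensor(x_bcd))
        d_s_fake_g = nets.D_X_seg(Tensor(out_g.seg.data))
        d_s_fake_f = nets.D_X_seg(Tensor(out_f_sc.seg.data))
        d_losses["disc_X_seg"] = obj.lsgan_d_loss(
            d_s_real, [d_s_fake_g, d_s_fake_f],
            fake_label=cfg.lsgan_fake_label)
    d_total = None
    for t in d_losses.values():
        d_total = t if d_total is None else d_total + t
    if not np.isfinite(float(d_total.data)):
        raise TrainingError("non-finite discriminator loss")
    nets.opt_disc.zero_grad()
    d_total.backward()
    nets.opt_disc.step(lr=lr)

    # ---- generator update against the refreshed discriminators --------
    terms: dict[str, Tensor] = {}
    terms["gan_F"] = obj.lsgan_g_loss(nets.D_Y_img(y_hat_img))
    terms["gan_G"] = obj.lsgan_g_loss(nets.D_X_img(x_hat_img))
    terms["cyc"] = obj.cycle_loss(out_g_cycle.image, x_clean,
                                  out_f_cycle.image, y_clean)
    terms["seg_F"] = obj.seg_supervised_loss(out_f.seg, x_bcd)
    terms["seg_G"] = obj.seg_supervised_loss(out_g_sup.seg, x_bcd)
    if not cfg.no_semisup:
        terms["sc"] = obj.structural_consistency_loss(out_g.seg,
                                                      out_f_sc.seg)
        terms["segGAN_G"], terms["segGAN_F"] = obj.seg_adversarial_g_losses(
            nets.D_X_seg(out_g.seg), nets.D_X_seg(out_f_sc.seg))
    total, report = obj.total_objective(terms, no_semisup=cfg.no_semisup)
    for k, v in d_losses.items():
        report.terms[k] = float(v.data)
    nets.opt_gen.zero_grad()
    total.backward()
    nets.opt_gen.step(lr=lr)
    return report


# ---------------------------------------------------------------------------
# fit / infer
# ---------------------------------------------------------------------------

def _build_samplers(config: TrainConfig, dataset: DatasetBundle,
                    rng: np.random.Generator):
    aug = config.effective_augment()
    encode = (lambda lab: encode_bc(lab, config.contour_radius)) \
        if config.bc_only else \
        (lambda lab: encode_bcd(lab, config.contour_radius,
                                config.d_clip_in, config.d_clip_out))
    src_imgs, src_maps = [], []
    for rec in dataset.roles("source_train"):
        src_imgs.append(dataset.image(rec).data.astype(np.float32))
        src_maps.append(encode(dataset.labels(rec)))
    src = _CropSampler(src_imgs, src_maps, config.crop_size, aug, "source",
                       rng)
    tgt = None
    if config.mode == "cysgan":
        tgt_imgs = [dataset.image(rec).data.astype(np.float32)
                    for rec in dataset.roles("target_train")]
        tgt = _CropSampler(tgt_imgs, None, config.crop_size, aug, "target",
                           rng)
    return src, tgt


def fit(config: TrainConfig, manifest_path: str, out_dir: str | None = None,
        resume_from: str | None = None, progress: bool = False) -> str:
    """Run the optimisation loop; returns the final checkpoint path.

    All randomness (init, crop order, augmentation) derives from
    ``config.seed``. Structured per-term loss records are appended to
    ``train_log.jsonl`` every ``config.log_every`` iterations.
    """
    out_dir = out_dir or os.path.dirname(os.path.abspath(manifest_path))
    os.makedirs(out_dir, exist_ok=True)
    dataset = DatasetBundle(manifest_path, allow_target_labels=False)

    start_iter = 0
    if resume_from is not None:
        resume_compatible(resume_from, config)
        nets, start_iter, rng_state = load_checkpoint(resume_from)
        nets.config = config
        rng = np.random.default_rng()
        if rng_state is not None:
            rng.bit_generator.state = rng_state
    else:
        nets = Networks(config)
        rng = np.random.default_rng(np.random.SeedSequence([config.seed,
                                                            0x20]))
    src, tgt = _build_samplers(config, dataset, rng)

    log_path = os.path.join(out_dir, "train_log.jsonl")
    final_path = os.path.join(out_dir, "checkpoint_final.npz")
    iterator = range(start_iter, config.iterations)
    if progress:
        from tqdm import tqdm
        iterator = tqdm(iterator, desc="train")
    log_f = open(log_path, "a")
    try:
        for it in iterator:
            lr = cosine_annealed_lr(config.lr, it, config.iterations)
            batch_x = src.batch(config.batch_size)
            batch_y = tgt.batch(config.batch_size) if tgt is not None \
                else None
            report = train_step(batch_x, batch_y, nets, lr=lr)
            if config.log_every and (it % config.log_every == 0
                                     or it == config.iterations - 1):
                rec = {"iteration": it, "lr": lr, "total": report.total}
                rec.update(report.terms)
                log_f.write(json.dumps(rec) + "\n")
                log_f.flush()
            if config.checkpoint_every and it and \
                    it % config.checkpoint_every == 0:
                save_checkpoint(
                    os.path.join(out_dir, f"checkpoint_{it:07d}.npz"),
                    nets, it + 1, rng_state=rng.bit_generator.state)
    finally:
        log_f.close()
    save_checkpoint(final_path, nets, config.iterations,
                    rng_state=rng.bit_generator.state)
    return final_path


@dataclass(frozen=True)
class TilingConfig:
    tile: tuple[int, int, int] = (16, 16, 16)
    overlap: int = 4


def _ramp_weights(shape, overlap: int) -> np.ndarray:
    """Separable cosine-ramp blending window, 1 in the tile core."""
    ws = []
    for n in shape:
        w = np.ones(n, dtype=np.float32)
        m = min(overlap, n // 2)
        if m > 0:
            ramp = 0.5 * (1.0 - np.cos(np.pi * (np.arange(1, m + 1) / m)))
            # avoid exact zeros so every voxel keeps positive total weight
            ramp = 0.01 + 0.99 * ramp
            w[:m] = ramp
            w[-m:] = ramp[::-1]
        ws.append(w)
    return ws[0][:, None, None] * ws[1][None, :, None] * ws[2][None, None, :]


def infer(checkpoint_path: str, volume: Volume,
          tiling: TilingConfig = TilingConfig(),
          strip_head: bool = True,
          return_maps: bool = False):
    """Segment a whole volume with the target-domain generator ``G``.

    The generator runs over overlapping tiles; per-channel predictions are
    blended with cosine-ramp weights and the blended maps decoded by the
    marker-controlled watershed. Returns :class:`InstanceLabels` (and the
    blended :class:`BCDMaps` if ``return_maps``).
    """
    nets, _, _ = load_checkpoint(checkpoint_path)
    cfg = nets.config
    nets.G.eval()
    model = strip_translation_head(nets.G) if strip_head else None
    gen = nets.G
    div = 2 ** cfg.gen_depth
    tile = tuple(min(t, s) for t, s in zip(tiling.tile, volume.shape))
    if any(t % div or t < div for t in tile):
        raise UsageError(f"tile {tile} incompatible with generator "
                         f"divisor {div}")
    data = volume.data.astype(np.float32)
    shape = data.shape
    nc = cfg.seg_channels
    acc = np.zeros((nc, *shape), dtype=np.float64)
    wacc = np.zeros(shape, dtype=np.float64)
    weights = _ramp_weights(tile, tiling.overlap)

    def tile_starts(n, t):
        if n <= t:
            return [0]
        step = max(t - tiling.overlap, 1)
        starts = list(range(0, n - t, step)) + [n - t]
        return sorted(set(starts))

    for z0 in tile_starts(shape[0], tile[0]):
        for y0 in tile_starts(shape[1], tile[1]):
            for x0 in tile_starts(shape[2], tile[2]):
                sl = (slice(z0, z0 + tile[0]), slice(y0, y0 + tile[1]),
                      slice(x0, x0 + tile[2]))
                crop = data[sl][None, None]
                if strip_head:
                    seg = model(Tensor(crop)).data[0]
                else:
                    seg = gen(Tensor(crop)).seg.data[0]
                acc[(slice(None),) + sl] += seg * weights
                wacc[sl] += weights
    blended = (acc / np.maximum(wacc, 1e-12)).astype(np.float32)
    maps = BCDMaps.from_stack(blended)
    labels = decode_bcd(maps, theta_fg=cfg.decode.theta_fg,
                        theta_contour=cfg.decode.theta_contour,
                        theta_seed=cfg.decode.theta_seed,
                        min_seed_size=cfg.decode.min_seed_size,
                        min_instance_size=cfg.decode.min_instance_size)
    if return_maps:
        return labels, maps
    return labels
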