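"""Training objectives: LSGAN, cycle-consistency, supervised BCD losses,
structural consistency, segmentation-based adversarial losses, and their
uniform-weight composition.

Conventions (all means are over voxels / patch-map elements, per batch):

* LSGAN generator target is +1; the discriminator's fake target defaults to
  0 (the convention of the reference CycleGAN implementation) and can be
  switched to -1 via ``fake_label``.
* The supervised segmentation loss is BCE on the B and C probability
  channels plus MSE on the D regression channel, computed against *binary*
  encoded targets. When it is applied to outputs derived from a synthesized
  image, that image must be detached first so segmentation objectives never
  steer the translation head.
* The total objective is the unweighted sum of the enabled generator-side
  terms; ablation flags remove whole groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ShapeError, TrainingError, UsageError
from .nn import Tensor, core

__all__ = ["LossReport", "lsgan_g_loss", "lsgan_d_loss", "cycle_loss",
           "seg_supervised_loss", "structural_consistency_loss",
           "seg_adversarial_g_losses", "total_objective",
           "GENERATOR_TERMS", "SEMISUP_TERMS"]

# generator-side term names, in the order they enter the full objective
GENERATOR_TERMS = ("gan_F", "gan_G", "cyc", "seg_F", "seg_G",
                   "sc", "segGAN_G", "segGAN_F")
SEMISUP_TERMS = ("sc", "segGAN_G", "segGAN_F")
BCE_EPS = 1e-7


@dataclass
class LossReport:
    """Per-term scalar values plus the generator-side total."""

    terms: dict[str, float] = field(default_factory=dict)
    total: float = 0.0

    def __getitem__(self, key: str) -> float:
        return self.terms[key]

    def __contains__(self, key: str) -> bool:
        return key in self.terms


def lsgan_g_loss(disc_scores_on_fake: Tensor) -> Tensor:
    """Generator-side least-squares loss: mean (score - 1)^2."""
    return core.mean_sq_to_const(disc_scores_on_fake, 1.0)


def lsgan_d_loss(scores_real: Tensor, scores_fake, fake_label: float = 0.0
                 ) -> Tensor:
    """Discriminator least-squares loss.

    ``scores_fake`` may be a single tensor or a sequence of tensors (e.g.
    the two fake streams seen by the segmentation discriminator), whose
    squared errors are pooled by averaging over all their elements.
    """
    real_term = core.mean_sq_to_const(scores_real, 1.0)
    fakes = (list(scores_fake) if isinstance(scores_fake, (list, tuple))
             else [scores_fake])
    fake_terms = [core.mean_sq_to_const(f, fake_label) for f in fakes]
    # pool: average of per-stream means weighted by element count
    sizes = np.array([f.data.size for f in fakes], dtype=np.float64)
    weights = sizes / sizes.sum()
    fake_total = fake_terms[0] * float(weights[0])
    for t, w in zip(fake_terms[1:], weights[1:]):
        fake_total = fake_total + t * float(w)
    return real_term + fake_total


def cycle_loss(reconstructed_x, clean_x, reconstructed_y, clean_y) -> Tensor:
    """L1 reconstruction in both domains against the *clean* crops."""
    return core.abs_mean(reconstructed_x, _arr(clean_x)) + \
        core.abs_mean(reconstructed_y, _arr(clean_y))


def _arr(x) -> np.ndarray:
    return x.data if isinstance(x, Tensor) else np.asarray(x)


def _check_binary(a: np.ndarray, name: str) -> None:
    if not np.isin(a, (0.0, 1.0)).all():
        raise UsageError(f"supervised target {name} must be binary; "
                         "encode labels first")


def seg_supervised_loss(pred: Tensor, target) -> Tensor:
    """BCE(B) + BCE(C) + MSE(D) against encoded (binary B/C) targets.

    ``pred`` is an (N, 3, ...) or (N, 2, ...) seg output; ``target`` a
    matching stack (numpy or BCDMaps-stacked, batch-broadcast not allowed).
    """
    t = _arr(target)
    if pred.data.shape != t.shape:
        raise ShapeError(f"pred {pred.data.shape} vs target {t.shape}")
    nc = t.shape[1]
    _check_binary(t[:, 0], "B")
    _check_binary(t[:, 1], "C")
    loss = core.bce_mean(_chan(pred, 0), t[:, 0:1], eps=BCE_EPS) + \
        core.bce_mean(_chan(pred, 1), t[:, 1:2], eps=BCE_EPS)
    if nc == 3:
        loss = loss + core.sq_diff_mean(_chan(pred, 2), t[:, 2:3])
    return loss


def _chan(t: Tensor, ch: int) -> Tensor:
    data = t.data[:, ch:ch + 1]

    def bwd(g):
        if t.requires_grad:
            full = np.zeros_like(t.data)
            full[:, ch:ch + 1] = g
            t._accumulate(full)

    return Tensor(data, parents=(t,), backward=bwd)


def structural_consistency_loss(seg_from_g: Tensor,
                                seg_from_f_of_translated: Tensor) -> Tensor:
    """Mean L1 between the two generators' segmentation stacks for the
    same underlying target-domain crop (channels weigh equally since they
    share one spatial shape)."""
    return core.abs_mean(seg_from_g, seg_from_f_of_translated)


def seg_adversarial_g_losses(disc_scores_on_pred_g: Tensor,
                             disc_scores_on_pred_f: Tensor
                             ) -> tuple[Tensor, Tensor]:
    """Generator-side LSGAN terms for the two predicted-seg streams."""
    return (lsgan_g_loss(disc_scores_on_pred_g),
            lsgan_g_loss(disc_scores_on_pred_f))


def total_objective(terms: dict[str, Tensor], no_semisup: bool = False
                    ) -> tuple[Tensor, LossReport]:
    """Uniform-weight sum of the enabled generator-side terms.

    Returns the differentiable total and a scalar report (which also keeps
    any extra, non-generator entries passed in, e.g. discriminator losses,
    out of the total). Raises :class:`TrainingError` on a non-finite term.
    """
    enabled = [t for t in GENERATOR_TERMS
               if not (no_semisup and t in SEMISUP_TERMS)]
    report = LossReport()
    total: Tensor | None = None
    for name in enabled:
        if name not in terms:
            continue
        term = terms[name]
        val = float(term.data)
        if not np.isfinite(val):
            raise TrainingError(f"non-finite loss term {name!r}: {val}")
        report.terms[name] = val
        total = term if total is None else total + term
    for name, term in terms.items():
        if name in report.terms or name in GENERATOR_TERMS:
            continue
        val = float(term.data if isinstance(term, Tensor) else term)
        if not np.isfinite(val):
            raise TrainingError(f"non-finite loss term {name!r}: {val}")
        report.terms[name] = val
    if total is None:
        total = Tensor(np.asarray(0.0))
    report.total = float(total.data)
    return total, report
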