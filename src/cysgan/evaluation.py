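"""Instance-level matching and the AP-50 metric.

AP-50 is average precision with instance matches counted at IoU strictly
greater than 0.5 (strict inequality guarantees the geometric matching is
one-to-one). Predictions are ranked by a confidence score - by default the
mean predicted foreground probability inside each instance, or 1.0 when no
probability map is available - with deterministic tie-breaking (larger
instance first, then lower ID). Matching is greedy in rank order and the
average precision is the area under the all-point-interpolated
precision-recall curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ShapeError
from .volumes_io import InstanceLabels

__all__ = ["MatchRow", "MatchTable", "iou_matrix", "ap50",
           "mean_b_scores"]


@dataclass
class MatchRow:
    pred_id: int
    gt_id: int | None
    iou: float
    score: float


@dataclass
class MatchTable:
    rows: list[MatchRow] = field(default_factory=list)
    tp: int = 0
    fp: int = 0
    fn: int = 0


def _labels_array(x) -> np.ndarray:
    return x.data if isinstance(x, InstanceLabels) else np.asarray(x)


def iou_matrix(pred, gt) -> dict[tuple[int, int], float]:
    """Pairwise IoU of every overlapping (pred, gt) instance pair.

    Returned as a sparse mapping ``(pred_id, gt_id) -> IoU``;
    non-overlapping pairs are absent.
    """
    p, g = _labels_array(pred), _labels_array(gt)
    if p.shape != g.shape:
        raise ShapeError(f"shape mismatch: {p.shape} vs {g.shape}")
    p = p.ravel().astype(np.int64)
    g = g.ravel().astype(np.int64)
    both = (p > 0) & (g > 0)
    p_sizes = np.bincount(p[p > 0])
    g_sizes = np.bincount(g[g > 0])
    if not both.any():
        return {}
    gmax = int(g.max()) + 1
    pairs = p[both] * gmax + g[both]
    uniq, counts = np.unique(pairs, return_counts=True)
    out = {}
    for pair, inter in zip(uniq, counts):
        pid, gid = int(pair // gmax), int(pair % gmax)
        union = int(p_sizes[pid]) + int(g_sizes[gid]) - int(inter)
        out[(pid, gid)] = float(inter) / float(union)
    return out


def mean_b_scores(pred, b_map: np.ndarray) -> dict[int, float]:
    """Default confidence: mean predicted foreground probability per
    instance."""
    p = _labels_array(pred)
    if p.shape != np.asarray(b_map).shape:
        raise ShapeError("B map shape mismatch")
    ids = np.unique(p)
    ids = ids[ids > 0]
    return {int(i): float(np.asarray(b_map)[p == i].mean()) for i in ids}


def ap50(pred, gt, scores: dict[int, float] | None = None,
         iou_threshold: float = 0.5,
         return_table: bool = False):
    """Average precision at IoU > ``iou_threshold``.

    ``scores``: per-prediction confidences; missing entries (or ``None``)
    default to 1.0. Empty ground truth is defined as 1.0 against empty
    predictions and 0.0 otherwise.
    """
    p, g = _labels_array(pred), _labels_array(gt)
    if p.shape != g.shape:
        raise ShapeError(f"shape mismatch: {p.shape} vs {g.shape}")
    pred_ids = np.unique(p)
    pred_ids = pred_ids[pred_ids > 0]
    gt_ids = np.unique(g)
    gt_ids = gt_ids[gt_ids > 0]
    n_gt = int(gt_ids.size)
    if n_gt == 0:
        ap = 1.0 if pred_ids.size == 0 else 0.0
        if return_table:
            return ap, MatchTable(fp=int(pred_ids.size))
        return ap
    if pred_ids.size == 0:
        if return_table:
            return 0.0, MatchTable(fn=n_gt)
        return 0.0

    scores = scores or {}
    sizes = np.bincount(p.ravel().astype(np.int64))
    ranked = sorted(
        (int(i) for i in pred_ids),
        key=lambda i: (-scores.get(i, 1.0), -int(sizes[i]), i))
    ious = iou_matrix(p, g)

    matched_gt: set[int] = set()
    table = MatchTable()
    tp_flags = []
    for pid in ranked:
        cands = [(gid, v) for (pp, gid), v in ious.items()
                 if pp == pid and v > iou_threshold
                 and gid not in matched_gt]
        if cands:
            gid, best = max(cands, key=lambda t: (t[1], -t[0]))
            matched_gt.add(gid)
            tp_flags.append(True)
            table.rows.append(MatchRow(pid, gid, best,
                                       scores.get(pid, 1.0)))
        else:
            tp_flags.append(False)
            table.rows.append(MatchRow(pid, None, 0.0,
                                       scores.get(pid, 1.0)))
    tp_flags = np.asarray(tp_flags)
    tp_cum = np.cumsum(tp_flags)
    fp_cum = np.cumsum(~tp_flags)
    recall = tp_cum / n_gt
    precision = tp_cum / (tp_cum + fp_cum)
    # all-point interpolation: precision envelope from the right
    prec_env = np.maximum.accumulate(precision[::-1])[::-1]
    prev_r = 0.0
    ap = 0.0
    for r, pe in zip(recall, prec_env):
        ap += (r - prev_r) * pe
        prev_r = r
    table.tp = int(tp_cum[-1])
    table.fp = int(fp_cum[-1])
    table.fn = n_gt - table.tp
    if return_table:
        return float(ap), table
    return float(ap)
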