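"""Task-aligned positive/negative sample assignment (TAL).

For each ground-truth instance, anchor points falling inside the gt box are
ranked by the alignment metric m = score^a * IoU^b (score taken at the gt
class from the current aligned predictions, IoU between the currently
decoded box and the gt); the top-k candidates become positives. An anchor
claimed by several instances goes to the one with the highest m. Soft
classification targets are m normalized per instance to its maximum IoU.

Defaults a = 1, b = 6, k = 13 are the published task-aligned-learning
values; all three are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import AssignConfig
from .geometry import Box, iou_matrix

__all__ = ["Assignment", "tal_assign", "lr_schedule"]


@dataclass
class Assignment:
    num_anchors: int
    positive_indices: np.ndarray      # (P,) anchor indices
    positive_labels: np.ndarray       # (P,) class per positive
    positive_gt_index: np.ndarray     # (P,) matched instance per positive
    positive_gt_boxes: np.ndarray     # (P, 4) matched boxes, xyxy
    positive_strides: np.ndarray      # (P,) anchor strides
    soft_targets: np.ndarray          # (P,) alignment-normalized targets
    metric: np.ndarray = field(repr=False, default=None)  # (A, G) diagnostics

    @property
    def n_pos(self) -> int:
        return len(self.positive_indices)

    @property
    def n_neg(self) -> int:
        return self.num_anchors - self.n_pos


def tal_assign(anchors: np.ndarray, strides: np.ndarray, scores: np.ndarray,
               boxes: np.ndarray, gts: list[tuple[Box, int]],
               cfg: AssignConfig | None = None) -> Assignment:
    """Assign anchors spanning all pyramid levels to ground-truth instances.

    `anchors` is (A, 2) xy, `strides` (A,), `scores` (A, num_classes) current
    classification scores, `boxes` (A, 4) currently decoded boxes. An image
    with zero ground truth yields an all-negative assignment.
    """
    cfg = cfg or AssignConfig()
    a = len(anchors)
    empty = lambda: Assignment(a, np.empty(0, np.int64), np.empty(0, np.int64),
                               np.empty(0, np.int64), np.empty((0, 4)),
                               np.empty(0), np.empty(0))
    if not gts:
        return empty()
    if cfg.mode == "center":
        return _center_assign(anchors, strides, gts, cfg, empty)
    gt_boxes = np.array([[g.x_min, g.y_min, g.x_max, g.y_max] for g, _ in gts])
    gt_labels = np.array([lbl for _, lbl in gts], dtype=np.int64)
    g = len(gts)

    ax, ay = anchors[:, 0][:, None], anchors[:, 1][:, None]
    inside = ((ax > gt_boxes[None, :, 0]) & (ax < gt_boxes[None, :, 2])
              & (ay > gt_boxes[None, :, 1]) & (ay < gt_boxes[None, :, 3]))  # (A, G)
    ious = iou_matrix(boxes, gt_boxes)                          # (A, G)
    cls_score = np.clip(scores[:, gt_labels], 1e-9, 1.0)        # (A, G)
    metric = (cls_score ** cfg.metric_alpha) * (ious ** cfg.metric_beta)
    metric = np.where(inside, metric, -1.0)

    # per-gt top-k candidates among inside anchors (ties -> lower index)
    chosen = np.full((a, g), False)
    for j in range(g):
        cand = np.where(inside[:, j])[0]
        if len(cand) == 0:
            continue
        order = cand[np.lexsort((cand, -metric[cand, j]))]
        chosen[order[:cfg.topk], j] = True

    # anchors claimed by several instances go to the highest-metric one
    claimed = np.where(chosen, metric, -1.0)
    best_gt = np.argmax(claimed, axis=1)
    is_pos = claimed[np.arange(a), best_gt] > -1.0
    pos = np.where(is_pos)[0]
    if len(pos) == 0:
        return empty()
    gt_of = best_gt[pos]

    # soft targets: metric normalized per-instance to its max IoU
    soft = np.zeros(len(pos))
    for j in range(g):
        sel = gt_of == j
        if not sel.any():
            continue
        m = metric[pos[sel], j]
        soft[sel] = m / (m.max() + 1e-12) * ious[pos[sel], j].max()

    return Assignment(
        num_anchors=a,
        positive_indices=pos,
        positive_labels=gt_labels[gt_of],
        positive_gt_index=gt_of,
        positive_gt_boxes=gt_boxes[gt_of],
        positive_strides=np.asarray(strides)[pos],
        soft_targets=soft,
        metric=metric,
    )


def _center_assign(anchors, strides, gts, cfg, empty):
    """Geometric-proximity assignment (the pre-task-aligned convention):
    an anchor is positive for a gt if it lies inside the gt box and within
    `center_radius` strides of the gt center; conflicts go to the smaller
    gt. Targets are hard (soft targets fixed at 1)."""
    gt_boxes = np.array([[g.x_min, g.y_min, g.x_max, g.y_max] for g, _ in gts])
    gt_labels = np.array([lbl for _, lbl in gts], dtype=np.int64)
    areas = ((gt_boxes[:, 2] - gt_boxes[:, 0])
             * (gt_boxes[:, 3] - gt_boxes[:, 1]))
    ax, ay = anchors[:, 0][:, None], anchors[:, 1][:, None]
    st = np.asarray(strides)[:, None]
    inside = ((ax > gt_boxes[None, :, 0]) & (ax < gt_boxes[None, :, 2])
              & (ay > gt_boxes[None, :, 1]) & (ay < gt_boxes[None, :, 3]))
    cx = 0.5 * (gt_boxes[:, 0] + gt_boxes[:, 2])[None]
    cy = 0.5 * (gt_boxes[:, 1] + gt_boxes[:, 3])[None]
    near = (np.abs(ax - cx) <= cfg.center_radius * st) \
        & (np.abs(ay - cy) <= cfg.center_radius * st)
    ok = inside & near
    cost = np.where(ok, areas[None, :], np.inf)
    best_gt = np.argmin(cost, axis=1)
    is_pos = np.isfinite(cost[np.arange(len(anchors)), best_gt])
    pos = np.where(is_pos)[0]
    if len(pos) == 0:
        return empty()
    gt_of = best_gt[pos]
    return Assignment(len(anchors), pos, gt_labels[gt_of], gt_of,
                      gt_boxes[gt_of], np.asarray(strides)[pos],
                      np.ones(len(pos)))


def lr_schedule(iteration: int, epoch: int, cfg) -> float:
    """Linear warmup from ratio*base over `warmup_iters`, then stepwise
    decay by `decay_factor` after each listed epoch (epochs 1-based)."""
    base = cfg.lr
    if cfg.warmup_iters > 0 and iteration < cfg.warmup_iters:
        frac = iteration / cfg.warmup_iters
        warm = cfg.warmup_ratio + (1.0 - cfg.warmup_ratio) * frac
    else:
        warm = 1.0
    decay = cfg.decay_factor ** sum(1 for d in cfg.decay_epochs if epoch > d)
    return base * warm * decay
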