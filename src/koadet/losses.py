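"""Bounding-box regression losses (IoU family through EIoU) and
classification losses (focal with a difficulty scale, weighted BCE).

Two surfaces are provided. The scalar :class:`~koadet.geometry.Box` API
(`eiou_loss`, `ciou_loss`, ...) is the reference definition used by tests
and diagnostics. The tensor functions (`eiou_loss_t`, `focal_loss_t`, ...)
are the differentiable versions the training loop optimizes; both compute
the same quantities.

EIoU decomposes into three nonnegative parts: the IoU loss 1 - IoU, the
center-distance loss rho^2 / c^2 normalized by the squared diagonal of the
enclosing box, and the edge-length loss penalizing width and height errors
normalized by the enclosing box's width and height. Unlike CIoU's
aspect-ratio term, the edge lengths are penalized directly, so width and
height can shrink or grow independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import nn
from .config import LossConfig
from .geometry import Box, enclosing_box, iou

_EPS = 1e-10


@dataclass(frozen=True)
class EIoUComponents:
    iou_term: float
    distance_term: float
    aspect_term: float

    @property
    def total(self) -> float:
        return self.iou_term + self.distance_term + self.aspect_term


@dataclass
class ClassificationLossConfig:
    """Focal-loss settings: focusing parameter gamma, difficulty-scale
    sensitivity alpha (s = (1-p)^alpha for positives, p^alpha for negatives;
    alpha = 0 turns the scale off)."""

    gamma: float = 2.0
    alpha: float = 0.5
    eps: float = 1e-7

    def __post_init__(self):
        if self.gamma < 0 or self.alpha < 0:
            raise ValueError("gamma and alpha must be nonnegative")


# ---------------------------------------------------------------------------
# scalar box losses
# ---------------------------------------------------------------------------

def eiou_loss(pred: Box, gt: Box) -> EIoUComponents:
    """EIoU between a predicted and a ground-truth box, by named component."""
    hull = enclosing_box(pred, gt)
    cw, ch = hull.width, hull.height
    if cw <= 0 and ch <= 0:
        if pred == gt:
            return EIoUComponents(0.0, 0.0, 0.0)
        raise ValueError("degenerate enclosing box for distinct boxes")
    if cw <= 0 or ch <= 0:
        raise ValueError("degenerate enclosing box (zero width or height)")
    (px, py), (gx, gy) = pred.center, gt.center
    rho2 = (px - gx) ** 2 + (py - gy) ** 2
    c2 = cw * cw + ch * ch
    return EIoUComponents(
        iou_term=1.0 - iou(pred, gt),
        distance_term=rho2 / c2,
        aspect_term=((pred.width - gt.width) ** 2 / (cw * cw)
                     + (pred.height - gt.height) ** 2 / (ch * ch)),
    )


def giou_loss(pred: Box, gt: Box) -> float:
    """GIoU loss (reference baseline for the convergence comparison)."""
    hull = enclosing_box(pred, gt)
    c_area = hull.area
    ix = min(pred.x_max, gt.x_max) - max(pred.x_min, gt.x_min)
    iy = min(pred.y_max, gt.y_max) - max(pred.y_min, gt.y_min)
    inter = max(ix, 0.0) * max(iy, 0.0)
    union = pred.area + gt.area - inter
    giou = inter / (union + _EPS) - (c_area - union) / (c_area + _EPS)
    return 1.0 - giou


def diou_loss(pred: Box, gt: Box) -> float:
    """DIoU loss: 1 - IoU plus normalized squared center distance."""
    hull = enclosing_box(pred, gt)
    (px, py), (gx, gy) = pred.center, gt.center
    rho2 = (px - gx) ** 2 + (py - gy) ** 2
    c2 = hull.width ** 2 + hull.height ** 2
    return 1.0 - iou(pred, gt) + rho2 / (c2 + _EPS)


def _ciou_v(w: float, h: float, wg: float, hg: float) -> float:
    return (4.0 / math.pi ** 2) * (math.atan(wg / hg) - math.atan(w / h)) ** 2


def ciou_loss(pred: Box, gt: Box) -> float:
    """CIoU loss: DIoU plus the aspect-ratio consistency term alpha_v * v."""
    if gt.width <= 0 or gt.height <= 0:
        raise ValueError("ground-truth box must have positive width and height")
    if pred.width <= 0 or pred.height <= 0:
        raise ValueError("predicted box must have positive width and height")
    i = iou(pred, gt)
    v = _ciou_v(pred.width, pred.height, gt.width, gt.height)
    alpha_v = v / ((1.0 - i) + v + _EPS)
    return diou_loss(pred, gt) + alpha_v * v


def ciou_aspect_gradients(pred: Box, gt: Box, eps: float = 1e-5
                          ) -> tuple[float, float]:
    """Central-difference dv/dw and dv/dh of CIoU's aspect term v.

    Diagnostic for the pathology motivating EIoU: the two gradients have
    opposite signs, so width and height cannot both move toward the target
    through this term.
    """
    w, h, wg, hg = pred.width, pred.height, gt.width, gt.height
    dv_dw = (_ciou_v(w + eps, h, wg, hg) - _ciou_v(w - eps, h, wg, hg)) / (2 * eps)
    dv_dh = (_ciou_v(w, h + eps, wg, hg) - _ciou_v(w, h - eps, wg, hg)) / (2 * eps)
    return dv_dw, dv_dh


# ---------------------------------------------------------------------------
# scalar classification losses
# ---------------------------------------------------------------------------

def _difficulty_scale(p: np.ndarray, t: np.ndarray, alpha: float) -> np.ndarray:
    # s = (1-p)^alpha on positives, p^alpha on negatives: up-weights hard
    # examples, suppresses easy ones; alpha = 0 -> s == 1 everywhere.
    return np.where(t > 0.5, (1.0 - p) ** alpha, p ** alpha)


def focal_classification_loss(p: np.ndarray, t: np.ndarray,
                              cfg: ClassificationLossConfig | None = None,
                              ) -> float:
    """Focal loss, summed over positives and negatives, normalized by N_pos.

    Per sample: -s * (1 - p_t)^gamma * log(p_t) with p_t = p for positives
    (t = 1) and 1 - p for negatives (t = 0); s is the difficulty scale.
    Probabilities outside (0, 1) are clamped, never rejected.
    """
    cfg = cfg or ClassificationLossConfig()
    p = np.clip(np.asarray(p, dtype=np.float64), cfg.eps, 1.0 - cfg.eps)
    t = np.asarray(t, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError("probability/label shape mismatch")
    pt = np.where(t > 0.5, p, 1.0 - p)
    s = _difficulty_scale(p, t, cfg.alpha)
    per = -s * (1.0 - pt) ** cfg.gamma * np.log(pt)
    n_pos = max(int((t > 0.5).sum()), 1)
    return float(per.sum() / n_pos)


def weighted_bce(pred: np.ndarray, truth: np.ndarray,
                 weight: np.ndarray | float = 1.0, eps: float = 1e-7) -> float:
    """Mean binary cross-entropy over N elements, optionally scaled per
    element by `weight` (the difficulty scale s)."""
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValueError("prediction/label length mismatch")
    w = np.broadcast_to(np.asarray(weight, dtype=np.float64), pred.shape)
    p = np.clip(pred, eps, 1.0 - eps)
    per = -w * (truth * np.log(p) + (1.0 - truth) * np.log(1.0 - p))
    return float(per.mean())


# ---------------------------------------------------------------------------
# differentiable tensor versions
# ---------------------------------------------------------------------------

def focal_loss_t(p: nn.Tensor, targets: np.ndarray, gamma: float,
                 alpha: float, eps: float = 1e-7) -> nn.Tensor:
    """Tensor focal loss; `targets` is a constant binary array of p's shape."""
    t = np.asarray(targets, dtype=np.float32)
    pc = nn.clip(p, eps, 1.0 - eps)
    one_m = 1.0 - pc
    pos = nn.power(one_m, gamma + alpha) * nn.log(pc)
    neg = nn.power(pc, gamma + alpha) * nn.log(one_m)
    per = -(pos * t + neg * (1.0 - t))
    n_pos = max(int((t > 0.5).sum()), 1)
    return nn.tsum(per) * (1.0 / n_pos)


def eiou_loss_t(pred: nn.Tensor, gt: np.ndarray, eps: float = 1e-7) -> nn.Tensor:
    """Per-row EIoU totals between predicted (N,4) boxes and constant gt."""
    g = np.asarray(gt, dtype=np.float32)
    px1, py1 = pred[:, 0], pred[:, 1]
    px2, py2 = pred[:, 2], pred[:, 3]
    gx1, gy1, gx2, gy2 = g[:, 0], g[:, 1], g[:, 2], g[:, 3]
    iw = nn.maximum(nn.minimum(px2, gx2) - nn.maximum(px1, gx1), 0.0)
    ih = nn.maximum(nn.minimum(py2, gy2) - nn.maximum(py1, gy1), 0.0)
    inter = iw * ih
    area_p = (px2 - px1) * (py2 - py1)
    area_g = (gx2 - gx1) * (gy2 - gy1)
    union = area_p + area_g - inter
    iou_v = inter / (union + eps)
    cw = nn.maximum(px2, gx2) - nn.minimum(px1, gx1)
    ch = nn.maximum(py2, gy2) - nn.minimum(py1, gy1)
    c2 = cw * cw + ch * ch + eps
    dx = (px1 + px2) * 0.5 - (gx1 + gx2) * 0.5
    dy = (py1 + py2) * 0.5 - (gy1 + gy2) * 0.5
    rho2 = dx * dx + dy * dy
    dw = (px2 - px1) - (gx2 - gx1)
    dh = (py2 - py1) - (gy2 - gy1)
    return (1.0 - iou_v) + rho2 / c2 + dw * dw / (cw * cw + eps) \
        + dh * dh / (ch * ch + eps)


def smooth_l1_t(pred: nn.Tensor, target: np.ndarray, beta: float = 1.0) -> nn.Tensor:
    """Per-element smooth-L1 (the replaced baseline regression), summed over
    the last axis. Inputs are expected pre-normalized (e.g. by stride)."""
    t = np.asarray(target, dtype=np.float32)
    d = pred - t
    ad = nn.maximum(d, -d)
    quad = 0.5 * ad * ad * (1.0 / beta)
    lin = ad - 0.5 * beta
    return nn.tsum(nn.minimum(quad, lin), axis=-1)


def weighted_bce_t(pred: nn.Tensor, truth: np.ndarray,
                   weight: np.ndarray | float = 1.0,
                   eps: float = 1e-7) -> nn.Tensor:
    t = np.asarray(truth, dtype=np.float32)
    w = np.asarray(weight, dtype=np.float32)
    p = nn.clip(pred, eps, 1.0 - eps)
    per = -(nn.log(p) * t + nn.log(1.0 - p) * (1.0 - t))
    return nn.tmean(per * w)


def total_loss(cls_prob: nn.Tensor, boxes: nn.Tensor, assignment,
               cfg: LossConfig) -> tuple[nn.Tensor, nn.Tensor, nn.Tensor]:
    """Composite objective: focal classification over all anchors plus mean
    box-regression loss over the positive anchors (unit weights by default).

    `cls_prob` is (A, num_classes) aligned scores, `boxes` is (A, 4) decoded
    aligned boxes, `assignment` a :class:`koadet.assigner.Assignment`.
    """
    a, c = cls_prob.shape
    pos = assignment.positive_indices
    soft = cfg.soft_targets and len(pos) > 0
    if soft:
        # quality-focal form: positives pulled toward the alignment target t,
        # with |t - p|^gamma modulation; negatives as in plain focal
        targets = np.zeros((a, c), dtype=np.float32)
        targets[pos, assignment.positive_labels] = \
            assignment.soft_targets.astype(np.float32)
        pc = nn.clip(cls_prob, cfg.eps, 1.0 - cfg.eps)
        d = pc - targets
        mod = nn.power(nn.maximum(d, -d), cfg.gamma)
        bce = -(nn.log(pc) * targets + nn.log(1.0 - pc) * (1.0 - targets))
        cls = nn.tsum(mod * bce) * (1.0 / max(len(pos), 1))
    else:
        targets = np.zeros((a, c), dtype=np.float32)
        if len(pos):
            targets[pos, assignment.positive_labels] = 1.0
        cls = focal_loss_t(cls_prob, targets, cfg.gamma, cfg.alpha, cfg.eps)
    if len(pos):
        pb = nn.take_rows(boxes, pos)
        if cfg.reg_loss == "l1":
            strides = assignment.positive_strides.reshape(-1, 1).astype(np.float32)
            reg_per = smooth_l1_t(pb * (1.0 / strides),
                                  assignment.positive_gt_boxes / strides)
        else:
            reg_per = eiou_loss_t(pb, assignment.positive_gt_boxes)
        if soft:
            w = assignment.soft_targets.astype(np.float32)
            w = w / max(float(w.sum()), 1e-8)
            reg = nn.tsum(reg_per * w)
        else:
            reg = nn.tmean(reg_per)
    else:
        reg = nn.Tensor(0.0)
    total = cls * cfg.cls_weight + reg * cfg.reg_weight
    return cls, reg, total
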