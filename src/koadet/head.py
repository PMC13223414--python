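"""Task-aligned detection head.

The pyramid features first pass through a shared interactive extractor of
N = 6 3x3 convolutions (group-normalized, 32 groups, ReLU), whose stacked
outputs serve every downstream branch. Two task-aligned predictors (TAPs)
then produce classification scores and box distances: each task computes
layer-attention weights omega in (0,1) over the N interactive layers from
the globally pooled stack, rescales the layers, and predicts through a 1x1
reduction conv and a 3x3 output conv (sigmoid for scores; exponential
mapping scaled by the level stride for the four nonnegative distances).

Two alignment maps are learned from the same interactive stack by pairs of
1x1 convolutions: a spatial probability map M in (0,1) that adjusts the
classification prediction (P_align = sqrt(P * M) by default), and an
8-channel offset map O holding one (di, dj) offset per box boundary, which
re-samples each boundary's distance prediction at its own best nearby
anchor via bilinear interpolation. Disabling alignment (M = 1, O = 0)
reduces the module to a plain decoupled head.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import nn
from .config import HeadConfig
from .geometry import anchor_grid

__all__ = ["TaskAlignedHead", "HeadLevelOutput"]


@dataclass
class HeadLevelOutput:
    """Per-level head products (tensors stay in the autodiff graph)."""

    scores: nn.Tensor          # (A, num_classes) aligned classification scores
    boxes: nn.Tensor           # (A, 4) decoded aligned boxes, xyxy
    distances: nn.Tensor       # (A, 4) aligned (l, t, r, b) distances
    raw_scores: nn.Tensor      # (A, num_classes) pre-alignment scores
    spatial_prob: nn.Tensor    # (1, 1, H, W) alignment map M
    offsets: nn.Tensor         # (1, 8, H, W) alignment map O
    anchors: np.ndarray        # (A, 2) anchor xy coordinates
    stride: float
    shape: tuple[int, int]


class TaskAlignedHead(nn.Module):
    def __init__(self, cfg: HeadConfig | None = None,
                 strides: tuple[float, ...] = (8, 16, 32, 64, 128),
                 seed: int = 0):
        super().__init__()
        self.cfg = cfg = cfg or HeadConfig()
        self.strides = tuple(strides)
        rng = np.random.default_rng(seed)
        c, n = cfg.channels, cfg.num_inter_layers
        if c % cfg.gn_groups != 0:
            raise ValueError(
                f"head channels {c} not divisible by {cfg.gn_groups} groups")
        self.inter_convs = [nn.Conv2d(c, c, 3, bias=False, rng=rng)
                            for _ in range(n)]
        self.inter_norms = [nn.GroupNorm(cfg.gn_groups, c) for _ in range(n)]

        red = max(c // 4, 8)
        prior_bias = -math.log((1.0 - cfg.prior_prob) / cfg.prior_prob)
        self.branches: dict[str, dict] = {}
        for task, out_c in (("cls", cfg.num_classes), ("loc", 4)):
            br = {
                "fc1": nn.Linear(n * c, c, rng=rng),
                "fc2": nn.Linear(c, n, rng=rng),
                "reduce": nn.Conv2d(n * c, c, 1, rng=rng),
                "pred": nn.Conv2d(c, out_c, 3, rng=rng),
            }
            self.branches[task] = br
            setattr(self, f"_{task}_fc1", br["fc1"])
            setattr(self, f"_{task}_fc2", br["fc2"])
            setattr(self, f"_{task}_reduce", br["reduce"])
            setattr(self, f"_{task}_pred", br["pred"])
        self._cls_pred.bias.data[:] = prior_bias

        self.m_conv1 = nn.Conv2d(n * c, red, 1, rng=rng)
        self.m_conv2 = nn.Conv2d(red, 1, 1, rng=rng)
        self.m_conv2.bias.data[:] = prior_bias
        self.o_conv1 = nn.Conv2d(n * c, red, 1, rng=rng)
        self.o_conv2 = nn.Conv2d(red, 8, 1, rng=rng)
        self.o_conv2.weight.data *= 0.01  # start near identity offsets

        self.dist_scale = nn.Parameter(np.ones(len(strides), dtype=np.float32),
                                       no_decay=True)

    # -- pipeline operations ----------------------------------------------
    def interactive_extractor(self, x: nn.Tensor) -> list[nn.Tensor]:
        """N stacked 3x3 conv + GN(32) + ReLU maps, all retained."""
        feats = []
        for conv, norm in zip(self.inter_convs, self.inter_norms):
            x = nn.relu(norm(conv(x)))
            feats.append(x)
        return feats

    def layer_attention(self, inter: list[nn.Tensor], task: str) -> nn.Tensor:
        """omega = sigmoid(fc2(relu(fc1(GAP(concat(inter)))))), one weight per
        interactive layer."""
        br = self.branches[task]
        x = nn.global_avg_pool(nn.concat(inter, axis=1))  # (1, N*C)
        return nn.sigmoid(br["fc2"](nn.relu(br["fc1"](x))))  # (1, N)

    def task_predict(self, inter: list[nn.Tensor], task: str) -> nn.Tensor:
        """Scale layers by omega, concatenate, reduce 1x1, predict 3x3."""
        br = self.branches[task]
        omega = self.layer_attention(inter, task)
        scaled = [f * nn.reshape(omega[:, k], (1, 1, 1, 1))
                  for k, f in enumerate(inter)]
        z = nn.relu(br["reduce"](nn.concat(scaled, axis=1)))
        return br["pred"](z)

    def alignment_maps(self, inter: list[nn.Tensor]
                       ) -> tuple[nn.Tensor, nn.Tensor]:
        """Spatial probability map M in (0,1) and 8-channel offset map O."""
        stack = nn.concat(inter, axis=1)
        m = nn.sigmoid(self.m_conv2(nn.relu(self.m_conv1(stack))))
        o = self.o_conv2(nn.relu(self.o_conv1(stack)))
        return m, o

    def align_classification(self, p: nn.Tensor, m: nn.Tensor) -> nn.Tensor:
        if self.cfg.align_mode == "product":
            return p * m
        return nn.sqrt(p * m)

    def align_localization(self, dist_map: nn.Tensor, o: nn.Tensor) -> nn.Tensor:
        return nn.boundary_sample(dist_map, o)

    # -- forward --------------------------------------------------------------
    def _distances(self, raw: nn.Tensor, level: int) -> nn.Tensor:
        scale = self.dist_scale[level]
        return nn.exp(nn.clip(raw * scale, -12.0, 8.0)) * float(self.strides[level])

    def forward_level(self, feat: nn.Tensor, level: int) -> HeadLevelOutput:
        _, _, h, w = feat.shape
        inter = self.interactive_extractor(feat)
        p = nn.sigmoid(self.task_predict(inter, "cls"))       # (1,K,H,W)
        raw_loc = self.task_predict(inter, "loc")             # (1,4,H,W)
        dist_map = self._distances(raw_loc, level)
        if self.cfg.align:
            m, o = self.alignment_maps(inter)
            p_align = self.align_classification(p, m)
            d_align = self.align_localization(dist_map, o)
        else:
            m = nn.Tensor(np.ones((1, 1, h, w), dtype=np.float32))
            o = nn.Tensor(np.zeros((1, 8, h, w), dtype=np.float32))
            p_align, d_align = p, dist_map

        k = self.cfg.num_classes
        scores = nn.reshape(nn.transpose(p_align, (0, 2, 3, 1)), (h * w, k))
        raw_scores = nn.reshape(nn.transpose(p, (0, 2, 3, 1)), (h * w, k))
        dists = nn.reshape(nn.transpose(d_align, (0, 2, 3, 1)), (h * w, 4))
        anchors = anchor_grid(h, w, self.strides[level])
        ax = anchors[:, 0].astype(np.float32)
        ay = anchors[:, 1].astype(np.float32)
        boxes = nn.stack([ax - dists[:, 0], ay - dists[:, 1],
                          ax + dists[:, 2], ay + dists[:, 3]], axis=1)
        return HeadLevelOutput(scores=scores, boxes=boxes, distances=dists,
                               raw_scores=raw_scores, spatial_prob=m,
                               offsets=o, anchors=anchors,
                               stride=float(self.strides[level]), shape=(h, w))

    def forward(self, pyramid: list[nn.Tensor]) -> list[HeadLevelOutput]:
        if len(pyramid) != len(self.strides):
            raise ValueError("pyramid level count mismatch")
        return [self.forward_level(f, i) for i, f in enumerate(pyramid)]
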