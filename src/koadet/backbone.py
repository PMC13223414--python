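"""EfficientNet-style backbone with compound scaling.

Nine stages: a 3x3 stem convolution, seven MBConv stage groups (mobile
inverted bottlenecks with squeeze-and-excitation), and a classifier stage
(1x1 conv + global pooling + linear). Detection uses the feature maps of
the stride-8, stride-16, and stride-32 stage groups (C4, C5, C6); the
classifier stage exists for structural completeness and optional
pretraining hooks but is skipped by the detection forward pass.

Channel counts are derived from the base profile by the canonical compound
scaling rule: width-scaled channels rounded to the nearest multiple of 8
(not dropping below 90% of the unrounded value) and depth-scaled repeat
counts rounded up.
"""

from __future__ import annotations

import math

import numpy as np

from . import nn
from .config import (BASE_HEAD_CHANNELS, BASE_STAGES, BASE_STEM_CHANNELS,
                     BackboneConfig)

__all__ = ["round_filters", "round_repeats", "SEBlock",
           "DepthwiseSeparableConv", "MBConv", "Backbone"]


def round_filters(channels: int, multiplier: float, divisor: int = 8) -> int:
    c = channels * multiplier
    new = max(divisor, int(c + divisor / 2) // divisor * divisor)
    if new < 0.9 * c:
        new += divisor
    return int(new)


def round_repeats(repeats: int, multiplier: float) -> int:
    return int(math.ceil(repeats * multiplier))


class SEBlock(nn.Module):
    """Squeeze-and-excitation channel gate.

    Global average pool (squeeze), bottleneck transform with ReLU, restore
    with sigmoid: each channel is rescaled by an excitation value in (0, 1).
    """

    def __init__(self, channels: int, se_channels: int,
                 rng: np.random.Generator):
        super().__init__()
        self.reduce = nn.Conv2d(channels, se_channels, 1, rng=rng)
        self.expand = nn.Conv2d(se_channels, channels, 1, rng=rng)

    def excitation(self, x: nn.Tensor) -> nn.Tensor:
        n, c = x.shape[0], x.shape[1]
        s = nn.reshape(nn.global_avg_pool(x), (n, c, 1, 1))
        return nn.sigmoid(self.expand(nn.relu(self.reduce(s))))

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        return x * self.excitation(x)


class DepthwiseSeparableConv(nn.Module):
    """Per-channel spatial convolution followed by 1x1 cross-channel mixing.

    Parameter count is C*k^2 + C*C_out (weights only), strictly fewer than a
    dense convolution's C*C_out*k^2 for C_out > 1, k > 1.
    """

    def __init__(self, cin: int, cout: int, k: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if k % 2 == 0:
            raise ValueError("kernel size must be odd")
        rng = rng or np.random.default_rng(0)
        self.depthwise = nn.Conv2d(cin, cin, k, stride=stride, groups=cin,
                                   bias=False, rng=rng)
        self.pointwise = nn.Conv2d(cin, cout, 1, bias=False, rng=rng)

    def weight_count(self) -> int:
        return self.depthwise.weight.size + self.pointwise.weight.size

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        return self.pointwise(self.depthwise(x))


class MBConv(nn.Module):
    """Mobile inverted bottleneck: expand (1x1 + BN + swish), depthwise k x k
    (+ BN + swish), SE gate, project (1x1 + BN), residual when stride 1 and
    channels match."""

    def __init__(self, cin: int, cout: int, expansion: int, k: int,
                 stride: int, se_ratio: float, drop_rate: float,
                 rng: np.random.Generator):
        super().__init__()
        mid = cin * expansion
        self.has_expand = expansion != 1
        if self.has_expand:
            self.expand_conv = nn.Conv2d(cin, mid, 1, bias=False, rng=rng)
            self.expand_bn = nn.BatchNorm2d(mid)
        self.dw_conv = nn.Conv2d(mid, mid, k, stride=stride, groups=mid,
                                 bias=False, rng=rng)
        self.dw_bn = nn.BatchNorm2d(mid)
        self.se = SEBlock(mid, max(1, int(cin * se_ratio)), rng)
        self.project_conv = nn.Conv2d(mid, cout, 1, bias=False, rng=rng)
        self.project_bn = nn.BatchNorm2d(cout)
        self.use_residual = stride == 1 and cin == cout
        self.drop_rate = drop_rate
        self._drop_rng = np.random.default_rng(rng.integers(2 ** 31))

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        h = x
        if self.has_expand:
            h = nn.silu(self.expand_bn(self.expand_conv(h)))
        h = nn.silu(self.dw_bn(self.dw_conv(h)))
        h = self.se(h)
        h = self.project_bn(self.project_conv(h))
        if self.use_residual:
            if self.drop_rate > 0 and self.training:
                # stochastic depth on the residual branch
                keep = 1.0 - self.drop_rate
                mask = float(self._drop_rng.random() < keep) / keep
                h = h * mask
            h = h + x
        return h


class Backbone(nn.Module):
    """Compound-scaled feature extractor emitting (C4, C5, C6)."""

    MIN_INPUT = 32

    def __init__(self, cfg: BackboneConfig | None = None, num_classes: int = 5,
                 seed: int = 0):
        super().__init__()
        self.cfg = cfg = cfg or BackboneConfig()
        rng = np.random.default_rng(seed)
        w, d, div = cfg.width_multiplier, cfg.depth_multiplier, cfg.channel_divisor

        stem_c = round_filters(BASE_STEM_CHANNELS, w, div)
        self.stem_conv = nn.Conv2d(3, stem_c, 3, stride=2, bias=False, rng=rng)
        self.stem_bn = nn.BatchNorm2d(stem_c)

        self.stage_channels = [stem_c]
        self.blocks: list[nn.Module] = []
        self._stage_end: list[int] = []  # block index ending each stage group
        cin = stem_c
        for expansion, c, r, stride, k in BASE_STAGES:
            cout = round_filters(c, w, div)
            for i in range(round_repeats(r, d)):
                self.blocks.append(MBConv(cin, cout, expansion, k,
                                          stride if i == 0 else 1,
                                          cfg.se_ratio, cfg.drop_rate, rng))
                cin = cout
            self.stage_channels.append(cout)
            self._stage_end.append(len(self.blocks) - 1)

        head_c = round_filters(BASE_HEAD_CHANNELS, w, div)
        self.head_conv = nn.Conv2d(cin, head_c, 1, bias=False, rng=rng)
        self.head_bn = nn.BatchNorm2d(head_c)
        self.fc = nn.Linear(head_c, num_classes, rng=rng)
        self.stage_channels.append(head_c)

        # stage groups 3, 5, 7 (1-based MBConv groups) end at strides 8/16/32
        self._tap_stages = (2, 4, 6)
        self.out_channels = tuple(self.stage_channels[1 + s] for s in self._tap_stages)
        self.out_strides = (8, 16, 32)

        if cfg.pretrained_path:
            self.load_pretrained(cfg.pretrained_path)

    def load_pretrained(self, path) -> int:
        """Load externally supplied weights from an npz archive by parameter
        name; silently skips names or shapes that do not match. Returns the
        number of tensors loaded."""
        with np.load(path, allow_pickle=False) as data:
            loaded = 0
            for name, p in self.named_parameters():
                if name in data.files and data[name].shape == p.shape:
                    p.data = np.asarray(data[name], dtype=np.float32)
                    loaded += 1
        return loaded

    def summary(self) -> dict:
        return {"stage_channels": list(self.stage_channels),
                "out_channels": list(self.out_channels),
                "out_strides": list(self.out_strides)}

    def forward(self, image: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor, nn.Tensor]:
        """Detection forward: grayscale (N,1,H,W) -> (C4, C5, C6)."""
        n, c, h, w = image.shape
        if h < self.MIN_INPUT or w < self.MIN_INPUT:
            raise ValueError(f"image {h}x{w} smaller than {self.MIN_INPUT} px")
        if c == 1:
            image = nn.concat([image, image, image], axis=1)
        x = nn.silu(self.stem_bn(self.stem_conv(image)))
        taps = []
        tap_ends = {self._stage_end[s] for s in self._tap_stages}
        for i, block in enumerate(self.blocks):
            x = block(x)
            if i in tap_ends:
                taps.append(x)
        return tuple(taps)

    def classify(self, image: nn.Tensor) -> nn.Tensor:
        """Full 9-stage pass through the classifier head (logits)."""
        _, _, c6 = self.forward(image)
        x = nn.silu(self.head_bn(self.head_conv(c6)))
        return self.fc(nn.global_avg_pool(x))
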