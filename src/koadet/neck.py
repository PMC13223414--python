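"""Path Aggregation Feature Pyramid (PAFPN).

Top-down fusion of the backbone's (C4, C5, C6) followed by a bottom-up
aggregation path, producing five uniform-channel pyramid levels P3..P7 at
strides 8, 16, 32, 64, 128. Every merge can use learnable softmax-normalized
fusion weights (adaptive fusion) or plain addition; disabling the bottom-up
path reduces the neck to a plain FPN for the ablation harness.

P6 and P7 are produced from P5 by two extra 3x3 stride-2 convolutions (the
second preceded by ReLU); all five outputs pass through a final ReLU so the
pyramid is nonnegative.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .config import NeckConfig

__all__ = ["PAFPN", "PYRAMID_STRIDES"]

PYRAMID_STRIDES = (8, 16, 32, 64, 128)


def _upsample2x(x: nn.Tensor, mode: str) -> nn.Tensor:
    if mode == "nearest":
        return nn.upsample_nearest2x(x)
    if mode == "bilinear":
        return _upsample_bilinear2x(x)
    raise ValueError(f"unknown upsample mode {mode!r}")


def _upsample_bilinear2x(x: nn.Tensor) -> nn.Tensor:
    # separable half-pixel-aligned 2x bilinear: y[2i] = .25 a[i-1] + .75 a[i],
    # y[2i+1] = .75 a[i] + .25 a[i+1], with edge replication
    def along(t: nn.Tensor, axis: int) -> nn.Tensor:
        n = t.shape[axis]
        sl = lambda a, b: tuple(slice(a, b) if d == axis else slice(None)
                                for d in range(t.ndim))
        pad = nn.concat([t[sl(0, 1)], t, t[sl(n - 1, n)]], axis=axis)
        lo = pad[sl(0, n)]
        mid = pad[sl(1, n + 1)]
        hi = pad[sl(2, n + 2)]
        even = lo * 0.25 + mid * 0.75
        odd = mid * 0.75 + hi * 0.25
        inter = nn.stack([even, odd], axis=axis + 1)
        shape = list(t.shape)
        shape[axis] = 2 * n
        return nn.reshape(inter, tuple(shape))

    return along(along(x, 2), 3)


def _crop_to(x: nn.Tensor, h: int, w: int) -> nn.Tensor:
    # deterministic top-left crop after 2x upsampling of a ceil-halved map
    if x.shape[2] == h and x.shape[3] == w:
        return x
    return x[:, :, :h, :w]


class _Fuse(nn.Module):
    """Two-input merge: softmax-weighted sum (adaptive) or plain addition."""

    def __init__(self, adaptive: bool):
        super().__init__()
        self.adaptive = adaptive
        if adaptive:
            self.logits = nn.Parameter(np.zeros(2, dtype=np.float32),
                                       no_decay=True)

    def forward(self, a: nn.Tensor, b: nn.Tensor) -> nn.Tensor:
        if not self.adaptive:
            return a + b
        e = nn.exp(self.logits)
        w = e * nn.power(nn.tsum(e), -1.0)
        return a * w[0] + b * w[1]


class PAFPN(nn.Module):
    def __init__(self, in_channels: tuple[int, int, int],
                 cfg: NeckConfig | None = None, seed: int = 0):
        super().__init__()
        self.cfg = cfg = cfg or NeckConfig()
        rng = np.random.default_rng(seed)
        c = cfg.channels
        self.laterals = [nn.Conv2d(ci, c, 1, rng=rng) for ci in in_channels]
        self.td_fuse = [_Fuse(cfg.adaptive_fusion) for _ in range(2)]
        self.smooth = nn.Conv2d(c, c, 3, rng=rng)
        self.down = [nn.Conv2d(c, c, 3, stride=2, pad=1, rng=rng)
                     for _ in range(2)]
        self.bu_fuse = [_Fuse(cfg.adaptive_fusion) for _ in range(2)]
        self.extra = [nn.Conv2d(c, c, 3, stride=2, pad=1, rng=rng)
                      for _ in range(2)]
        self.out_channels = c
        self.strides = PYRAMID_STRIDES

    # -- pipeline operations ----------------------------------------------
    def lateral_project(self, c4: nn.Tensor, c5: nn.Tensor, c6: nn.Tensor
                        ) -> list[nn.Tensor]:
        """1x1-project the backbone maps to the uniform pyramid width."""
        return [lat(x) for lat, x in zip(self.laterals, (c4, c5, c6))]

    def top_down_fuse(self, laterals: list[nn.Tensor]) -> list[nn.Tensor]:
        """Coarse-to-fine fusion: each finer level adds the 2x-upsampled
        coarser fused level (cropped to size on odd shapes)."""
        fused = [laterals[-1]]
        for k, lat in zip(range(len(laterals) - 2, -1, -1),
                          reversed(laterals[:-1])):
            up = _upsample2x(fused[0], self.cfg.upsample)
            up = _crop_to(up, lat.shape[2], lat.shape[3])
            fused.insert(0, self.td_fuse[k](lat, up))
        return fused  # fine -> coarse

    def bottom_up_aggregate(self, fused: list[nn.Tensor]) -> list[nn.Tensor]:
        """Fine-to-coarse aggregation with stride-2 3x3 convs + ReLU, then
        the two extra stride-2 convs producing P6 and P7."""
        outs = [nn.relu(self.smooth(fused[0]))]
        for k in range(1, len(fused)):
            if self.cfg.bottom_up:
                d = self.down[k - 1](outs[-1])
                d = _crop_to(d, fused[k].shape[2], fused[k].shape[3])
                outs.append(nn.relu(self.bu_fuse[k - 1](d, fused[k])))
            else:
                outs.append(nn.relu(fused[k]))  # plain FPN (ablation)
        p6 = nn.relu(self.extra[0](outs[-1]))
        p7 = nn.relu(self.extra[1](p6))
        outs.extend([p6, p7])
        return outs

    def forward(self, c4: nn.Tensor, c5: nn.Tensor, c6: nn.Tensor
                ) -> list[nn.Tensor]:
        return self.bottom_up_aggregate(self.top_down_fuse(
            self.lateral_project(c4, c5, c6)))
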