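"""Box algebra shared by the losses, head, assigner, and evaluation.

Coordinates are continuous pixel values with the origin at the top-left
corner, x rightward and y downward. Widths are plain differences
(``x_max - x_min``) with no +1 pixel convention, so IoU is scale-free.
Zero-area boxes are legal values (the decode of four zero distances) but
contribute zero to IoU.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "Box", "AnchorPoint", "iou", "iou_matrix", "enclosing_box",
    "decode_distances", "encode_distances", "nms", "Detection",
    "anchor_grid",
]


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle in image pixel coordinates."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self):
        if self.x_max < self.x_min or self.y_max < self.y_min:
            raise ValueError(
                f"invalid box: max < min in {self.as_tuple()}")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x_min, self.y_min, self.x_max, self.y_max)

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x_min + self.x_max), 0.5 * (self.y_min + self.y_max))


@dataclass(frozen=True)
class AnchorPoint:
    """Grid cell center on a pyramid level: ((j+0.5)*stride, (i+0.5)*stride)."""

    level: int
    x: float
    y: float
    stride: float


@dataclass(frozen=True)
class Detection:
    box: Box
    label: int
    score: float


def iou(a: Box, b: Box) -> float:
    """Intersection over union; 0 when disjoint or the union is degenerate."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    inter = max(ix, 0.0) * max(iy, 0.0)
    union = a.area + b.area - inter
    if union <= 0.0:
        return 0.0
    return inter / union


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between (N,4) and (M,4) arrays of xyxy boxes."""
    a = np.atleast_2d(np.asarray(a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(b, dtype=np.float64))
    ix = (np.minimum(a[:, None, 2], b[None, :, 2])
          - np.maximum(a[:, None, 0], b[None, :, 0]))
    iy = (np.minimum(a[:, None, 3], b[None, :, 3])
          - np.maximum(a[:, None, 1], b[None, :, 1]))
    inter = np.clip(ix, 0, None) * np.clip(iy, 0, None)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(union > 0, inter / union, 0.0)
    return out


def enclosing_box(a: Box, b: Box) -> Box:
    """Smallest axis-aligned box containing both inputs (convex hull)."""
    return Box(min(a.x_min, b.x_min), min(a.y_min, b.y_min),
               max(a.x_max, b.x_max), max(a.y_max, b.y_max))


def decode_distances(p: AnchorPoint, distances: Sequence[float]) -> Box:
    """Distance-to-box conversion: (l, t, r, b) offsets from an anchor point."""
    l, t, r, b = distances
    if min(l, t, r, b) < 0:
        raise ValueError(f"negative distance in {distances}")
    return Box(p.x - l, p.y - t, p.x + r, p.y + b)


def encode_distances(box: Box, p: AnchorPoint) -> tuple[float, float, float, float]:
    """Inverse of :func:`decode_distances` for a point inside the box."""
    return (p.x - box.x_min, p.y - box.y_min, box.x_max - p.x, box.y_max - p.y)


def nms(detections: Sequence[Detection | tuple],
        iou_threshold: float = 0.6) -> list[Detection]:
    """Class-wise greedy non-maximum suppression.

    Detections are visited in descending score order (ties broken by lower
    original index, so the result is deterministic); a candidate is kept iff
    its IoU with every same-class survivor is <= the threshold.
    """
    dets = [d if isinstance(d, Detection) else Detection(*d) for d in detections]
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].score, i))
    keep: list[int] = []
    for i in order:
        d = dets[i]
        ok = True
        for j in keep:
            s = dets[j]
            if s.label == d.label and iou(s.box, d.box) > iou_threshold:
                ok = False
                break
        if ok:
            keep.append(i)
    return [dets[i] for i in keep]


def anchor_grid(h: int, w: int, stride: float, level: int = 0) -> np.ndarray:
    """Anchor-point coordinates for an (h, w) feature map, as (h*w, 2) xy."""
    jj, ii = np.meshgrid(np.arange(w), np.arange(h))
    x = (jj.reshape(-1) + 0.5) * stride
    y = (ii.reshape(-1) + 0.5) * stride
    return np.stack([x, y], axis=1).astype(np.float64)
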