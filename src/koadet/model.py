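"""End-to-end detector: backbone -> PAFPN -> task-aligned head -> NMS."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import nn
from .backbone import Backbone
from .config import EvalConfig, RunConfig
from .geometry import Box, Detection, nms
from .head import HeadLevelOutput, TaskAlignedHead
from .neck import PAFPN

__all__ = ["KneeDetector", "save_checkpoint", "load_checkpoint"]


class KneeDetector(nn.Module):
    """Graded knee-OA lesion detector over 8-bit grayscale radiographs."""

    def __init__(self, cfg: RunConfig | None = None):
        super().__init__()
        self.cfg = cfg = cfg or RunConfig()
        seed = cfg.seed
        self.backbone = Backbone(cfg.backbone, num_classes=cfg.head.num_classes,
                                 seed=seed)
        self.neck = PAFPN(self.backbone.out_channels, cfg.neck, seed=seed + 1)
        self.head = TaskAlignedHead(cfg.head, strides=self.neck.strides,
                                    seed=seed + 2)

    def forward(self, image: nn.Tensor) -> list[HeadLevelOutput]:
        c4, c5, c6 = self.backbone(image)
        pyramid = self.neck(c4, c5, c6)
        return self.head(pyramid)

    @staticmethod
    def prepare_image(pixels: np.ndarray) -> nn.Tensor:
        """8-bit grayscale (H, W) raster -> normalized (1,1,H,W) tensor."""
        x = np.asarray(pixels, dtype=np.float32) / 255.0
        x = (x - 0.5) / 0.25
        return nn.Tensor(x[None, None])

    def detect(self, pixels: np.ndarray, eval_cfg: EvalConfig | None = None
               ) -> list[Detection]:
        """Run detection on one grayscale image (eval mode, no gradients)."""
        ec = eval_cfg or self.cfg.eval
        was_training = self.training
        self.eval()
        try:
            with nn.no_grad():
                outputs = self.forward(self.prepare_image(pixels))
        finally:
            if was_training:
                self.train()
        cands: list[Detection] = []
        h_img, w_img = np.asarray(pixels).shape[:2]
        for out in outputs:
            scores = out.scores.numpy()
            boxes = out.boxes.numpy()
            for a, c in zip(*np.where(scores >= ec.score_floor)):
                x1, y1, x2, y2 = boxes[a]
                x1 = float(np.clip(x1, 0, w_img))
                x2 = float(np.clip(x2, x1, w_img))
                y1 = float(np.clip(y1, 0, h_img))
                y2 = float(np.clip(y2, y1, h_img))
                cands.append(Detection(Box(x1, y1, x2, y2), int(c),
                                       float(scores[a, c])))
        cands.sort(key=lambda d: -d.score)
        cands = cands[:4 * ec.max_detections]
        return nms(cands, ec.nms_iou)[:ec.max_detections]


def save_checkpoint(path: str | Path, model: KneeDetector,
                    extra: dict | None = None) -> None:
    """Self-describing archive: weights (npz) + config + metadata (json)."""
    path = Path(path)
    if path.suffix != ".npz":
        path = Path(str(path) + ".npz")
    state = model.state_dict()
    meta = {"config": model.cfg.to_dict(), "extra": extra or {}}
    state["__meta__"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path: str | Path) -> tuple[KneeDetector, dict]:
    path = Path(path)
    if path.suffix != ".npz" and not path.exists():
        path = Path(str(path) + ".npz")
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(bytes(data["__meta__"].tobytes()).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    cfg = RunConfig.from_dict(meta["config"])
    model = KneeDetector(cfg)
    model.load_state_dict(state)
    return model, meta["extra"]
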