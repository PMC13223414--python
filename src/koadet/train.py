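"""End-to-end training loop.

Per image (batch size 1): forward through backbone, neck, and head; TAL
assignment on the detached predictions; composite focal + box-regression
loss; AdamW step with linear warmup and stepwise decay. Normalization-layer
parameters (and biases) are exempt from weight decay. Training logs are
line-delimited JSON records of (iteration, epoch, lr, cls, reg, total).
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np

from . import nn
from .assigner import lr_schedule, tal_assign
from .config import RunConfig
from .data_io import ImageSample, augment
from .evaluation import evaluate_detector
from .head import HeadLevelOutput
from .losses import total_loss
from .model import KneeDetector, save_checkpoint

__all__ = ["flatten_outputs", "train_step", "train_detector"]


def flatten_outputs(outputs: list[HeadLevelOutput]
                    ) -> tuple[nn.Tensor, nn.Tensor, np.ndarray, np.ndarray]:
    """Concatenate per-level head outputs across the pyramid.

    Returns (scores (A, K), boxes (A, 4), anchors (A, 2), strides (A,)).
    """
    scores = nn.concat([o.scores for o in outputs], axis=0)
    boxes = nn.concat([o.boxes for o in outputs], axis=0)
    anchors = np.concatenate([o.anchors for o in outputs], axis=0)
    strides = np.concatenate([np.full(len(o.anchors), o.stride)
                              for o in outputs])
    return scores, boxes, anchors, strides


def train_step(model: KneeDetector, sample: ImageSample, opt: nn.AdamW,
               cfg: RunConfig, step_now: bool = True) -> dict:
    """One forward/assign/loss/backward(/step) cycle; returns loss scalars.

    With gradient accumulation (`cfg.train.accumulate` > 1) the caller
    defers the optimizer step by passing `step_now=False`.
    """
    outputs = model.forward(model.prepare_image(sample.pixels))
    scores, boxes, anchors, strides = flatten_outputs(outputs)
    with nn.no_grad():
        assignment = tal_assign(anchors, strides, scores.numpy(),
                                boxes.numpy(), sample.annotations, cfg.assign)
    cls, reg, total = total_loss(scores, boxes, assignment, cfg.loss)
    if cfg.loss.use_pixel_bce:
        # auxiliary pixel-wise BCE: supervise each level's spatial
        # probability map with the ground-truth joint-region mask
        from .losses import weighted_bce_t

        aux_terms = []
        for out in outputs:
            mask = np.zeros(len(out.anchors), dtype=np.float32)
            for b, _ in sample.annotations:
                inside = ((out.anchors[:, 0] > b.x_min)
                          & (out.anchors[:, 0] < b.x_max)
                          & (out.anchors[:, 1] > b.y_min)
                          & (out.anchors[:, 1] < b.y_max))
                mask[inside] = 1.0
            m_flat = nn.reshape(out.spatial_prob, (len(out.anchors),))
            aux_terms.append(weighted_bce_t(m_flat, mask))
        aux = sum(aux_terms[1:], aux_terms[0]) * (1.0 / len(aux_terms))
        total = total + aux
    if cfg.train.accumulate > 1:
        total = total * (1.0 / cfg.train.accumulate)
    total.backward()
    if step_now:
        if cfg.train.grad_clip:
            norm = np.sqrt(sum(float((p.grad ** 2).sum())
                               for p in opt.params if p.grad is not None))
            if norm > cfg.train.grad_clip:
                scale = cfg.train.grad_clip / (norm + 1e-12)
                for p in opt.params:
                    if p.grad is not None:
                        p.grad *= scale
        opt.step()
        opt.zero_grad()
    return {"cls_loss": float(cls.data), "reg_loss": float(reg.data),
            "total_loss": float(total.data), "n_pos": assignment.n_pos}


def train_detector(samples: list[ImageSample], model: KneeDetector | None = None,
                   cfg: RunConfig | None = None, out_dir: str | Path | None = None,
                   eval_samples: list[ImageSample] | None = None,
                   eval_every: int = 0, max_iters: int | None = None,
                   ) -> tuple[KneeDetector, list[dict]]:
    """Train on a list of samples; returns the model and the metric history.

    With `out_dir` set, writes `train_log.jsonl`, the serialized run config,
    and a final `checkpoint.npz` that reloads to identical eval metrics.
    """
    cfg = cfg or RunConfig()
    model = model or KneeDetector(cfg)
    tc = cfg.train
    opt = nn.AdamW(model.parameters(), lr=tc.lr, weight_decay=tc.weight_decay)
    rng = np.random.default_rng(tc.seed)
    history: list[dict] = []
    log_file = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        cfg.save(out_dir / "config.yaml")
        log_file = open(out_dir / "train_log.jsonl", "w")
    model.train()
    iteration = 0
    try:
        for epoch in range(1, tc.epochs + 1):
            order = rng.permutation(len(samples))
            for idx in order:
                sample = samples[idx]
                if tc.augment:
                    sample = augment(sample, tuple(tc.augment),
                                     seed=int(rng.integers(2 ** 31)))
                lr = lr_schedule(iteration, epoch, tc)
                opt.lr = lr
                step_now = (iteration + 1) % max(tc.accumulate, 1) == 0
                rec = train_step(model, sample, opt, cfg, step_now=step_now)
                if not np.isfinite(rec["total_loss"]):
                    raise RuntimeError(
                        f"non-finite loss at iteration {iteration}: {rec} "
                        f"(epoch {epoch}, lr {lr:.3g})")
                rec.update(iteration=iteration, epoch=epoch, lr=lr,
                           t=round(time.time(), 3))
                history.append(rec)
                if log_file:
                    log_file.write(json.dumps(rec) + "\n")
                iteration += 1
                if max_iters is not None and iteration >= max_iters:
                    raise StopIteration
            if eval_every and eval_samples and epoch % eval_every == 0:
                report = evaluate_detector(model, eval_samples, cfg.eval)
                rec = {"epoch": epoch, "iteration": iteration,
                       "mAP": {str(t): m for t, m in report.map_at.items()}}
                history.append(rec)
                if log_file:
                    log_file.write(json.dumps(rec) + "\n")
                model.train()
    except StopIteration:
        pass
    finally:
        if log_file:
            log_file.close()
    model.eval()
    if out_dir is not None:
        save_checkpoint(out_dir / "checkpoint.npz", model,
                        extra={"iterations": iteration, "seed": tc.seed})
    return model, history
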