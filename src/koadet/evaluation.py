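"""Detection metrics: precision, recall, AP/mAP, IoU-thresholded matching,
FPS, PR curves, and the per-grade confusion matrix.

A detection is a true positive iff its class equals the ground-truth class
and its IoU with a not-yet-matched ground-truth box strictly exceeds the
threshold (0.5 by default); matching is greedy in descending score. AP is
the area under the monotone (right-max interpolated) precision-recall
envelope; classes without ground truth have undefined AP and are excluded
from the mean.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .config import GRADE_NAMES, NUM_GRADES, EvalConfig
from .geometry import Box, Detection, iou

__all__ = ["MatchOutcome", "EvalReport", "match_detections",
           "precision_recall", "average_precision", "mean_average_precision",
           "fps", "confusion_matrix", "evaluate_detections",
           "evaluate_detector"]


@dataclass
class MatchOutcome:
    """Per-detection TP/FP flags (in descending-score order) and per-gt
    matched flags for one image at one IoU threshold."""

    order: np.ndarray          # indices of dets sorted by descending score
    tp_flags: np.ndarray       # bool per ordered detection
    matched_gt: np.ndarray     # int per ordered detection (-1 for FP)
    gt_matched: np.ndarray     # bool per ground truth

    @property
    def tp(self) -> int:
        return int(self.tp_flags.sum())

    @property
    def fp(self) -> int:
        return int(len(self.tp_flags) - self.tp)

    @property
    def fn(self) -> int:
        return int(len(self.gt_matched) - self.gt_matched.sum())


def match_detections(dets: list[Detection], gts: list[tuple[Box, int]],
                     iou_threshold: float = 0.5) -> MatchOutcome:
    """Greedy class-aware matching: descending score (ties by lower index),
    each detection claims the highest-IoU unmatched same-class gt if that
    IoU strictly exceeds the threshold."""
    order = np.array(sorted(range(len(dets)),
                            key=lambda i: (-dets[i].score, i)), dtype=np.int64)
    gt_matched = np.zeros(len(gts), dtype=bool)
    tp_flags = np.zeros(len(dets), dtype=bool)
    matched_gt = np.full(len(dets), -1, dtype=np.int64)
    for k, i in enumerate(order):
        d = dets[i]
        best_j, best_iou = -1, iou_threshold
        for j, (gbox, glabel) in enumerate(gts):
            if gt_matched[j] or glabel != d.label:
                continue
            ov = iou(d.box, gbox)
            if ov > best_iou:
                best_j, best_iou = j, ov
        if best_j >= 0:
            gt_matched[best_j] = True
            tp_flags[k] = True
            matched_gt[k] = best_j
    return MatchOutcome(order, tp_flags, matched_gt, gt_matched)


def precision_recall(outcome: MatchOutcome) -> tuple[float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN); 0/0 is 0 for P and 1 for R."""
    tp, fp, fn = outcome.tp, outcome.fp, outcome.fn
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 1.0
    return p, r


def average_precision(scores, tp_flags, n_gt: int,
                      mode: str = "continuous") -> float | None:
    """AP from scored TP/FP flags of one class; None when the class has no
    ground truth (excluded from the mean)."""
    if n_gt == 0:
        return None
    scores = np.asarray(scores, dtype=np.float64)
    tp_flags = np.asarray(tp_flags, dtype=bool)
    if len(scores) == 0:
        return 0.0
    order = np.lexsort((np.arange(len(scores)), -scores))
    tp = np.cumsum(tp_flags[order])
    fp = np.cumsum(~tp_flags[order])
    recall = tp / n_gt
    precision = tp / np.maximum(tp + fp, 1)
    if mode == "11point":
        return float(np.mean([precision[recall >= t].max(initial=0.0)
                              for t in np.linspace(0, 1, 11)]))
    # monotone right-max envelope, integrated over recall
    mrec = np.concatenate(([0.0], recall, [recall[-1]]))
    mpre = np.concatenate(([0.0], precision, [0.0]))
    mpre = np.maximum.accumulate(mpre[::-1])[::-1]
    idx = np.where(mrec[1:] != mrec[:-1])[0]
    return float(np.sum((mrec[idx + 1] - mrec[idx]) * mpre[idx + 1]))


def mean_average_precision(per_class_ap: dict | list) -> float:
    """Unweighted mean over classes with defined AP."""
    values = (list(per_class_ap.values()) if isinstance(per_class_ap, dict)
              else list(per_class_ap))
    defined = [v for v in values if v is not None]
    if not defined:
        raise ValueError("no class has a defined AP")
    return float(np.mean(defined))


def fps(seconds_per_image: float) -> float:
    """Frames per second = 1 / S."""
    if seconds_per_image <= 0:
        raise ValueError("detection time must be positive")
    return 1.0 / seconds_per_image


def confusion_matrix(all_dets: list[list[Detection]],
                     all_gts: list[list[tuple[Box, int]]],
                     iou_threshold: float = 0.5) -> np.ndarray:
    """Row-normalized (gts x predictions) matrix with a trailing 'missed'
    column: each gt takes the class of its highest-score detection with
    IoU >= threshold regardless of class; rows with instances sum to 1."""
    counts = np.zeros((NUM_GRADES, NUM_GRADES + 1), dtype=np.float64)
    for dets, gts in zip(all_dets, all_gts):
        for gbox, glabel in gts:
            best = None
            for d in sorted(dets, key=lambda d: -d.score):
                if iou(d.box, gbox) >= iou_threshold:
                    best = d
                    break
            if best is None:
                counts[glabel, NUM_GRADES] += 1
            else:
                counts[glabel, best.label] += 1
    sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(sums > 0, counts / sums, 0.0)
    return out


@dataclass
class EvalReport:
    per_class_ap: dict[float, dict[str, float | None]]
    map_at: dict[float, float]
    pr_curves: dict[float, dict[str, tuple[list, list]]]
    confusion: np.ndarray
    fps: float | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_class_ap": {str(t): v for t, v in self.per_class_ap.items()},
            "mAP": {str(t): v for t, v in self.map_at.items()},
            "pr_curves": {str(t): {c: [list(map(float, r)), list(map(float, p))]
                                   for c, (r, p) in d.items()}
                          for t, d in self.pr_curves.items()},
            "confusion": self.confusion.tolist(),
            "fps": self.fps,
            **self.extras,
        }


def evaluate_detections(all_dets: list[list[Detection]],
                        all_gts: list[list[tuple[Box, int]]],
                        cfg: EvalConfig | None = None) -> EvalReport:
    """Dataset-level report from per-image detections and ground truths."""
    cfg = cfg or EvalConfig()
    per_class_ap: dict[float, dict] = {}
    pr_curves: dict[float, dict] = {}
    map_at: dict[float, float] = {}
    for thr in cfg.iou_thresholds:
        outcomes = [match_detections(d, g, thr)
                    for d, g in zip(all_dets, all_gts)]
        aps, curves = {}, {}
        for c, name in enumerate(GRADE_NAMES):
            scores, flags = [], []
            n_gt = 0
            for dets, gts, out in zip(all_dets, all_gts, outcomes):
                n_gt += sum(1 for _, g in gts if g == c)
                for k, i in enumerate(out.order):
                    if dets[i].label == c:
                        scores.append(dets[i].score)
                        flags.append(bool(out.tp_flags[k]))
            aps[name] = average_precision(scores, flags, n_gt, cfg.ap_mode)
            if n_gt and scores:
                order = np.lexsort((np.arange(len(scores)),
                                    -np.asarray(scores)))
                tp = np.cumsum(np.asarray(flags)[order])
                fp = np.cumsum(~np.asarray(flags)[order])
                curves[name] = ((tp / n_gt).tolist(),
                                (tp / np.maximum(tp + fp, 1)).tolist())
            else:
                curves[name] = ([], [])
        per_class_ap[thr] = aps
        pr_curves[thr] = curves
        map_at[thr] = mean_average_precision(aps)
    confusion = confusion_matrix(all_dets, all_gts)
    return EvalReport(per_class_ap, map_at, pr_curves, confusion)


def plot_pr_curves(report: "EvalReport", path, iou_threshold: float = 0.5
                   ) -> None:
    """Render the per-grade precision-recall curves to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for name, (rec, prec) in report.pr_curves[iou_threshold].items():
        if rec:
            ap = report.per_class_ap[iou_threshold][name]
            ax.plot(rec, prec, label=f"{name} (AP {ap:.2f})")
    ax.set_xlabel("recall")
    ax.set_ylabel("precision")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1.05)
    ax.set_title(f"PR curves @ IoU {iou_threshold}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_confusion(report: "EvalReport", path) -> None:
    """Render the row-normalized grade confusion matrix to an image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(report.confusion, vmin=0, vmax=1, cmap="Blues")
    ax.set_xticks(range(NUM_GRADES + 1),
                  list(GRADE_NAMES) + ["missed"], rotation=45)
    ax.set_yticks(range(NUM_GRADES), GRADE_NAMES)
    ax.set_xlabel("predicted")
    ax.set_ylabel("actual")
    for i in range(NUM_GRADES):
        for j in range(NUM_GRADES + 1):
            v = report.confusion[i, j]
            if v > 0:
                ax.text(j, i, f"{v:.0%}", ha="center", va="center",
                        fontsize=7, color="white" if v > 0.5 else "black")
    fig.colorbar(im)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def evaluate_detector(model, samples, cfg: EvalConfig | None = None,
                      measure_fps: bool = False) -> EvalReport:
    """Run the detector over a dataset and compute the full report; FPS is
    the reciprocal of the median per-image detection time (forward + NMS)."""
    cfg = cfg or EvalConfig()
    all_dets, all_gts, times = [], [], []
    for s in samples:
        t0 = time.perf_counter()
        dets = model.detect(s.pixels, cfg)
        times.append(time.perf_counter() - t0)
        all_dets.append(dets)
        all_gts.append(list(s.annotations))
    report = evaluate_detections(all_dets, all_gts, cfg)
    if measure_fps and times:
        report.fps = fps(float(np.median(times)))
    return report
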