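"""Configuration dataclasses and YAML (de)serialization.

Two ready-made profiles are provided: :func:`default_config` mirrors the
full-scale detector (EfficientNet-B4 compound scaling, 256-channel pyramid,
162x300 radiographs) and :func:`tiny_config` is a CPU-sized profile
(width 0.25 / depth 0.4, 64x64 phantoms, 64-channel pyramid) that runs the
identical code path.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

# (expansion, channels, repeats, stride, kernel) for the seven MBConv stage
# groups of the base (B0) profile; stem and classifier head bracket them.
BASE_STAGES = (
    (1, 16, 1, 1, 3),
    (6, 24, 2, 2, 3),
    (6, 40, 2, 2, 5),
    (6, 80, 3, 2, 3),
    (6, 112, 3, 1, 5),
    (6, 192, 4, 2, 5),
    (6, 320, 1, 1, 3),
)
BASE_STEM_CHANNELS = 32
BASE_HEAD_CHANNELS = 1280

GRADE_NAMES = ("KL0", "KL1", "KL2", "KL3", "KL4")
NUM_GRADES = len(GRADE_NAMES)


@dataclass
class BackboneConfig:
    """Compound-scaled EfficientNet-style backbone."""

    width_multiplier: float = 1.4
    depth_multiplier: float = 1.8
    input_resolution: int = 380
    se_ratio: float = 0.25
    channel_divisor: int = 8
    drop_rate: float = 0.0
    pretrained_path: str | None = None   # optional external weight archive

    def __post_init__(self):
        if self.width_multiplier <= 0 or self.depth_multiplier <= 0:
            raise ValueError("scaling multipliers must be positive")


@dataclass
class NeckConfig:
    channels: int = 256
    adaptive_fusion: bool = True     # learnable softmax fusion weights
    bottom_up: bool = True           # False -> plain FPN (ablation)
    upsample: str = "nearest"        # or "bilinear"


@dataclass
class HeadConfig:
    num_classes: int = NUM_GRADES
    channels: int = 256
    num_inter_layers: int = 6
    gn_groups: int = 32
    align: bool = True               # False -> plain decoupled head (ablation)
    align_mode: str = "geometric"    # sqrt(P*M); "product" -> P*M
    prior_prob: float = 0.01         # classification bias init


@dataclass
class LossConfig:
    gamma: float = 2.0               # focal focusing parameter
    alpha: float = 0.5               # difficulty-scale sensitivity in s
    cls_weight: float = 1.0
    reg_weight: float = 1.0
    reg_loss: str = "eiou"           # or "l1" (ablation baseline)
    soft_targets: bool = True        # positives trained toward the TAL
                                     # alignment-normalized targets; the
                                     # regression is weighted by them
    use_pixel_bce: bool = False      # optional auxiliary, off by default
    eps: float = 1e-7


@dataclass
class AssignConfig:
    mode: str = "tal"                # "tal" or "center" (geometric proximity,
                                     # the pre-task-aligned baseline)
    metric_alpha: float = 1.0        # exponent a on the classification score
    metric_beta: float = 6.0         # exponent b on the IoU
    topk: int = 13
    center_radius: float = 1.5       # in strides, for mode="center"


@dataclass
class TrainConfig:
    lr: float = 2e-4
    weight_decay: float = 1e-4
    epochs: int = 50
    batch_size: int = 1
    warmup_iters: int = 500
    warmup_ratio: float = 1e-3
    decay_epochs: tuple[int, ...] = (8, 11)
    decay_factor: float = 0.1
    grad_clip: float | None = None
    accumulate: int = 1              # optimizer step every k images
    augment: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.warmup_iters < 0 or self.lr <= 0 or self.weight_decay < 0:
            raise ValueError("invalid optimization settings")
        if tuple(sorted(self.decay_epochs)) != tuple(self.decay_epochs):
            raise ValueError("decay epochs must be sorted ascending")


@dataclass
class EvalConfig:
    iou_thresholds: tuple[float, ...] = (0.5, 0.75)
    nms_iou: float = 0.6
    score_floor: float = 0.05
    max_detections: int = 100
    ap_mode: str = "continuous"      # or "11point"


@dataclass
class PhantomConfig:
    """Synthetic knee-radiograph phantom generator settings.

    Joint-gap ranges are fractions of image height, strictly ordered and
    non-overlapping across grades K0..K4 (gap narrows as severity grows);
    osteophyte bump counts grow with grade.
    """

    width: int = 162
    height: int = 300
    gap_fractions: tuple[tuple[float, float], ...] = (
        (0.30, 0.34), (0.23, 0.27), (0.16, 0.20), (0.09, 0.13), (0.02, 0.06))
    bump_counts: tuple[tuple[int, int], ...] = (
        (0, 0), (1, 2), (3, 4), (5, 6), (7, 9))
    bone_intensity: tuple[int, int] = (150, 210)
    background_intensity: int = 25
    blur_sigma: float = 1.2
    noise_sigma: float = 6.0
    box_margin_fraction: float = 0.06
    samples_per_grade: int = 12
    seed: int = 0

    def __post_init__(self):
        if len(self.gap_fractions) != NUM_GRADES or len(self.bump_counts) != NUM_GRADES:
            raise ValueError("gap_fractions/bump_counts need one range per grade")
        prev_min = float("inf")
        for lo, hi in self.gap_fractions:
            if not (0.0 <= lo <= hi):
                raise ValueError(f"invalid gap_fractions range ({lo}, {hi})")
            if hi >= prev_min:
                raise ValueError(
                    "gap_fractions ranges must be strictly decreasing across grades")
            prev_min = lo
        if max(hi for _, hi in self.gap_fractions) >= 1.0:
            raise ValueError("gap larger than image height")
        if any(lo < 0 or hi < lo for lo, hi in self.bump_counts):
            raise ValueError("invalid bump_counts")


@dataclass
class RunConfig:
    """Merged configuration for a full pipeline run."""

    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    neck: NeckConfig = field(default_factory=NeckConfig)
    head: HeadConfig = field(default_factory=HeadConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    assign: AssignConfig = field(default_factory=AssignConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kw = {}
        sections = {f.name: f for f in dataclasses.fields(cls)}
        for name, value in d.items():
            if name not in sections:
                raise ValueError(f"unknown config section: {name}")
            f = sections[name]
            if dataclasses.is_dataclass(f.type) or name in (
                    "backbone", "neck", "head", "loss", "assign",
                    "train", "eval", "phantom"):
                sub = sections[name].default_factory()  # type: ignore[misc]
                valid = {sf.name for sf in dataclasses.fields(sub)}
                unknown = set(value) - valid
                if unknown:
                    raise ValueError(
                        f"unknown fields in [{name}]: {sorted(unknown)}")
                for k, v in value.items():
                    cur = getattr(sub, k)
                    if isinstance(cur, tuple) and isinstance(v, list):
                        v = tuple(tuple(e) if isinstance(e, list) else e for e in v)
                    setattr(sub, k, v)
                sub.__post_init__() if hasattr(sub, "__post_init__") else None
                kw[name] = sub
            else:
                kw[name] = value
        return cls(**kw)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


ABLATION_MODES = ("none", "pafpn", "pafpn+tood", "full")


def apply_ablation(cfg: RunConfig, mode: str) -> RunConfig:
    """Configure one rung of the component ladder, in place.

    "none" is the plain baseline (FPN-only neck, decoupled head with
    geometric center-sampling assignment, smooth-L1 regression); "pafpn"
    adds the bottom-up aggregation path; "pafpn+tood" adds the task-aligned
    head and task-aligned learning; "full" additionally swaps the
    regression to EIoU.
    """
    if mode not in ABLATION_MODES:
        raise ValueError(f"ablation mode must be one of {ABLATION_MODES}")
    cfg.neck.bottom_up = mode != "none"
    tood = mode in ("pafpn+tood", "full")
    cfg.head.align = tood
    cfg.assign.mode = "tal" if tood else "center"
    cfg.loss.soft_targets = tood
    cfg.loss.reg_loss = "eiou" if mode == "full" else "l1"
    return cfg


def default_config() -> RunConfig:
    return RunConfig()


def tiny_config(seed: int = 0) -> RunConfig:
    """CPU-sized profile: same code path, scaled-down everything."""
    return RunConfig(
        backbone=BackboneConfig(width_multiplier=0.25, depth_multiplier=0.4,
                                input_resolution=64),
        neck=NeckConfig(channels=64),
        head=HeadConfig(channels=64),
        # from-scratch settings (no transfer learning at this scale): higher
        # base lr, short warmup, decay late in the 20-epoch schedule
        train=TrainConfig(lr=1e-3, epochs=20, warmup_iters=100,
                          decay_epochs=(16, 19), seed=seed),
        phantom=PhantomConfig(width=64, height=64, blur_sigma=0.8,
                              noise_sigma=5.0, samples_per_grade=15, seed=seed),
        seed=seed,
    )
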