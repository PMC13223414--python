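# Methods

## Problem

Knee osteoarthritis (KOA) is read on radiographs through two coupled signs:
narrowing of the joint space between femur and tibia, and marginal
osteophytes (bone spurs). The Kellgren–Lawrence (KL) scale grades severity
from K0 (normal) to K4 (severe). `koadet` frames KL grading as object
detection: one network both localizes the joint lesion region and assigns
it a KL grade, so a reading produces a box, a grade, and a confidence.

## Detector

The model is a one-stage anchor-free detector with three parts.

**Backbone.** An EfficientNet-style feature extractor with compound
scaling: nine stages (3×3 stem, seven MBConv stage groups with
squeeze-and-excitation gates and swish activations, and a classifier stage
kept for structural completeness and pretraining hooks). Channel widths
scale by a width multiplier rounded to multiples of 8 (never below 90% of
the unrounded value); repeat counts scale by a depth multiplier rounded
up. The default profile uses width 1.4 / depth 1.8 / resolution 380; the
detection pass taps the stride-8/16/32 stage-group outputs (C4, C5, C6),
whose channel counts increase monotonically. Grayscale input is replicated
to three channels at the stem so externally pretrained weights remain
loadable.

**Neck.** A path-aggregation feature pyramid (PAFPN). The three backbone
maps are projected to a uniform width by 1×1 convolutions, fused
top-down (each finer level adds the 2× nearest-neighbor upsample of the
coarser fused level), then aggregated bottom-up with 3×3 stride-2
convolutions and ReLU. Two further stride-2 convolutions extend the
pyramid to five levels P3–P7 at strides 8–128; all five outputs are
post-ReLU and share one channel width (256 default). Every two-input merge
can optionally use learnable softmax-normalized fusion weights ("adaptive
fusion"; plain addition is the toggle used by identity-style tests).
Disabling the bottom-up pass reduces the neck to a plain FPN for
ablations. When an upsampled map is one cell larger than its target (odd
sizes) it is cropped top-left — a fixed, deterministic rule.

**Head.** A task-aligned head shared across pyramid levels. Six 3×3
convolutions with 32-group group-normalization and ReLU form the
interactive extractor; all six maps are retained and feed every branch.
Each task (classification, localization) computes layer-attention weights
ω ∈ (0,1)^6 from the globally pooled stack through two fully connected
layers and a sigmoid, rescales the six maps, and predicts through a 1×1
reduction and a 3×3 output convolution. Classification passes through a
sigmoid; localization outputs four distances per location mapped through
`exp(scale_level · raw) · stride` (a per-level learnable scale), which
guarantees positivity. Two alignment maps are computed from the same
stack by pairs of 1×1 convolutions: a spatial probability map M ∈ (0,1)
that adjusts classification as P_align = √(P·M) (plain product available
by config), and an 8-channel offset map O with an independent (Δrow, Δcol)
offset per box boundary; each boundary's distance prediction is re-sampled
at its offset location by bilinear interpolation with border clamping.
Setting M ≡ 1 and O ≡ 0 (config) reduces the module to a plain decoupled
head. The classification output conv is bias-initialized to a 0.01 prior
so early training is not swamped by negatives; the offset conv weights
start near zero so alignment begins at identity.

## Training

**Assignment.** Task-aligned learning (TAL): for each ground-truth
instance, anchor points inside its box are ranked by the alignment metric
m = score^a · IoU^b (a = 1, b = 6) between current predictions and the
instance; the top k = 13 become positives, conflicts resolved toward the
higher metric. Soft classification targets are m normalized per instance
to its maximum IoU. A geometric center-sampling mode (positives within 1.5
strides of the instance center) provides the pre-task-aligned baseline
used in ablations.

**Losses.** Classification uses a focal loss: per sample
−s·(1−p_t)^γ·log p_t with γ = 2 and a difficulty scale s = (1−p)^α for
positives and p^α for negatives (α = 0.5; α = 0 disables the scale),
summed and normalized by the positive count. When TAL soft targets are
enabled (the full configuration) the positive targets are the normalized
alignment metrics with |t−p|^γ modulation, and the regression loss is
weighted by the same targets. Regression uses EIoU: the sum of
(1 − IoU), squared center distance over the squared diagonal of the
enclosing box, and squared width/height errors over the squared enclosing
width/height — penalizing edge lengths directly, where CIoU's
aspect-ratio term yields opposing ∂v/∂w and ∂v/∂h gradients (exposed as a
finite-difference diagnostic). The total objective is
1·classification + 1·regression (both weights configurable). A pixel-wise
weighted binary cross-entropy is available as an optional auxiliary and is
off by default: its role as a segmentation-style term inside a detection
objective is ambiguous, so it is not part of the composite loss. When
enabled it supervises each level's spatial probability map M against the
ground-truth joint-region mask — the most natural pixel-level target the
detector owns.

**Optimization.** AdamW with decoupled weight decay 1e-4;
normalization-layer parameters and biases are exempt. Batch size 1.
Learning rate ramps linearly from ratio 0.001 over the warmup iterations,
then decays ×0.1 after each listed epoch. The full-scale profile uses the
reference schedule (lr 2e-4, warmup 500, decay after epochs 8 and 11, 50
epochs), which presumes ImageNet-transferred weights. The tiny profile
trains from scratch, so it uses standard from-scratch settings: lr 1e-3,
warmup 100, 20 epochs, decay after epochs 16 and 19.

**Inference.** Scores below 0.05 are dropped, class-wise greedy NMS at
IoU 0.6 (ties broken by input order), at most 100 detections per image.
Both thresholds are configurable; the reference text names NMS but states
no thresholds, so these follow common detector practice.

## Evaluation

A detection is a true positive iff its class matches and its IoU with a
not-yet-matched ground truth strictly exceeds the threshold (0.5 and 0.75
reported); matching is greedy in descending score. AP integrates the
monotone right-max envelope of the PR curve over recall
(11-point sampling available by config); mAP is the unweighted mean over
classes with ground truth. Precision 0/0 is defined as 0, recall 0/0 as 1.
FPS is the reciprocal of the median per-image detection time and is
reported, never asserted. The confusion matrix attributes each ground
truth to the class of its highest-score detection at IoU ≥ 0.5 regardless
of class, with a trailing "missed" column, rows normalized.

Note that "TP at 0.75 ⊆ TP at 0.5" is not a theorem of greedy matching:
two detections contesting one instance (scores 0.9/IoU 0.6 vs 0.8/IoU
0.8) break it. It does hold in the post-NMS regime of at most one
claimant per instance, which is where the metric is used; tests assert it
there.

## Synthetic phantoms

The generator renders a two-bone knee silhouette: femur above, tibia
below, with curved articular surfaces, a mild vertical density gradient,
Gaussian blur (detector blur) and additive Gaussian noise (quantum noise).
Severity is encoded by the two KL cues. The joint-space gap is drawn
uniformly from per-grade ranges expressed as fractions of image height —
K0 0.30–0.34 down to K4 0.02–0.06, strictly non-overlapping so a trivial
gap-width threshold classifier exceeds 90% accuracy (the learnability
floor). Osteophyte bump counts grow from 0 (K0) to 7–9 (K4), placed at
the joint margins. Grade is therefore carried by two monotone cues, so
classification cannot collapse to a single linear feature. The ground
truth is one box around the joint region (bone extent plus margin and
bump radius). All randomness flows from explicit seeds; generation is
bit-reproducible.

What the phantoms do not emulate: anatomical texture (trabecular
patterns, soft tissue), subchondral sclerosis and cysts, exposure
variation, bilateral views, or annotation noise. Passing the scaled-down
training checks therefore demonstrates that the pipeline's mechanics
(assignment, losses, decoding, evaluation) work end to end on learnable
imagery — not that the model reaches clinical accuracy on real
radiographs.

## Problem sizes and numerical choices

The test suite's end-to-end checks use the tiny profile: width 0.25 /
depth 0.4 backbone, 64-channel pyramid and head, 64×64 phantoms, 60
training and 15 test images (12/3 per grade via the floor-based 8:2
split), 1200 iterations per run, three seeds per configuration. These
sizes were chosen so a full training run completes in about 90 seconds of
single-CPU numpy while remaining above the ~300-iteration floor where the
full configuration reliably separates from the baseline.

Numerics: float32 throughout; probabilities clamped to [1e-7, 1−1e-7]
rather than rejected; EIoU tensor form adds 1e-7 to denominators;
BatchNorm uses eps 1e-3 (batch-1 statistics on small maps) and GroupNorm
1e-5; distance logits are clipped to [−12, 8] before exponentiation; NMS
and matching break score ties by lower original index; degenerate
zero-area boxes are legal values with zero IoU. The VOC reader subtracts
1 from the 1-based minima; writing adds it back, so integer-coordinate
fixtures round-trip exactly (float coordinates round-trip to ~1e-9).

## Known limitations

- The network stack is a purpose-built numpy autodiff; it is correct (all
  layers are finite-difference checked) but single-threaded and far from
  GPU speeds, so the full-scale 380-resolution profile is buildable and
  runnable yet impractical to train here.
- Batch size is fixed at 1 (as in the reference schedule); gradient
  accumulation is available but no multi-image batching.
- The ImageNet-transfer path is a weight-loading hook only; no pretrained
  weights ship with the package.
- At the tiny scale, run-to-run variance across seeds is large (test sets
  of 15 images quantize per-class AP in steps of 1/3); conclusions are
  therefore taken as medians over seeds.
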