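# koadet

Graded knee-osteoarthritis (KOA) lesion detection on radiographs.

Radiologists grade KOA on the Kellgren–Lawrence (KL) scale, K0 (normal)
through K4 (severe), from two radiographic signs: narrowing of the joint
space between femur and tibia, and marginal osteophytes. `koadet` treats
grading as object detection — one network localizes the joint lesion
region and labels it with a KL grade — for researchers who want a fully
inspectable, CPU-runnable reference implementation of this detector
family, end to end.

The model is a one-stage anchor-free detector:

- **Backbone** — EfficientNet-style feature extractor with compound
  scaling (width ×1.4, depth ×1.8 in the default profile): MBConv blocks
  with squeeze-and-excitation, emitting stride-8/16/32 maps C4–C6.
- **Neck** — path-aggregation feature pyramid (PAFPN): top-down fusion
  followed by bottom-up aggregation, five 256-channel levels P3–P7.
- **Head** — task-aligned predictor: six shared 3×3 group-normalized
  convolutions, per-task layer attention ω = σ(fc₂(δ(fc₁(x̄)))), a spatial
  probability map M aligning classification (P_align = √(P·M)) and an
  8-channel offset map O aligning each box boundary by bilinear
  re-sampling. Boxes decode anchor-free from four distances
  (l, t, r, b).
- **Losses** — focal classification loss with a difficulty scale, and
  EIoU box regression
  `L = 1 − IoU + ρ²(b, b^gt)/c² + (w−w^gt)²/c_w² + (h−h^gt)²/c_h²`,
  whose edge-length penalty avoids CIoU's opposing width/height
  gradients. Training uses task-aligned assignment
  (m = score·IoU⁶, top-13) and AdamW with warmup + step decay.
- **Evaluation** — VOC-style per-class AP and mAP at IoU 0.5/0.75, PR
  curves, per-grade confusion matrix, FPS = 1/S.

Everything, including the network layers, gradients, and optimizer, runs
on a small numpy reverse-mode autodiff core (`koadet.nn`) — no deep
learning framework required.

Because the clinical X-ray dataset is external, the package ships a
seeded **synthetic phantom generator**: two-bone knee silhouettes whose
joint-space gap narrows and whose osteophyte count grows with KL grade,
plus blur and noise, with ground-truth joint boxes. Every pipeline stage
is trainable and testable on these phantoms.

## Worked example

Generate phantoms, train the tiny CPU profile, and evaluate:

```bash
koadet generate --profile tiny --seed 0 --out data/phantoms
koadet train    --profile tiny --seed 0 --data data/phantoms --out runs/full
koadet eval runs/full/checkpoint.npz --data data/phantoms
```

The eval report (seed 0, tiny profile: 64×64 phantoms, 60 train / 15
test, 1200 iterations) prints, among other fields:

```
"mAP":          {"0.5": 0.6160, "0.75": 0.5311}
"per_class_ap"  ["0.5"]: {"KL0": 0.778, "KL1": 0.600, "KL2": 0.733,
                          "KL3": 0.358, "KL4": 0.611}
```

mAP@0.5 is the mean over the five KL grades of the area under each
precision–recall curve, counting a detection correct only when its grade
matches and its IoU with the ground-truth joint box exceeds 0.5. Errors
concentrate between adjacent grades (the report's confusion matrix shows
K2 read as K3, K4 as K3/K0), which is the expected failure mode: the
grade cues are ordinal. Across seeds {0, 1, 2} the median mAP@0.5 of this
full configuration is 0.64, versus 0.36 for the plain-FPN / plain-head /
smooth-L1 baseline under identical seeds (`koadet ablate` reproduces the
whole component ladder).

Detect on a single image:

```bash
koadet detect runs/full/checkpoint.npz data/phantoms/phantom_g0_s222.png \
    --overlay overlay.png
# image_id,label,score,x_min,y_min,x_max,y_max
# phantom_g0_s222,KL1,0.4650,10.5,17.1,54.2,48.3
# phantom_g0_s222,KL0,0.3662,10.5,17.1,54.2,48.3
```

(Here a normal knee is read as K1 with K0 the runner-up — an adjacent-
grade confusion on a healthy joint.)

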