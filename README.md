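# budpose3d

Toolkit for the perception side of automated tea-bud harvesting: reading
and converting visibility-aware eight-keypoint bud annotations,
label-synchronized image augmentation, lightweight detection building
blocks, inter-frame keypoint gating, adaptive multi-frame depth fusion
with pinhole back-projection to metric 3D picking-point coordinates, and
PCK/OKS/mAP evaluation — all exercisable on a bundled synthetic RGB-D
scene simulator, so no field data is required to run or test anything.

## Who it is for

Researchers and engineers building detection-to-3D-localization pipelines
for plant-organ harvesting (tea buds here, but nothing is bud-specific in
the geometry): people who need the plumbing around a keypoint detector —
annotation formats, augmentation that keeps labels honest, robust depth
fusion, and the standard pose-estimation metrics — as a tested library
rather than scattered scripts.

## The core method

A detector proposes per-frame pixel coordinates `(u_t, v_t)` of a bud's
*picking point* (the cut location 1–2 cm below the third-leaf/main-stem
node). Across an N-frame window (N ∈ [3, 10] at a 90 fps depth stream),
three steps turn these into stable metric 3D coordinates:

1. **Consistency gate.** The displacement
   `Δ_i = √((u_i − u_{i−1})² + (v_i − v_{i−1})²)` between consecutive
   frames must satisfy `Δ_i ≤ ε` (default ε = 3 px); otherwise that
   frame's depth sample is discarded — a slipped match would sample depth
   at the wrong surface.

2. **Adaptive depth fusion.** With valid samples `{d_i > 0}` (zeros are
   sensor holes) and their population standard deviation σ:

   - σ ≤ T → `d̂ = mean{d_i}` (stable window, suppress noise),
   - σ > T → `d̂ = median{d_i}` (outliers present, stay robust),

   with T = 0.01 m by default.

3. **Pinhole deprojection.** `X = (u − cx)·d̂/fx`, `Y = (v − cy)·d̂/fy`,
   `Z = d̂`, reported in millimeters.

Localization quality is measured with `PCK@t` (fraction of points with 3D
error strictly below t, sampled every 0.5 mm) and
`OKS = exp(−d²/(2·s²·k²))` where s is the object scale in mm and k a
scale-adjusting factor; detection quality with precision, recall and
AP = ∫ P(R) dR at an IoU (or OKS) threshold of 0.5.

The package also provides forward-contract implementations (inference
only, NumPy) of the lightweight architecture pieces around the detector:
the EfficientNetV2 stage table with Fused-MBConv/MBConv blocks tapped
into a P3/P4/P5 pyramid at strides 8/16/32, a cross-scale feature fusion
block (per-branch 1×1 adjust + RepBlocks + element-wise addition), and
spatial-channel synergistic attention (multi-kernel depthwise spatial
gating plus compressed channel self-attention behind a residual path).

## Worked example

`python examples/benchmark_fusion.py` simulates 200 picking points over
10-frame windows with 5 mm Gaussian depth noise, 5% holes and 10%
background outliers (+0.5–2 m), and compares the four fusion strategies
on identical inputs:

```
  strategy    RMSE (mm)   PCK@5mm  mean OKS
    single       480.02      0.48     0.777
      mean       206.11      0.34     0.378
    median        40.88      0.78     0.934
  adaptive        40.87      0.78     0.935
```

Single-frame estimates inherit every outlier; averaging dilutes but never
rejects them; the median rejects them; the adaptive rule matches the
median under corruption while keeping the mean's noise suppression on
quiet windows. The other scripts in `examples/` walk through annotation
round-trips, label-synchronized augmentation, the backbone forward pass
and the gate→fuse→deproject chain, each printing what it computes.

A thin CLI wraps the same functions:
`budpose3d convert|split|gate|localize|simulate|bench-fusion --help`.

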