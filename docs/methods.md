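# Methods

This note documents the models, parameter choices and numerical decisions
behind `budpose3d`, and what the synthetic tests do and do not establish
about field data.

## Annotation model

A bud is one bounding box plus exactly eight keypoints, each with a
visibility flag: 0 invisible (heavily occluded, indeterminable — the
coordinates may be a (0,0) placeholder), 1 occluded but inferable, 2
clearly visible. The anatomical identity of the eight slots is
configurable through a TOML schema (`names`, `picking_point_index`,
default 7 = the picking point) rather than hard-coded, because slot
semantics are a labeling convention, not a property of the format. Pixels
are 0-based, origin top-left, `u` = column; normalization divides by
image width/height with no half-pixel offset. Labelme points are assigned
to rectangles by containment, ties and orphans resolved by nearest
rectangle center. YOLO-pose lines are written with 6-decimal fixed
formatting, so round trips are exact to 5·10⁻⁷ per normalized field. The
7:2:1 split is interpreted as train:test:val, floor-allocated with the
rounding remainder given to train — so 5,000 items split into
3500/1000/500 and 3 items yield 3/0/0.

## Augmentation

Geometric ops (rotation about the pixel center `((W−1)/2, (H−1)/2)`,
flips) move keypoints through the identical affine map as the pixels;
right-angle rotations of square images are exact array ops, arbitrary
angles use bilinear resampling. Boxes are recomputed as the axis-aligned
hull of the transformed corners, clipped to the canvas; keypoints mapped
off-canvas become invisible. Photometric ops never touch labels.
Occlusion patches blacken pixels and downgrade covered visible keypoints
to occluded (2 → 1, never upward) — a deliberate package rule that keeps
synthetic-occlusion labels consistent with the manual flag semantics.
No parameter ranges for these ops are standardized anywhere, so the
defaults are documented, config-driven, field-plausible values: rotations
±30°, fog opacity 0.2–0.6, 1–3 patches of 5–20% image width, rain as
seeded anti-aliased streaks at a common direction with ±5° jitter, fog as
constant-color alpha blending. Every stochastic op takes a mandatory
seed. Letterboxing scales by `s = min(target/W, target/H)` with symmetric
padding and returns the exact forward/inverse point maps.

## Network building blocks

The blocks are inference-only forward contracts in float32 NumPy (im2col
plus BLAS matmul); there is no training, autograd or pretrained weights,
because the contribution being engineered here is testable structure:
shape/stride arithmetic, residual and gating behavior, determinism.

- **Backbone.** The stage table is the standard EfficientNetV2 layout
  (stem conv, Fused-MBConv ×2/×4/×4 at 24/48/64 channels, MBConv with
  SE 0.25 at 128/160/256, strides 2,1,2,2,2,1,2, the classification head
  excluded). Strides apply to the first layer of each stage; residuals
  attach when stride is 1 and channels match; SE hidden width is
  `in_channels/4`. P3/P4/P5 are tapped after stages 3/5/6, the unique
  points where the cumulative stride is 8/16/32 — the table itself does
  not name tap points, so they are inferred from stride arithmetic and
  asserted. Batch normalization runs in inference form (stored
  statistics, identity at initialization); activation is SiLU throughout,
  with GroupNorm only inside the attention block where it belongs.

- **CSFF.** Each of the two adjacent-scale branches gets its own 1×1
  channel adjustment and RepBlock stack; results are added element-wise.
  The coarser input is nearest-upsampled ×2, a finer input goes through a
  stride-2 3×3 convolution; scale ratios outside {1, 2} are rejected. A
  RepBlock is the re-parameterizable 3×3 + 1×1 + identity sum followed by
  activation; N defaults to 2. Identity initialization (identity 1×1,
  zero RepBlock convolutions, linear activation as in the merged-deploy
  form) makes the block an exact pass-through, which anchors the additive
  contract in tests.

- **SCSA.** The spatial half (SMSA) splits channels into 4 equal groups,
  applies one depthwise-separable convolution per group with kernels
  3/5/7/9, concatenates, GroupNorm(4), 1×1 mix, sigmoid — a full 2D
  spatial gate multiplied onto the input. The channel half (PCSA) pools
  the gated map to 7×7 tokens, applies single-head self-attention over
  channel tokens with the query/key dimension compressed by r = 4, and a
  linear projection + sigmoid produces the channel gate. Output is
  `x + channel_gate · (spatial_gate · x)` — the residual combination is
  additive rather than gated-only. Pool size 7, r = 4, and the exact
  attention parameterization are this package's choices; sigmoid gates
  guarantee values strictly inside (0, 1).

- **Lightweighting check.** The package asserts that the assembled
  backbone+CSFF+SCSA has strictly fewer parameters than the same neck and
  attention over a conventional CSP/Darknet-style reference backbone of
  equal stage and block count with the classic channel-doubling schedule
  (64→1024). That comparison captures the direction of the design — wide
  late stages dominate CSP parameter counts, which the MBConv widths
  avoid — and is computed from layer shapes without allocating the
  reference. Parameter parity with any specific published detector is
  not claimed: neck and head widths of such models are not reproducible
  from their stage tables alone.

## Tracking and gating

Displacement is computed against the previous **raw** frame, not the last
kept frame: under the alternative reading a single slipped match would
poison every subsequent comparison, while under this one a jump costs
exactly the frames that actually moved (the return jump is also large, so
a one-frame excursion typically costs two frames — visible in the
examples). The boundary Δ = ε is kept; only exceedance discards.
Matching between frames is a pluggable interface; the built-in fallback
is greedy mutual-nearest pairing within a radius, accepted in order of
increasing distance, which is exact for the sparse, well-separated point
sets the simulator produces. A learned dense matcher can be slotted in
where its output provides the same (index, index) pairs. The additional
temporal-stability jitter filter is implemented as an optional flag of
frames whose Δ exceeds 3× the window median; it is off by default since
no quantitative definition of that filter is standard.

## Depth fusion and deprojection

σ is the **population** standard deviation of the valid set — the
deterministic choice, giving σ = 0 for a single sample instead of an
undefined value. The boundary σ = T takes the mean branch. Even-sized
medians average the two central values. Holes (d = 0) are excluded from
the valid set and from M. Depth is read at the nearest integer pixel with
no interpolation: bilinear interpolation across an object boundary blends
foreground and background depths and corrupts exactly the samples the
gate tried to protect. Units are meters internally and millimeters at
interfaces. Deprojection ignores distortion by default (consumer depth
streams are emitted undistorted); the intrinsics container carries an
optional coefficient list as a hook. The pixel back-projected is the most
recent kept frame's, i.e. the actionable current position. A mode-based
fusion variant was considered (continuous depth samples make an exact
mode degenerate) and median kept as the robust branch.

## Synthetic scenes: what they emulate and what they don't

Each bud is a three-segment stem polyline with slight random bends, grown
upward with up to 20° tilt from a base sampled inside the 0.3–2.0 m
workspace; leaf nodes sit at the joints, leaf tips branch laterally, and
the picking point lies 10–20 mm below the third-leaf node along the stem
direction. Observation noise: Gaussian pixel jitter (default 1 px) for
bud oscillation and tracking error; depth corruption as Gaussian noise
(default 5 mm), holes (5%), and additive positive outliers of +0.5–2 m
(10%) modeling background bleed-through — the failure mode median
filtering targets. Depth maps are rasterized by stamping each point's
sample in a small neighborhood with nearest-surface (z-buffer) conflict
resolution. Sequence headers record the nominal 90 fps rate; computation
does not use it.

The simulator reproduces the *geometry and error structure* of the
problem, not its appearance: there is no foliage clutter, no correlated
(wind-gust) motion, no detector — pixel tracks are ground truth plus
i.i.d. jitter, and depth errors are independent across frames. Passing
tests therefore establish the correctness and robustness ordering of the
fusion/gating machinery under the stated noise model, not field accuracy
of any detector.

## Benchmark and evaluation choices

The four-strategy benchmark (defaults: 200 picking points, 10-frame
windows, the mixed-noise model above) feeds every strategy identical
gated windows; points whose window has no valid sample are dropped from
all strategies alike so error lists stay aligned. Problem sizes were
chosen so the full suite runs in seconds on one CPU while keeping the
statistical orderings stable across seeds. PCK uses strict inequality
(d < t), so PCK@0 ≡ 0, on a 0.5 mm grid up to 10 mm by default. AP uses
the all-points monotone-envelope interpolation of ∫P(R)dR, verified
exhaustively against a brute-force oracle on all rankings of length ≤ 6.
OKS defaults: k = 0.1, s = the bud's 3D bounding-box diagonal in mm; the
keypoint-set TP criterion (mean OKS ≥ 0.5 replacing IoU in the greedy
matcher) is this package's rule, configurable, since no single canonical
definition exists.

## Known limitations

- The network blocks are forward-only; no claim is made about trained
  accuracy, and the attention/RepBlock parameterizations fix details that
  published diagrams leave open.
- The nearest-neighbour matcher is not a substitute for dense learned
  matching under large appearance change; it is the fallback interface.
- The depth simulator's independent per-frame noise understates temporally
  correlated sensor errors (e.g. persistent edge bleed at one pixel),
  which would narrow the adaptive rule's advantage over the plain mean.
- Brown–Conrady distortion handling is a hook, not an implementation.
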