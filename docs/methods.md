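# Methods

This note records the models and procedures the package implements, the
defaults it ships with, and the choices made where the design was open.

## The classifier

Lite3D maps a clip of `k = 10` ROI-only frames (3 channels, 64×64) to a
probability vector over ℓ behavior categories. The stack is

| layer | kernel (h×w×p) | output (k×c@h×w) |
|-------|----------------|-------------------|
| C1    | conv 16 @ 3×3×1 | 10×16@62×62 |
| S1    | max-pool 3×3×1  | 10×16@21×21 |
| C2    | conv 32 @ 3×3×3 | 8×32@19×19 |
| S2    | max-pool 3×3×1  | 8×32@7×7 |
| C3    | conv 64 @ 3×3×3 | 6×64@5×5 |
| S3    | max-pool 2×2×2  | 3×64@3×3 |
| C4    | conv ℓ @ 3×3×3  | 1×ℓ@1×1 |

C1's temporal extent is deliberately 1: the first layer extracts only
spatial features per frame; temporal mixing starts at C2. The head C4
produces one 1×1 map per category and is flattened directly — there are no
fully connected layers. Convolutions are valid (no padding), stride 1.

**Pooling rounding.** All printed shapes require *ceiling* division at the
pooling layers (62/3 → 21, 19/3 → 7, 5/2 → 3), i.e. a partial window at
the far border still emits an element (padded with −∞ for the max). Pool
stride equals the pool kernel (non-overlapping). With these two rules the
admissible-input intervals below are exactly the sets of sizes that
propagate to a 1×1×1 final map.

**Admissible input sizes.** Because conv shrinks an axis by `kernel − 1`
and pooling maps `d → ceil(d/p)`, the preimage of a target final size under
the stack is a closed interval computed exactly by walking the stack
backwards: a conv adds `kernel − 1` to both endpoints; a pool maps
`[lo, hi] → [(lo−1)·p + 1, hi·p]`. For the reference stack this gives
63 ≤ w = h ≤ 80 and 9 ≤ k ≤ 10; the tests additionally verify both
intervals by exhaustive forward propagation. The upper endpoints coincide
with the no-rounding (exact-division) solution. The solver accepts any
conv/pool stack, not just the reference one; it checks and propagates but
does not invert (choosing kernels to hit a given input size is in general
not analytically solvable).

**Parameter counting.** A conv layer with `n` kernels of `s×s×t` over
`c_in` channels holds `s²·t·c_in·n + n` parameters; pooling holds none.
Reference blocks: 448 / 13,856 / 55,360, head 1728ℓ + ℓ; ℓ = 7 gives
81,767 ≈ 0.08 M. The built model's enumerated arrays must (and do) agree
with the analytic count; this is asserted at build time.

**Numerics.** The network is implemented in numpy (float32) with
im2col + BLAS matmuls for convolution and numba-compiled loops for the
pooling passes; gradients are hand-derived and checked against finite
differences in the test suite. Convolution is implemented as
cross-correlation, the universal deep-learning convention; for learned
kernels this differs from true convolution only by a kernel flip. Hidden
activation is rectified-linear (the stack's design family standard;
configurable), the output is softmax. Weights initialize as fan-in-scaled
Gaussians (std √(2/fan_in)), biases zero, under a caller-supplied seed.
Max-pooling ties split the gradient equally among tied positions (a valid
subgradient; ties are measure-zero for continuous inputs).

## Loss

Focal loss with natural log, batch-mean reduction, probabilities clamped
at 1e−7 before the log. Default γ = 2, inside the recommended [0, 5) —
larger γ suppresses the gradient once predictions clear a low confidence
bar (at γ = 20 the loss is essentially flat beyond p ≈ 0.2, which stalls
learning; reproduced as a property test only). Class weights default to
the complement-frequency rule α_i = 1 − S_i/S_total computed from the
training split ("auto"); a scalar α (e.g. 1) is also accepted, and both a
focal and a plain cross-entropy mode are exposed. The complement rule
degenerates to α = 0 for a single-class problem, so training falls back to
α = 1 when C = 1.

## Tracker

Gates: IoU > α **and** Euclidean center distance < β, evaluated against a
thread's most recent box — detected or predicted (configurable in
principle; the most-recent-box rule is the default because after a miss
the predicted box is the best available location estimate). Where the
published gates leave the design open, the choices are:

* assignment is greedy — detections in descending confidence, nearest
  center among gated threads wins; only the gates themselves are part of
  the published method, so the simplest deterministic resolution is used
  (no Hungarian assignment, no appearance model);
* the linear predictor uses exactly the last two boxes (order-1 velocity),
  size copied from the last box;
* defaults α = 0.3, β = 10% of the frame diagonal, k = 10, r = k/2 = 5;
  all configurable since the gates are species-dependent.

Thread ids are never reused. After every step the working sets satisfy
P = T − U and A ∩ (U ∪ P) = ∅, asserted in tests frame by frame.

## Cut-paste-warp

Boxes are 0-based half-open pixel rectangles. The ROI is copied onto a
black canvas of the original frame size at its original position, and the
canvas is resized (bilinear, anisotropic — no letterboxing, since source
frames may be non-square) to n×n. Everything outside the mapped ROI is
zero up to a ≤ 1 px interpolation margin; the ROI centroid maps to within
1.5 px of its scaled position. Grayscale input is replicated to 3
channels. A track may emit a sequence every frame once its FIFO stack
holds k boxes (sliding emission).

## Synthetic scenes

The generator emulates fixed-camera tank footage: a dark blue-green
background with optional low-frequency texture, additive Gaussian pixel
noise (σ = 0.02 in [0,1] units), and ellipse-with-tail fish sprites with a
darker dorsal shading. Default frame size is 160×120 with body lengths of
24–40 px and speeds of 2.5–5 px/frame, chosen so a fish occupies a
realistic fraction of the frame and its motion survives the warp to 64×64
at the pixel scale — mirroring tank cameras, where animals are large in
the field of view. The five kinematic programs:

* **normal** — forward motion along the body axis with small heading
  jitter; near walls the fish banks away smoothly (rate-limited steering,
  0.10 rad/frame inside a 1.2-body-length margin) rather than reflecting,
  since an instantaneous heading flip would mimic a tumble;
* **cartwheeling** — steady in-plane rotation of the body axis
  (0.30 rad/frame, a full tumble every ~21 frames) with slow drift;
* **side_swim** — rolled body (flattened silhouette, pale belly tone),
  drifting perpendicular to the body axis;
* **grinding** — confined to the bottom 25% strip, rubbing back and forth
  with a ~7-frame period (every classification window sees both
  directions) and a roll/aspect wobble;
* **lifeless** — exact zero displacement at the bottom.

A hand-coded rule over four kinematic summaries — path length,
orientation span, body aspect, bottom occupancy with net-to-path
displacement ratio — classifies default-parameter scenes perfectly
(asserted in the tests). This guarantees the learning task is solvable:
any end-to-end failure is a model or training defect, not an artifact of
ambiguous data. The rates above were set to keep those summaries
non-overlapping between classes: a steering-limited swimmer's orientation
span stays near or below ~1 rad per 10-frame window while a tumble sweeps
~3 rad, and the grinding period is shorter than the window so its motion
never looks monotone.

Training sequences are drawn as the *last* k frames of a scene run for
k plus a random burn-in of up to 24 frames, so clips cover arbitrary
kinematic phase — the same distribution the tracker's sliding windows see
at prediction time. These contracts are asserted over generated data: lifeless tracks have
zero displacement, grinding boxes keep their bottom edge in the bottom
strip, cartwheeling orientation sweeps ≥ 2π per 40 frames. A fish may
switch programs mid-scene (used for label-latency tests). The generator is
bit-deterministic under its seed, including the detector stand-in, which
applies per-box Bernoulli dropout and Gaussian center/size jitter to the
truth boxes.

What the generator does **not** model: occlusion and crossing targets,
appearance variation between individuals, lighting changes, water turbidity,
background clutter, or detector confusion between species. Passing tests
therefore demonstrate that the pipeline's machinery is correct and that the
classifier learns genuine spatiotemporal signatures — not that it would
transfer to real footage unchanged. Species identity is a config tag, not a
kinematic one: behaviors with the same kinematics (e.g. bottom-rubbing)
share one program.

The real-data vocabulary collapses here to the five kinematically distinct
categories; real datasets with more labels (e.g. separate per-species
anomaly names) remain representable since the head size ℓ is free.

## Training and evaluation

Defaults follow the published recipe: batch 32, Adam, learning rate 1e−3,
up to 50 epochs; shuffling, initialization and the train/test split
(stratified 80/20 by sequence) all derive from one seed. The acceptance
check trains on 200 sequences per class (1000 total) for 12 epochs —
enough for the loss curve to flatten on this task — and
requires held-out macro-F1 ≥ 0.9. Overall metrics are macro-averaged over
classes; per-class precision, recall and the confusion matrix are reported
alongside. Expert-vote label cleaning is a real-data concern and is out of
scope for synthetic data; `evaluate` accepts any labeled sequence set, so
an exclusion list can be applied upstream.

End-to-end, a behavior label at frame t reflects only frames
(t−k+1, …, t) by construction of the FIFO stack, so after a kinematic
switch the label must settle within k frames. The acceptance test asserts
this with a cartwheeling→side_swim switch: both classes are cleanly
separated from every other, so the measurement isolates label latency
(the turnover bound under test) from class-boundary confusion. In
practice the label flips about half a stack after the switch, once the
new kinematics dominate the window.

## Known limitations

* The numpy/numba training loop is single-core and unbatched across
  devices; it trains the 0.08 M-parameter model in minutes but is not a
  general deep-learning runtime.
* The two free-swimming gaits remain the hardest pair: a minority of
  normal windows — mostly sustained wall-avoidance turns — are read as
  cartwheeling and vice versa, while the rolled and bottom-dwelling
  classes are recognized essentially perfectly. The published per-class
  results show the same pattern (tumbling precision below the
  bottom-dwelling classes), so this is a property of the class geometry,
  not an implementation artifact.
* The tracker has no appearance model: crossing targets of similar size
  can swap identities; the published gates do not address this either.
* `ground_truth_detector` models dropout and jitter but not false
  positives; detector hallucinations would spawn short-lived tracks that
  die after r misses.
* The synthetic scenes are deliberately simple (see above); absolute
  metric values on them do not predict real-data performance.
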