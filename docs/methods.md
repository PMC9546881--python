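# Methods

This note documents the models, numerical conventions and design choices
behind `casabench`: a simulator of 2-D grayscale semen-microscopy videos
with exact ground truth, plus the detector, tracker and metric stack used
to benchmark CASA image-processing algorithms against it.

## Coordinate and time conventions

Image coordinates have the origin at the top-left pixel, x rightward,
y downward, 0-based integer pixel indices; continuous positions are
rounded half-up when rasterized. Time advances in steps of `T = 1/fps`
(default 15 FPS) and all kinematics are evaluated at frame times. All
randomness flows from a single seed through `numpy.random.SeedSequence`
spawning (one stream per cell plus one for frame noise), so an entire
video, its ground truth and every benchmark table are bit-reproducible.

## Cell image model

A cell's image is synthesized from two point sets — the head position
(one point) and the flagellum polyline (`M = 200` points) — through three
point-spread functions on a 25×25 px support (half-width 12):

* **Head center.** The head point is convolved with an anisotropic
  Gaussian (`σ_x = 1.86`, `σ_y = 2.86` px, matching the minor/major head
  radii of the reference sample), scaled to peak at 255, complemented, and
  merged with the uniform background: `I5 = max(0, I4 − (255 − B_L))` with
  `B_L = 204`. An isolated head's darkest pixel is exactly 0.
* **Membrane halo.** The same head point convolved with the positive part
  of the Laplacian of an anisotropic Gaussian (`σ_x = 2.79`,
  `σ_y = 4.29` px), scaled to peak at 51. Clipping the Laplacian keeps
  only its positive ring, which renders as the bright "horseshoe" halo
  seen around heads in phase-contrast-like images. Note the clipped ring's
  maximum sits at radius `2σ` (the unclipped Laplacian's zero crossing is
  at `σ√2`, where the clipping starts).
* **Flagellum.** The rasterized tail polyline convolved with an isotropic
  clipped Laplacian of Gaussian (`σ_f = 1.5` px), scaled to peak at 13
  (≈5% of 255). The clipping is applied to this kernel too, so a thin
  curve renders as a single bright band rather than the double ridge the
  raw LoG would produce.

The composed frame is `clip(I5 + I6 + I8, 0, 255)` quantized to 8 bits;
convolution uses zero padding cropped to the frame, so cells fade
naturally at borders.

**Gain calibration.** The head and membrane gains are fixed constants
computed once from the single-point kernel response (`gain =
peak / max(kernel)`), never per-frame maxima, so overlapping cells
superpose additively and rendering is local. The flagellum input is a
*polyline*, whose per-point responses superpose along the curve, so a
single-point gain cannot fix the tail's rendered peak; the flagellum gain
is therefore calibrated **per isolated tail** (per connected component in
the staged API, per cell in the scene renderer). It remains a per-cell
constant — there is no frame-level normalization — so additivity and
locality are preserved while every isolated tail peaks at exactly 13.

**Variable intensity.** Each cell can carry an intensity factor in (0, 1]
that scales its deviation from the background (head deficit, membrane,
tail) before summation, emulating cells swimming deeper in the counting
chamber. Because convolution is linear, the scene renderer folds per-cell
factors and per-tail gains into the rasterized point weights and renders a
frame with a constant number of frame-sized convolutions.

## Swim models

* **Circular.** Head at
  `((r_c + a·sin(2πf_s t))·cos θ_c(t) + C_x, (... )·sin θ_c(t) + C_y)`
  with `θ_c(t) = 2πf_c t + φ0`. `f_c` is stored in cycles/s; a converter
  accepts rates printed in deg/s (50 deg/s ≡ 50/360 cycles/s). The
  flagellum is a Dresdner-style travelling wave
  `x(k) = b(k)·sin(2π(k/M − f_s t))` along the axis `y(k) = −λk/M`
  (`λ = 40` px), with amplitude profile `b(k) = a(αλk/M + β)`,
  `α = 0.02`, `β = 0.8`.
* **Linear mean.** Straight-line center plus a rotated ribbon offset (see
  README for the formulas); the correction constant
  `A_c = 1/max_θ(sin θ + A_har·sin 3θ)` pins the ribbon's vertical
  amplitude at exactly `r_h/2` (for `A_har = 0.1`, `A_c = 1/0.9`). The
  tail's travelling-wave oscillations are shaped by a transformed sigmoid
  `b1(k) = 1/(1+e^{αk/M+β})` (`α = 22, β = −2`), a decaying exponential
  `b2(k) = e^{−γ1 k/M}` (`γ1 = 5`) and the placement-correction profile
  `b3(k) = 1−e^{−γ2 k/M}` (`γ2 = 1.5`).
* **Hyperactive.** Driftless Brownian motion: per-axis increments
  `σ_b·W(T)`, `W(T) ~ N(0, T)`, independent axes; the flagellum is the
  arc-length resampling of the last `n = ⌈0.2 s/T⌉` head positions.
* **Immotile.** Head and tail frozen; the tail is a one-off snapshot of a
  hyperactive-style trailing flagellum generated *backwards in time* from
  the fixed head position.

**Tail indexing and attachment.** Tails carry exactly `M` points with the
index sampled at `M` evenly spaced values spanning [0, M], so both profile
endpoints (`b(0)` and `b(M)`) are realized. The printed travelling-wave
equations leave a small oscillatory offset between the `k = 0` tail point
and the head (up to a few px for the linear model); we re-anchor the local
curve by subtracting its root before rotation and translation, so the tail
root coincides with the head to machine precision. This is an attachment
convention only — it translates the whole tail and changes no shape.

**Tail rotation for circular swim.** The tail is rotated by the
instantaneous heading of the head path (the analytic tangent of the
circular-path equations), offset by −π/2 because the local tail axis
points along −y. Rotating by the beat phase instead would spin the tail at
the beat frequency, contradicting the requirement that the tail trail the
direction of movement.

**Scene features.** Per-frame positional jitter (independent Gaussian per
axis) shifts the rendered cell rigidly, and the *jittered* head position
is what enters the ground truth — it is what a detector can at best
recover. Mode transitions are evaluated once per second (every ⌈fps⌉
frames) from a row-stochastic 4×4 matrix; on a transition the new mode is
re-initialized at the current position and heading using the scene's
parameter templates. Cells may freely exit (and re-enter) the frame; truth
rows exist only while the head is inside.

**Noise scales.** The benchmark noise sweep (variances 0–1225) is on the
0–255 gray scale. The reference fixture's printed noise variance
8.22×10⁻⁶ is on a normalized [0, 1] intensity scale and is converted by
×255² (≈0.53 gray²) when applied.

## Detectors

All static methods operate on the complemented frame (cells are dark on a
light background, so "foreground" = head), then share the same cleaning:
morphological closing, dilation, erosion with a 2-px disk (dilation first
for the edge method), removal of components under 4 px², and centroid
extraction. Frames with near-zero gray-level variance return no
detections rather than an arbitrary global threshold. Choices the
benchmark description leaves open, and how we resolved them:

* **Adaptive (Bradley-style).** Threshold `T = μ_w + (1−s)(255−μ_w)` with
  `μ_w` the local mean over an 11-px window and sensitivity `s = 0.8`.
  The window is *cell-scale* (≈ one head diameter): a frame-scale window
  (N/16) lowers the threshold around close cell pairs and fuses them into
  one blob, destroying the method's characteristic advantage at low noise.
* **Spot enhancement.** The enhanced image is the complement plus its
  response to a zero-mean negated-LoG filter matched to the head sigmas,
  then Otsu. Thresholding the filter response alone fails structurally:
  the filtered background forms the dominant histogram mass and Otsu
  picks a degenerate split.
* **Edge.** 3×3 median filter, Sobel gradient magnitude, Otsu on the
  gradient, hole filling, then cleaning.
* **Mixture-of-Gaussians motion detector.** Per-pixel Stauffer–Grimson
  model, vectorized over the frame: 3 components, learning rate 0.005,
  background ratio 0.7, 20 training frames (empty detection lists during
  training), effective learning rate 1/t during burn-in. The component
  match gate is 4σ (squared distance 16, the convention of the widespread
  MOG2 implementations) rather than the classic 2.5σ: the tighter gate
  truncates the variance update, systematically underestimates heavy
  frame noise, and floods the mask with tail-outlier false positives —
  with it the detector's noise robustness cannot be reproduced.

## Trackers

All four algorithms share a constant-velocity Kalman filter: state
(x, y, vx, vy), white-acceleration process noise of intensity
`q = 600 px²/s³` (the scenarios' ribbon/beat/Brownian maneuvers have
accelerations of order 10²–10³ px/s²; a much smaller q over-smooths and
inflates MOTP, a much larger one stops filtering at all), measurement std
1 px, Euclidean gate 20 px, two-hit confirmation, three-miss deletion,
initial velocity std 50 px/s (the order of the swim speed). `P_D = 0.99`
and clutter density `10⁻⁶ /px²` reflect the measured behavior of the
adaptive detector on these scenes (per-frame detection rate ≈0.996 for
isolated cells, essentially zero clutter).

* **NN**: per-track greedy nearest gated detection in track-id order, each
  detection used once. **GNN**: Hungarian assignment on gated Euclidean
  costs.
* **PDAF**: per-track probabilistic weighting of all gated detections with
  the standard parametric association probabilities. **JPDAF**: exact
  enumeration of feasible joint events within connected clusters of
  tracks sharing gated detections (clusters over 8 tracks or 20 000
  events fall back to a hard per-cluster assignment).

Three engineering rules, all config-exposed, keep the probabilistic
associators comparable to production implementations instead of textbook
strawmen: (1) association likelihoods use an innovation covariance
inflated by 4 px in quadrature — the state update does not — absorbing
the CV model's mismatch with Brownian jumps and ribbon turning points
that would otherwise starve tracks of association probability;
(2) near-coincident tracks (within 2 px, and with similar velocities so
genuine crossings are spared) are merged, keeping the longer-lived one,
which prevents coalesced duplicates from starving each other; (3) new
tracks spawn from detections whose *total association probability*
across tracks is below 0.3 — spawning only from un-gated detections
would make a lost cell inside a neighbor's gate unrecoverable. A frame
counts as a miss for track management when the no-association
probability dominates (β₀ ≥ 0.5).

## Metrics

* **OSPA** (cutoff `c = 20` px, order `p = 2`): optimal assignment via the
  Hungarian algorithm on cutoff-saturated distances raised to `p`;
  `OSPA(∅, ∅) = 0`.
* **Precision/recall**: one-to-one optimal matching under a cutoff
  (default = OSPA's `c`, one consistent scale for detection evaluation);
  with no detections, precision is 1 if the truth is also empty, else 0.
* **CLEAR-MOT** (cutoff `c_T = 5` px): frame-by-frame correspondence with
  persistence (a matched pair stays matched while within `c_T`), Hungarian
  matching for the rest, identity switches counted once per change. MOTP
  is the *mean* matched distance (the raw sum is also reported);
  FP̄/M̄/MMĒ are normalized by the total ground-truth object count over
  all frames, and `MOTA = 1 − (FP̄ + M̄ + MMĒ)` holds exactly by
  construction.

## Benchmarks and problem sizes

`detection_noise_sweep` simulates the reference detection fixture
(250×250 px, 10 cells of which 3 immotile, movers split 50/50
linear/circular) as a 2-s, 30-frame video per replicate: the motion
detector needs its 20 training frames, and all five algorithms are scored
on the same 10 post-training frames so the comparison is fair. Default
20 replicates (mirroring the twenty-scenario design of the original
experiment); the packaged acceptance checks run 5.

`tracking_benchmark` simulates 500×500 px, 15 FPS, 10-s scenes with cells
assigned to the four modes with equal probability, at 20–200 cells.
Detections come from the adaptive detector on the noiseless frames — a
deliberate choice, documented here, that makes the tracker comparison
reproducible and attributes the ~1.4 px MOTP to detector centroid error
rather than synthetic measurement noise. The acceptance checks run the
20- and 200-cell conditions with 5 replicates.

## What the simulation does and does not capture

The generator produces uniform backgrounds, exactly three image structures
per cell (center, halo, tail ridge) and stationary noise. Real samples add
debris and non-sperm cells, illumination gradients, focus drift, midpiece
morphology, cell–cell collisions and 3-D motion — all out of scope here.
Benchmarks on these videos therefore measure an algorithm's behavior under
controlled geometry and noise, not its end-to-end clinical performance;
rankings transfer to real data only to the extent that the simulated
degradations (crowding, additive noise, faded cells, mode changes) are the
binding ones.

## Known limitations

* The flagellum gain is exactly calibrated per isolated tail; where two
  cells' tails overlap within a kernel support, their ridges superpose and
  may exceed 13 locally (clipped only in the final composition).
* The JPDAF's exhaustive enumeration is exponential in cluster size; the
  fallback for oversized clusters is a hard assignment, so in extremely
  dense scenes the JPDAF interpolates toward GNN behavior.
* The mixture background model assumes a static background; it never sees
  the simulator's (nonexistent) illumination drift, so its real-data
  robustness is untested here.
* MOTA can be negative when false positives overwhelm the truth count;
  this is inherent to the metric, not an error.
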