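# Methods

## The model

A fold front is an open curve in the transverse plane: x is the
medial-lateral (ML) position in µm (midline at 0), z is depth in µm,
positive inward, so deepening increases z. A curved line under in-plane
tension T experiences a net force per unit length of magnitude κT directed
toward its center of curvature (the Laplace force of a one-dimensional
interface); a straight line experiences none. Because the epithelium is thin
(~10 µm) relative to the fold's radius of curvature (~300 µm), the line law
applies to the tissue strip as a whole. Inertia is negligible at these
scales, so the Laplace force is balanced instantaneously by a normal viscous
drag −μ·v_n with an unknown dissipative prefactor μ, giving

    v_n = κ T(t) / μ.

Signed curvature is positive when the osculating center lies on the +z
(inward) side; under that convention positive tension always drives
deepening (v_n ≥ 0) wherever the front is convex toward the interior.

The model makes two strong assumptions worth keeping in mind: T is spatially
uniform along the front at any instant (tension varies in time but is taken
from a single proxy curve, or from a two-curve assignment in laterally
flattened geometries), and all dissipation is local and linear in the normal
velocity. It contains no bending stiffness and no buckling — the flat
regions of a pinned open front do not move until curvature diffuses into
them.

## Measurement operators

The operators mirror the quantification conventions of live-imaging studies
of this system, and their defaults are those conventions:

* **Curvature** at an anchor is the inverse circumradius of the circle
  through the anchor point and the two points located ``half_span`` =
  22.5 µm away *along arc length* on either side (arc length, not ML
  projection: it is the only convention that remains meaningful on steep
  fronts). The estimator is exact for any triplet sampled from a circle and
  second-order accurate (O(half_span²)) on smooth curves; a collinear
  triplet returns exactly 0. Anchors closer than the half-span to an
  endpoint are out of support and signalled with NaN.
* **Local normal** is perpendicular to the chord between the two flanking
  triplet points, oriented toward +z. This tangent definition is consistent
  with the circle fit and stable against landmark noise.
* **Normal deepening speed** between consecutive frames is the signed
  distance from the anchor to the intersection of its normal with the
  piecewise-linear next front, divided by the frame interval. Fronts between
  landmarks are always piecewise linear; with landmarks every ~20 µm the
  linear-interpolation error is subordinate to the measurement noise.
* **Temporal smoothing** is a centered 1 h 45 min boxcar (7 frames at
  15 min), truncated at the series edges; with 15-min frames the speed
  noise partially telescopes, because consecutive speed estimates share a
  front.
* **Ensemble averaging** reports mean and s.e.m. (sample sd/√n, n = animals)
  per (time, ML position), discarding entries sampled in fewer than 5
  animals or with curvature s.e.m. above 0.002 µm⁻¹.
* **Initial recoil velocity** is the least-squares slope of the post-ablation
  displacement over the 1–7 s window (0.25–1.25 s for the small circular-ROI
  protocol). A two-point difference-quotient variant exists behind a flag;
  the regression is the default because it reduces to the difference
  quotient on linear traces and is robust to frame noise. Recoil velocities
  carry tension units only up to an unknown prefactor; the collapse slope
  absorbs the units, so μ is reported in hybrid units
  (µm⁻¹·µm/s)/(µm/h).
* **Collapse and fit.** Ensemble profiles are joined with the 2 h
  sliding-window tension-proxy curve; the product error is propagated as
  σ_{κ·v} = κ̄σ_v + v̄σ_κ + σ_vσ_κ (the first-order expansion with the
  cross term retained). The fit is a line through the origin,
  slope = Σxy/Σx², unweighted by default (the collapse is fitted to the
  average values); a 1/sem² weighted variant exists. R² is reported both
  centered (1 − SS_res/Σ(y−ȳ)², which can be ≤0 for a poor fit) and
  uncentered; the centered value is the headline number. A nonpositive slope
  is a signalled model violation, not an exception, so tension-depleted
  scenarios can be explored. The fit pools all times and positions by
  default; per-time fits are a groupby away on the collapse table.

## Flow integrator

`simulate_flow` advances each node along its local normal by |κ|·T(t)/μ·dt
toward the triplet circumcenter (explicit Euler). Numerical choices:

* **Driving curvature** uses the same 22.5 µm arc-length triplet as the
  measurement operator, so measured and driving curvature agree pointwise
  wherever the curvature field is resolved at that scale; near open-front
  endpoints the span shrinks symmetrically to the available arc length. The
  triplet's flanks snap to the nearest polyline *vertices*: interpolating at
  exactly s ± 22.5 µm would place flank points on chords slightly inside a
  convex curve and bias the shrink rate upward by ~0.3 % over a long run.
* **Step control**: dt = min(dt_max, cfl·Δs_min/max|v|, cfl·Δs_min²·μ/2T).
  The third cap is the diffusive stability bound — curvature flow is locally
  a diffusion of the interface, and the advective CFL alone does not keep an
  explicit scheme stable. Defaults: dt_max = 0.05 h, cfl = 0.2.
* **Boundaries**: open fronts keep endpoints fixed (pinned tissue edges);
  closed contours are periodic.
* **Resampling**: per-step uniform resampling is available but off by
  default. Resampled nodes land on chords of the polyline, which biases a
  convex front inward by the chord sagitta at every step (~0.01 µm × 10³–10⁴
  steps is tens of µm); node spacing distorts only mildly over the runs used
  here, so the un-resampled scheme is both cheaper and more accurate.
* Accuracy on the analytic benchmark (closed circle, constant T/μ, shrunk to
  half its radius): maximum radius error ~7·10⁻⁵ relative; the front stays
  circular to the same tolerance.

Pointwise agreement between measured normal speed and κT/μ holds to ≤2 %
(with T evaluated at the mid-frame) where curvature varies slowly on the
22.5 µm triplet scale. At a flat-to-curved junction the measured κ is a
45 µm window average of a step-like field while the local displacement
follows the point value, so relative discrepancies there are O(1) at small
κ; this is a property of the windowed estimator, not an integrator error.

## Homogenisation

Under v_n ∝ κ a more curved region shrinks faster, driving curvature toward
spatial uniformity. The right geometry for this diagnostic is the *closed*
transverse body outline (`make_flattened_contour`: a ~300 µm circle with its
apical region clipped by the coverslip plane): a closed convex contour
conserves its total turning (2π) while its length shrinks, so mean curvature
rises monotonically while the CV = sd(κ)/mean(κ) falls (by ~90 % over the
default 6 h run). An *open* front with pinned endpoints instead converges to
the chord between its endpoints, so its mean curvature ultimately decays —
homogenisation there shows up in the CV, not in the mean.

## Surface detection

The apical z-map is detected per (laterally downscaled) pixel as the most
apical sufficiently prominent *peak of the z-intensity profile* (after
optional rolling-ball background subtraction and an optional per-slice
lateral variance filter that converts junctional texture into a bright
band). A running variance taken literally along z peaks on the *edges* of
an intensity band — variance is largest where a window straddles signal and
baseline — and would systematically report the apical edge rather than the
surface; the peak-of-profile definition keeps the detected height at the
band center. Choosing the most apical accepted peak (not the global
maximum) makes a deeper, brighter basal band lose against the apical
surface.

## Fiber quantification

Fibers are segmented by background subtraction (rolling-ball, implemented as
grayscale morphological opening with a ball element), fixed-threshold
binarisation (the threshold is an operator input; no default is presented as
correct), skeletonisation, and removal of skeleton branch points so that
crossing fibers split into linear portions. Length is the euclidean distance
between path endpoints; orientation comes from those endpoints, folded into
[0°, 90°] by θ_f = min(θ mod 180, 180 − θ mod 180); fibers ≤0.8 µm are
discarded; ROI averages weight orientation by length, with fibers assigned
to ROIs by midpoint. Skeleton endpoints retreat by roughly the bar
half-width per end, so endpoint lengths underestimate the drawn bar length
by a few pixels; orientation recovery on 8 µm bars at 0.161 µm pixels is
accurate to ~1°.

## Synthetic studies

The generator produces every input the pipeline consumes, under a known
ground truth. The reference study: 10 animals; a 300 µm arc of total arc
length 600 µm flattened medially over ±100 µm (the coverslip contact used to
achieve high-resolution imaging); tension ramping linearly 0.2 → 0.6
(recoil-proxy units, µm/s) over 18 → 24 hAPF, matching the observed rise of
recoil velocities during folding; frames every 15 min; observed fronts
resampled to landmarks every ~20 µm (the manual segmentation protocol) with
i.i.d. Gaussian displacement of sd 0.5 µm in both coordinates; recoil
proxies per animal and frame time with 5 % multiplicative log-normal noise
(log-normal keeps the proxy nonnegative). Per-animal seeds are
master_seed + index, so any subset of animals is reproducible regardless of
ensemble size.

μ defaults to 5·10⁻⁴. The choice trades off two desiderata that pull in
opposite directions: a larger cumulative flow ∫T/μ dt gives faster,
more life-like deepening but erases the initial curvature heterogeneity —
the very signal the collapse fit rests on — within the 6 h window, while a
smaller one preserves the heterogeneity at the cost of slower fronts. At
μ = 5·10⁻⁴ deepening speeds span ~0.5–2.5 µm/h (inside the range observed
in vivo, below the late-stage peak) and the reference study recovers μ
within 1 % with a collapse R² of 0.91–0.94 across seeds.

What the generator does *not* emulate: inter-animal variability of μ or
T(t) (no published characterisation exists; both are exposed as explicit
dispersion hooks rather than guessed), front overhangs, segmentation
outliers or drift, spatially varying tension, and realistic ablation
sampling — every synthetic animal contributes a proxy value at every frame
time, whereas a real study ablates each animal once and pools across many.
Passing tests on synthetic data therefore demonstrate the correctness of
the operators and the identifiability of μ under the stated noise model,
not robustness to every artefact of real microscopy.

## Degenerate inputs and conventions

* Boundary p-values: p = 0.05 and p = 0.01 both band as *weak* (strict
  inequality for the strong band). Zero-variance Welch comparisons: equal
  means → p = 1, different means → p = 0. ANOVA with all values equal →
  (F, p) = (0, 1). No multiple-testing correction by default;
  Benjamini-Hochberg is opt-in.
* Missing-value signalling: out-of-support anchors, normals that miss the
  next front, and empty ROIs return NaN (callers drop the position); hard
  misconfigurations raise typed exceptions (CLI exit code 2 for
  configuration, 3 for data).
* Sample statistics use ddof = 1 throughout; s.e.m. = sd/√n with n = animals
  contributing at that (time, position).
* The convergence-center depth used for material tracking has no published
  value and is a required input, never a default.
* The 22.5 µm half-span is treated as physical µm (pre-registration), and
  registration maps ML to % with independent left/right scales because the
  three landmarks do not assert symmetry.

## Known limitations

* The open-strip boundary condition (pinned endpoints) is an idealisation of
  the fold's mechanical coupling to head and thorax; real front ends are
  advected by neighbouring tissue flows, which are out of scope here.
* The collapse fit treats tension as position-independent within a dataset
  (or two-valued via the curvature-threshold rule); spatial tension
  gradients would be absorbed into scatter.
* Basal fronts are handled identically to apical ones apart from the side
  label; no basal-specific corrections are applied.
* The explicit integrator is first-order in time; defaults keep its error
  1–2 orders below the measurement tolerances, at the cost of small steps
  when tension is high or nodes are dense.
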