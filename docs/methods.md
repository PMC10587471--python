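# Methods

## The trajectory model

A fiber is modeled as a step-wise random walk with a constant step length
h (µm).  Conditional on the direction d of the previous step, the next
step's direction is drawn from the von Mises–Fisher (vMF) distribution on
the unit sphere with mean direction d and concentration parameter κ > 0;
the model has no time dimension.  κ acts as a stiffness: the expected
cosine of the turn per step is A(κ) = coth κ − 1/κ, so the directional
persistence length is approximately h / (1 − A(κ)).

Sampling uses the two-stage construction: a planar unit vector v uniform on
the circle, a polar component w on [−1, 1] with density ∝ e^{κw}, the
sample u₀ = (v √(1 − w²), w) about the pole μ₀ = (0, 0, 1), and a rotation
to the target mean direction by the closed-form matrix M whose third column
is μ.  w is drawn by exact inverse-CDF, w = 1 + ln(ξ + (1 − ξ)e^{−2κ})/κ
with ξ uniform on (0, 1), which is constant-time and exact at any κ (a
rejection sampler would give the same law).  M is singular at the antipode
μ = −μ₀; for μ₃ ≤ −1 + 10⁻⁶ the exact rotation diag(1, −1, −1) is
substituted.  A physical trajectory cannot step straight back onto the
previous point, so this case only arises from rounding.

Every stochastic routine takes an explicit integer seed (or an explicit
`numpy` generator internally); there is no global random state.

## κ estimation and its pitfalls

Standardization rotates each step's frame so the previous step lies on the
pole and records the next step's direction; n points yield n − 2 unit
vectors, and the mean resultant length L of that sample drives all three
estimators (moment formula L(3 − L²)/(1 − L²); the stiff-fiber shortcut
1/(1 − L), valid for L ≥ 0.9 i.e. κ > 10; and the exact moment estimator
solving A(κ) = L by bracketed root-finding, tolerance 10⁻⁹).  L = 1 (a
perfectly rigid fiber) and L = 0 are rejected as degenerate rather than
mapped to ±∞/0.

Two caveats worth stating explicitly:

- The azimuthal part of the standardized frame is a convention.  Under a
  global rotation of the trace, the polar angles of the standardized
  directions are exactly invariant but their azimuths rotate by a
  step-dependent amount, so the *sample* L (and hence κ̂) moves at the
  sampling-noise level.  This is inherent to any per-step closed-form
  frame choice and does not bias the estimate.
- κ̂ is only meaningful together with its sampling step.  Oversampling a
  trajectory (subdividing steps) manufactures collinear sub-steps and
  inflates κ̂ roughly in proportion to the subdivision factor;
  undersampling deflates it.  The `calibrate` module quantifies this and
  locates the natural step as the elbow of κ̂ versus step multiplier,
  computed as the maximal discrete second difference on log–log axes (both
  axes span an order of magnitude, and the raw second-difference profile is
  returned so a plateau can be read as a *region* rather than a point).
  An elbow is reported only when the maximal second difference exceeds 10%
  of the curve's log-range.

## The tracer

The tracer follows the flashlight scheme: auto-contrast the stack globally
to [0, 1] (per-section stretching would distort the cross-section
brightness comparison the selection rule depends on), Gaussian-blur each
section with a one-pixel radius, find the second point as the brightness
argmax on the circle of radius R around the seed, then iterate arc scans.
Arcs are sampled at 2n + 1 continuous positions with bilinear
interpolation (nearest-pixel reads at 60 nm/pixel would alias), spanning
[−α, α] about the current direction, where the direction is the XY vector
between the two most recent points (carried over unchanged on a pure-z
move).  Contiguous runs above B_min form peaks; a peak is rejected when its
maximum exceeds B_max (saturation/blob guard) or its arc-length width at
B_min falls outside [W_min, W_max] — the lower bound kills single-pixel
noise, the upper bound blobs and varicosity-scale structures.  Within a
section the surviving peak closest to the expected direction wins; across
the 2N + 1 scanned sections the brightest wins; ties go to the smaller
|section offset|, then the smaller |angle|.  On failure the radius walks
0.5R, 1R, 1.5R, … up to i_max extensions while the angle narrows as
α₀e^{−k(i−2)}, capped at α₀ (the printed formula would *widen* the arc at
the sub-radius extension, which contradicts the narrowing rationale and in
practice admits backward turns).  Both radius and angle revert after a
successful extended step.  Termination: no surviving peak after all
extensions (`no_peaks`), the same situation within reach of a stack border
(`stack_edge`), a step budget (`max_steps`), or a caller-driven stop
(`manual_stop`).

Defaults (R = 0.75 µm, α₀ = π/2, n = 50, k = 0.05, i_max = 4,
B_min = 0.25, B_max = 1.0, W_min = 0.1 µm, W_max = 3 µm,
N = ⌈R/z-step⌉) sit inside the typical working ranges for high-resolution
confocal stacks of thin axons; the arc increment R α₀/n ≈ 24 nm stays well
below half of any fiber width the peak filter is asked to keep, and a
warning is emitted when a parameter combination violates that rule.

Additions beyond the original scheme, each exposed as a `TracerParams`
option:

- **Self-overlap guard** (`self_avoid`, default 0.75 R): candidates closer
  than this to any trace point at least four steps back are rejected.
  This operationalizes the physical assumption that a fiber cannot fold
  back 180° onto itself.  Without it two failure loops exist: the 0.5R
  extension arc lies *inside* the bright tube at a signal end and orbits
  it forever, and a trace that reverses at an apparent hairpin slides back
  down its own tube offset by one section.
- **Sub-pixel refinement** (`xy_refine`, `z_refine`, `z_profile_sigma`):
  each accepted point is re-centered radially by a log-parabola peak fit
  along the motion direction (active only where that profile is actually
  peaked, i.e. on steeply inclined fibers whose in-section blob the arc
  clips off-center), laterally by a 1D brightness centroid along the
  in-section normal, and axially either by a three-section log-parabola
  or, when a calibrated axial profile width σ_z is supplied (bead-style
  PSF calibration combined with the fiber radius), by the uniform
  two-section log-ratio z* = midpoint + (σ_z²/Δz) ln(I_up/I_down).
  Refinements are deliberately *corner-preserving*: a 2D or iterated
  centroid slides points along the fiber, measurably straightens the
  recovered trajectory, and inflates κ̂ by tens of percent.
- **Spherical arcs** (`spherical_arcs`, default off = planar arcs with the
  same radius in every section): the arc radius in a section offset by dz
  becomes √(R² − dz²), and after z-refinement the point is slid radially
  so the 3D step is exactly R.  This removes the step-length jitter that
  planar arcs produce (3D steps of √(R² + dz²)) and with it the need to
  re-mark the trace before estimating κ.
- **Hooks**: `step_hook` may veto/replace each automatic point
  (programmatic proofreading), `failure_hook` may supply a manual bridge
  point when detection fails; the `overrides` list is the non-interactive
  form of the latter.  All inserted points are flagged `manual` in the log.

## Synthetic stacks and what they do and do not show

The renderer paints each fiber as a Gaussian tube (half of peak intensity
at one fiber radius) composited by maximum, applies an anisotropic Gaussian
PSF, adds a constant background and per-voxel Gaussian noise clamped to
[0, 1], and can interrupt the signal with Poisson-process gaps of
exponential length (plus caller-specified gap intervals for controlled
tests).  Stacks are written as 16-bit single-channel TIFF series with a
YAML calibration sidecar, the same format the reader accepts for real
exported confocal data.

This emulates the image statistics the tracer relies on — tubular bright
paths, anisotropic calibration (~0.06 µm/pixel XY, ~0.3 µm/section),
noise, gaps — but not real optics (Airy rings, depth-dependent
aberrations), photon (Poisson) noise, labeling heterogeneity along a
fiber, or true tissue clutter.  Passing the synthetic protocol therefore
demonstrates the algorithmic chain is correct and self-consistent; it does
not by itself certify performance on tissue.

## The accuracy-assessment protocol

`tracing_accuracy_protocol` re-enacts the point-by-point validation on
synthetic data: vMF fibers (default κ = 15, 300 steps of 0.75 µm) are
grown in a 185 × 185 × 21 µm volume until ten have an in-volume initial
segment of ≥ 150 points (shorter segments leave κ̂ dominated by its own
sampling error, which scales as √(2/n)); all in-volume runs are rendered
into one noisy stack; each fiber is traced from its segment start with
R equal to the generation step; every automatic point farther than 1 µm
from the fiber's true path (an identity error, e.g. a jump onto a crossing
fiber) is counted and replaced by a point on the true path, and a dead
stop away from the segment end is bridged manually — the programmatic
analog of the human proofreader, who fixes wrong decisions but does not
re-center points that are visibly on the fiber.  Scoring reports the
fraction of final trace points within 0.5 µm of the truth and the error of
the per-fiber κ̂.

Two protocol decisions deserve emphasis:

- **Applicability domain.**  Fibers are started mid-depth with in-plane
  initial directions, and a segment is only accepted if no single step
  turns by more than α₀ in XY projection: an arc subtending [−α₀, α₀]
  structurally cannot follow a sharper turn, and such events are handled
  on real data by manual branch decisions.  Within a 21 µm slab a κ = 15
  walk still wanders steeply in z, so this is a genuine, mechanism-derived
  restriction rather than a cosmetic one.
- **Estimation from raw tracer steps.**  The synthetic ground truth is a
  polyline whose curvature is concentrated entirely at vertices one step
  apart.  Any constant-chord resampling whose phase is not locked to those
  vertices splits turns across neighboring steps and inflates κ̂ by up to
  ~1.5× (a commensurate resampling — e.g. nudging at half the step and
  then at the step — is exact; an incommensurate one at 0.47× the step
  inflates by ~60%).  The tracer's own steps are one such sampling;
  re-marking them at a constant step afterwards adds a second,
  incommensurate resampling and compounds the aliasing.  The protocol
  therefore estimates κ from the tracer's steps directly (they are already
  constant with spherical arcs) and reports the estimate at their median
  length.  On real fibers, whose curvature is continuous, this vertex
  aliasing does not exist and nudging before estimation remains the
  recommended practice — which is why `nudge` stays the default workflow
  everywhere outside this protocol.

With these choices the protocol (seeds 0 and 7) traces ≥ 96.7% of points
to within 0.5 µm and recovers per-fiber κ within ±28% of the generating
value; the residual spread is dominated by per-fiber sampling error and
the conditioning implied by segment selection.

## Numerical choices and problem sizes

- A(κ) uses the series κ/3 − κ³/45 below κ = 10⁻⁴ to avoid catastrophic
  cancellation in coth κ − 1/κ; the exact estimator brackets the root in
  [10⁻⁹, max(10⁴, 10/(1 − L))].
- Nudging solves the sphere–segment quadratic exactly and takes the first
  forward crossing; output points lie on the source polyline to 10⁻⁹ and
  the trailing remainder shorter than one step is dropped.  A polyline
  that folds back entirely inside the first sphere has no valid nudge and
  raises.
- Volume clipping retains points inside the closed box without
  intersecting segments with the faces; retained plus discarded point
  counts always equal the walk's total.
- Fiber radii are drawn from Normal(0.20, 0.15) µm and redrawn below
  0.02 µm (a physical fiber cannot have non-positive radius; ~9% of the
  parent mass is negative).
- Default problem sizes keep the full suite to a few minutes on one CPU:
  calibration curves use twenty 1,000-step fibers; the accuracy protocol
  renders ten fibers into one full-size (3085 × 3085 × 71 voxel) stack.

## Known limitations

- Unbranched fibers only; branch points must be resolved by manual
  overrides, and no color (multi-fluorophore) information is used.
- The tracer assumes locally in-plane fibers; near-vertical stretches and
  XY-hairpins defeat the 2D arc search by construction.
- κ point estimates only: no confidence intervals or formal directional
  hypothesis tests (external directional-statistics toolboxes cover
  these), and no estimators for dimensions other than 3.
- The renderer's noise model is additive Gaussian; photon-limited regimes
  are not emulated.
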