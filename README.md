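# flashtrace

Single-fiber tracing in confocal z-stacks and von Mises–Fisher trajectory
analysis.

Serotonergic axons are long, thin (~1 µm), unfasciculated fibers whose 3D
trajectories look like realizations of a stochastic process.  Quantifying
that process requires (i) converting a noisy confocal z-stack into an
ordered array of XYZ coordinates for one fiber at a time, and (ii) reducing
the resulting trajectory to an interpretable stiffness parameter.
`flashtrace` implements the complete computational chain for researchers
working on axon morphology:

- **Trajectory model.**  A fiber is a step-wise random walk with constant
  step length; each step's direction follows the von Mises–Fisher (vMF)
  distribution on the sphere with mean direction equal to the previous step
  and concentration parameter κ > 0.  Low κ gives a flexible, tortuous
  fiber, high κ a rigid one.  Sampling uses Wood's construction (sample
  about the pole μ₀ = (0, 0, 1), then rotate by the closed-form matrix M
  with M μ₀ = μ).
- **Estimation.**  A trajectory is standardized by iteratively rotating each
  current step to μ₀ and recording the next step's direction; the mean
  resultant length L of that spherical sample yields κ via
  L(3 − L²)/(1 − L²) (default), 1/(1 − L) (valid for L ≥ 0.9, i.e. κ > 10),
  or the exact moment estimator solving A(κ) = coth κ − 1/κ = L.  Estimates
  are always reported together with their sampling step, e.g. κ(1.5 µm) = 20.
- **Step calibration.**  κ estimates depend on the sampling step:
  oversampling grossly inflates them, undersampling deflates them.  The
  κ-vs-step-multiplier curve has an elbow ("inflection") at the fiber's
  natural step, located here by the discrete second difference on log–log
  axes.
- **The "flashlight" tracer.**  From a seed point, the tracer repeatedly
  scans pixel intensities on an arc of radius R spanning [−α, α] about the
  expected direction, in the current optical section and N sections on each
  side; peaks are filtered by brightness ([B_min, B_max]) and width
  ([W_min, W_max]); within a section the peak closest to the expected
  direction wins, across sections the brightest.  When no peak is found the
  radius is extended through multiples of 0.5 R with an exponentially
  narrowing angle (αᵢ = α₀ e^(−k(i−2))), which bridges transient signal
  gaps.  Traces can be re-marked at an exact constant 3D step ("nudging")
  for unbiased κ estimation.
- **Synthetic microscopy.**  A renderer turns simulated fibers into
  anisotropic grayscale TIFF stacks (bright Gaussian tubes, PSF blur,
  additive noise, signal gaps) so every tracer feature can be validated
  against exact ground truth, including a full re-enactment of the
  point-by-point accuracy assessment protocol.

## Worked example

```bash
# simulate a 300-step fiber with kappa = 20 and 1.5 um steps
flashtrace simulate --kappa 20 --steps 300 --step-len 1.5 --seed 7 --out fiber.csv
# -> 301 points, path length 450 um -> fiber.csv

# estimate the concentration parameter at the native step
flashtrace estimate --trace fiber.csv --step 1.5
```

which prints (for this seed):

```json
{
  "kappa": 20.441918450532057,
  "method": "approx3d",
  "step_len_um": 1.5,
  "n_directions": 299,
  "L": 0.9500118073382808
}
```

The estimate (κ ≈ 20.4 from 299 step directions with mean resultant length
L ≈ 0.950) recovers the generating κ = 20 within the sampling error expected
of a 300-step fiber, and is explicitly tagged with the 1.5 µm step it was
computed at.  The same operations are available from Python:

```python
from flashtrace import WalkConfig, simulate_fiber, standardize_steps, estimate_kappa

trace = simulate_fiber(WalkConfig(kappa=20, n_steps=300, step_len=1.5, seed=7))
est = estimate_kappa(standardize_steps(trace), "approx3d", step_len=1.5)
```

Other subcommands: `volume` (multi-fiber clipped volumes), `render`
(synthetic TIFF stacks from ground-truth traces), `trace` (run the
flashlight tracer on a stack), `nudge`, `tortuosity`, and `calibrate`
(κ-vs-step curves and the inflection search).  Every run writes a JSON
manifest with the parameters, seed and versions needed to re-execute it.

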