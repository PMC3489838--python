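# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the design decisions behind `trunkrelax`, in the package's own
terms. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The measurement the pipeline emulates

A participant stands with pelvis and legs restrained while the legs are
rotated forward at ~3 deg/s, flexing the lumbar spine to a target angle
specified as a fraction (30–100 %) of the individual flexion-relaxation (FR)
angle — the near-end-range angle at which extensor muscle activity shuts
off. The target angle is held for 16 minutes while a harness load cell
records the restraint force at 1000 Hz; lumbar angle is recorded at 100 Hz
by inertial sensors. Trunk moment is force times the harness moment arm.
The exposure has three phases — loading ramp, constant-angle hold
(load-relaxation), unloading ramp — and the analysis extracts:

* **Initial moment / moment drop** — means over 3-s windows at the start
  and end of the hold, and their difference; also `t90`, the time from hold
  onset to 90 % of the total drop.
* **Neutral zone (NZ)** — the low-resistance region around upright posture
  on the angle–moment curve, normalized by the FR angle, compared pre
  (loading curve) vs post (unloading curve).
* **Energies** — areas `E1` (loading) and `E2` (unloading) under the
  angle–moment curves, dissipated energy `dE = E1 − E2`, and the
  viscoelastic state `RE = dE/E1 ∈ [0, 1]`.
* **Model parameters** — least-squares fits of four constant-angle
  relaxation models, compared by R² and RMSE.
* **Sensitivity coefficients** — dimensionless sensitivities of initial
  moment and moment drop to each model parameter.

## Relaxation models

Two Kelvin-solid (exponential) forms — the standard linear solid
`M(t) = θ₀(K₂ + K₁ e^{−t/T})` and the Prony series
`M(t) = θ₀(K_∞ + Σ Kᵢ e^{−t/τᵢ})` — and two power-law forms — the
Schapery-type `M(t) = θ₀(K_eq + C₁ t^{−C₂})` and modified-superposition
`M(t) = θ₀ K₀ t^{−β}`. The power-law equations are the standard forms from
the nonlinear-viscoelasticity literature; the primary sources for this
analysis print them only as unreadable equation images, so the adopted
forms are declared here explicitly and all downstream quantities are
defined against them. All angle units are degrees (stiffness Nm/deg),
matching how such parameters are conventionally reported for the trunk; no
radian conversion occurs anywhere.

Power-law forms diverge at t = 0 and are evaluated and fit only for
t ≥ 1 s after hold onset; 1 s is configurable (`POWER_LAW_T_MIN`,
`FitOptions.power_t_min`). The SLS stores the damping coefficient `C` as
its primary viscous parameter with `T = C/K₁` derived, so that sensitivity
analysis can sweep the damper itself.

## Synthetic trials and the hereditary-integral oracle

Ground truth is a generalized-Maxwell material driven by an *effective
deformation*: below the neutral-zone width (default 10 deg) the
deformation–angle slope is only 2 % of nominal, above it 1. Its moment
under an arbitrary angle history is the hereditary integral
`M(t) = K_∞ q(t) + Σᵢ Kᵢ ∫ e^{−(t−s)/τᵢ} q̇(s) ds`, discretized per branch
by the exponential–trapezoidal recursion
`hᵢ[n] = a hᵢ[n−1] + b Δq[n]`, `a = e^{−Δt/τᵢ}`,
`b = Kᵢτᵢ(1−a)/Δt`, which is *exact* for piecewise-linear histories and
unconditionally stable; it is executed as a first-order IIR filter. An
initial step to the first sample's angle is injected as `hᵢ[0] = Kᵢ q[0]`.
Negative total moments are clamped to zero: the harness only pushes.
Because trapezoidal profiles are piecewise linear, the oracle agrees with
the constant-angle closed forms to machine precision under a step history
and is insensitive to grid refinement — both properties are tested.

Generator defaults are the study conditions the analysis assumes:

| parameter | default | rationale |
| --- | --- | --- |
| ramp rate | 3 deg/s | protocol loading/unloading speed |
| hold duration | 960 s | 16-min exposure (tests shorten it) |
| exposure levels | 30/40/60/80/100 % FR | protocol levels |
| FR angle | normal(58.2, 12.0) deg, truncated > 0 | cohort mean (SD); only moments are reported, so a truncated normal is the minimal assumption |
| moment arm | 0.40 m | plausible T8-harness to L5/S1 distance |
| ground truth | Prony n=2: K_∞ 0.34, 0.23 Nm/deg @ 8.8 s, 0.36 Nm/deg @ 1704.5 s | cohort-mean fitted parameters at 100 % FR; gives the observed fast (first 30–60 s) and slow relaxation phases |
| stiffness–angle gain | e^{0.02·θ₀} | reproduces the exponential growth of initial moment with angle |
| NZ width / inner slope | 10 deg / 2 % | pre-exposure NZ ≈ 10 deg |
| force noise | 0.5 N | RMS noise of a strain-gauge load cell of the class used; not stated in the source protocol, so config-exposed |
| angle noise | 0.1 deg | IMU-class orientation noise |

What the generator does **not** emulate: voluntary muscle activity and its
slow decline, postural drift, creep-dependent FR changes between sessions,
inter-trial correlation within a subject beyond the shared FR angle, and
any thoracic/pelvic contribution to the measured angle. Passing tests
therefore demonstrate correctness of the *analysis* under the stated
material model and noise structure, not robustness to every artifact of in
vivo recording.

## Preprocessing choices

* Force is block-averaged onto the angle grid (10-sample means for
  1000→100 Hz), attenuating load-cell noise by √10; only the overlapping
  time span is kept.
* Phase boundaries come from the angle rate after a 1-s moving-average
  smooth (window ≪ ramp duration, so breakpoints move < 0.5 s), with a
  ±0.5 deg/s threshold — one sixth of the ramp rate, well above plateau
  noise. Records without a detectable plateau raise `UnusableTrialError`
  and are skipped (and counted) by the pipeline, as are holds shorter than
  two 3-s windows and holds whose target angle lies inside the neutral
  zone — the synthetic counterparts of discarded in vivo trials.
* Window means use all samples in the half-open interval `[t₀, t₀ + 3 s)`
  (final window closed at the end); means, not medians.
* `t90` is defined on the *total* drop (initial − final window mean), not
  on absolute moment, and is flagged unresolved when the drop is
  non-positive.

## Hysteresis, NZ and energies

Loading and unloading curves are re-binned onto a 0.25-deg angle grid by
within-bin averaging (≥ 5 bins required). The NZ walk starts at upright;
local slope is a linear regression over the trailing 1-deg window, and a
point fails when slope ≥ 0.1 Nm/deg or moment ≥ 7 Nm. The zone ends at the
first violation sustained for 2 consecutive bins, so one noisy bin cannot
collapse it; true breakpoints fail persistently and are recovered within
one bin. Pre-exposure NZ is measured on the loading curve and post-exposure
NZ on the unloading curve of the same trial (both exposed separately).
The reported NZ is the flexion-side extent.

Energies integrate the zero-floored moment over angle (trapezoid). Flooring
makes `E2` count only recovered work, so `RE` attains exactly 1 for a pure
damper whose unloading moment is clamped by the one-sided harness contact,
and exactly 0 for identical loading/unloading curves.

## Fitting

Bounded nonlinear least squares (trust-region reflective), 8 seeded starts
with log-uniform initial time constants on [1 s, hold duration]; bounds:
stiffness (0, 100] Nm/deg, τ ∈ [0.1 s, 10 × hold]. Best start by SSE, ties
by smaller parameter norm. Prony branches are sorted by ascending τ after
fitting (branch labels are exchangeable), and one Prony start is seeded
from an SLS solution with a vanishing second branch, so the nested model
never fits meaningfully worse. Schapery's `K_eq` is fit freely by default;
the variant that pins it to the final-window stiffness
(`FitOptions(fix_k_eq=True)`) is available, but pinning biases `K_eq`
upward by `C₁ t_end^{−C₂}` and was therefore not made the default — the
free fit recovers noiseless synthetic parameters to machine precision,
which the pinned variant cannot. The pipeline fits on the hold segment
block-mean-decimated to 1 Hz (configurable): the relaxation signal is slow,
decimation averages noise down, and fits stay cheap. R² uses the fitted
samples (t ≥ 1 s for power models); a zero-variance segment yields R² = NaN
with a flag.

## Sensitivity and trends

`SC = (ΔR/R̄)/(Δp/p̄)` with nominal values taken as means across trials and
ranges as min–max across trials (the alternative normalization
`(ΔR/Δp)(p̄/R̄)` is the same expression rearranged, so only one is
implemented). Outcomes are point evaluations of the closed forms — initial
moment `M(t_start)` and moment drop `M(t_start) − M(horizon)`, with
`t_start` 0 for Kelvin solids and 1 s for power laws — rather than 3-s
window means: point evaluation makes the initial moment of a Kelvin solid
*exactly* independent of its time constants and the moment drop exactly
independent of the parallel stiffness, which are the analytic signatures
the sensitivity table is checked against. (Window-averaged outcomes would
blur those exact zeros into small nonzero values.) Coefficients are
reported as absolute values.

Angle trends fit cohort-mean outcomes against exposure level (%FR) with
linear, exponential `a·e^{bx}`, and exponential-through-origin
`a·(e^{bx} − 1)` families; the through-origin form exists because a plain
exponential cannot pass through (0, 0), yet zero flexion must give zero
moment, so the origin is appended as a data point for such outcomes.

## Pipeline and determinism

All randomness flows from one `SeedSequence`: per-subject FR angles, then
per-trial generation seeds and per-trial fit seeds. CSVs are written with
fixed `%.10g` float formatting and a schema-version header comment, so one
config + seed pair reproduces byte-identical outputs. The run log records
the seed, a SHA-256 of the configuration, and every skipped trial with its
reason.

Default problem sizes in tests and demos (short 60–120-s holds, 2–10
subjects) are chosen so the full suite exercises every stage on an ordinary
workstation; the physics and the code paths are identical at the full 960-s
hold, which the oracle-equivalence, parameter-recovery and model-ordering
tests use directly.

## Known limitations

* The NZ slope rule operates near its detection limit when bin noise is
  comparable to (slope threshold − true inner slope) × window; at the
  largest exposures the angle-gained inner NZ slope approaches the 0.1
  Nm/deg threshold and the detected pre-exposure NZ shrinks — visible in
  the worked example at 100 % FR.
* Fitting a 1704.5-s time constant from a 960-s hold is weakly identified;
  under 1 % multiplicative noise the slow-τ error is the largest of any
  parameter (the recovery test bounds its mean at 10 %).
* The sensitivity table uses fitted per-trial parameters, so its nominal
  values inherit fitting bias at short holds.
* Power-law models are compared on t ≥ 1 s only; their R² is not defined
  over the same first second as the exponential models'.
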