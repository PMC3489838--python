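"""Seeded synthetic flexion-exposure trials.

Emulates an in vivo trunk load-relaxation protocol: the pelvis and legs are
rotated to impose a trapezoidal lumbar-flexion angle profile (loading ramp at
~3 deg/s, prolonged hold, unloading ramp) while a harness load cell records
the restraint force.  The generated trial carries two asynchronous streams —
lumbar angle at 100 Hz (IMU-like) and force at 1000 Hz (load-cell-like) —
with additive Gaussian sensor noise on each.

Ground truth is a generalized-Maxwell (Kelvin-solid) material whose moment
under an *arbitrary* angle history is computed by the discrete hereditary
(convolution) integral::

    M(t) = k_inf * q(t) + sum_i k_i * int_0^t exp(-(t-s)/tau_i) dq/ds ds

where ``q`` is the effective deformation after a low-stiffness neutral zone
is applied near the upright posture.  The per-branch recursion used here is
exact for piecewise-linear angle histories, so it doubles as an independent
oracle for the closed-form constant-angle relaxation equations.

Two further features of the real data are emulated: initial moment grows
exponentially with hold angle (stiffness scaled by ``exp(gain * theta0)``),
and relaxation has distinct fast (tens of seconds) and slow (hundreds to
thousands of seconds) phases via a default two-branch Prony ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import lfilter

from .models import ModelParams, PronyParams, SLSParams

__all__ = [
    "ProtocolSpec",
    "GroundTruthSpec",
    "TrialRecording",
    "default_truth",
    "truth_moment",
    "scale_stiffness",
    "generate_trial",
    "generate_cohort",
    "draw_fr_angles",
    "FR_ANGLE_MEAN_DEG",
    "FR_ANGLE_SD_DEG",
]

#: Cohort flexion-relaxation angle distribution (deg): mean and SD of the
#: lumbar angle at which extensor EMG shuts off, measured after a creep
#: pre-exposure in the emulated study population.
FR_ANGLE_MEAN_DEG = 58.2
FR_ANGLE_SD_DEG = 12.0

#: Exposure levels as fractions of the individual FR angle.
DEFAULT_FRACTIONS = (0.30, 0.40, 0.60, 0.80, 1.00)


@dataclass(frozen=True)
class ProtocolSpec:
    """Timing and geometry of one flexion exposure."""

    target_fraction_fr: float  # hold angle as a fraction of the FR angle
    fr_angle: float = FR_ANGLE_MEAN_DEG  # deg
    ramp_rate: float = 3.0  # deg/s, loading and unloading
    hold_duration: float = 960.0  # s (16-min exposure)
    angle_rate_hz: float = 100.0
    force_rate_hz: float = 1000.0
    moment_arm: float = 0.40  # m, harness rod to L5/S1 rotation centre

    def __post_init__(self) -> None:
        if self.ramp_rate <= 0 or self.hold_duration <= 0:
            raise ValueError("ramp_rate and hold_duration must be positive")
        if not 0 < self.target_fraction_fr <= 1:
            raise ValueError("target_fraction_fr must be in (0, 1]")
        if self.fr_angle <= 0:
            raise ValueError("fr_angle must be positive")
        if self.angle_rate_hz <= 0 or self.force_rate_hz <= 0:
            raise ValueError("sampling rates must be positive")
        if self.moment_arm <= 0:
            raise ValueError("moment_arm must be positive")

    @property
    def hold_angle(self) -> float:
        """Target hold angle theta0 (deg)."""
        return self.target_fraction_fr * self.fr_angle

    @property
    def ramp_duration(self) -> float:
        return self.hold_angle / self.ramp_rate

    @property
    def total_duration(self) -> float:
        return 2.0 * self.ramp_duration + self.hold_duration


@dataclass(frozen=True)
class GroundTruthSpec:
    """Material ground truth and sensor-noise model for synthesis.

    ``params`` must belong to a Kelvin-solid family (SLS or Prony); the
    power-law models have no hereditary-integral counterpart here.
    ``nz_width`` imposes a low-stiffness neutral zone: below it the local
    stiffness is ``nz_slope_fraction`` of the nominal value.  Stiffnesses
    are scaled by ``exp(stiffness_angle_gain * theta0)`` per trial, giving
    the exponential growth of initial moment with hold angle seen in vivo.
    """

    params: ModelParams = None  # type: ignore[assignment]
    nz_width: float = 10.0  # deg
    nz_slope_fraction: float = 0.02  # stiffness multiplier inside the NZ
    stiffness_angle_gain: float = 0.02  # 1/deg
    force_noise_sd: float = 0.5  # N, typical strain-gauge load-cell RMS noise
    angle_noise_sd: float = 0.1  # deg, IMU noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.params is None:
            object.__setattr__(self, "params", default_truth().params)
        if not isinstance(self.params, (SLSParams, PronyParams)):
            raise ValueError("ground-truth params must be SLS or Prony (Kelvin-solid)")
        if self.nz_width < 0:
            raise ValueError("nz_width must be non-negative")
        if self.nz_slope_fraction < 0 or self.nz_slope_fraction >= 1:
            raise ValueError("nz_slope_fraction must be in [0, 1)")
        if self.force_noise_sd < 0 or self.angle_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")


def default_truth(**overrides) -> GroundTruthSpec:
    """Default ground truth: two-branch Prony solid with fast (~9 s) and
    slow (~1700 s) relaxation phases.  The values are the cohort-mean
    parameters fitted to in vivo trunk relaxation at the full
    flexion-relaxation angle: k_inf = 0.34, fast branch 0.23 Nm/deg at
    8.8 s, slow branch 0.36 Nm/deg at 1704.5 s."""
    params = overrides.pop(
        "params",
        PronyParams(k_inf=0.34, branches=((0.23, 8.8), (0.36, 1704.5))),
    )
    return GroundTruthSpec(params=params, **overrides)


@dataclass(frozen=True)
class TrialRecording:
    """One synthetic (or loaded) exposure trial: raw two-stream recording."""

    angle_time: np.ndarray  # s
    angle: np.ndarray  # deg, at angle_rate_hz
    force_time: np.ndarray  # s
    force: np.ndarray  # N, at force_rate_hz
    moment_arm: float  # m
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("angle_time", "angle", "force_time", "force"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if len(self.angle_time) != len(self.angle):
            raise ValueError("angle stream lengths differ")
        if len(self.force_time) != len(self.force):
            raise ValueError("force stream lengths differ")
        for tv in (self.angle_time, self.force_time):
            if len(tv) > 1 and np.any(np.diff(tv) <= 0):
                raise ValueError("time vectors must be strictly increasing")
        if not np.all(np.isfinite(self.force)):
            raise ValueError("force must be finite")
        if self.moment_arm <= 0:
            raise ValueError("moment_arm must be positive")


# -- hereditary-integral ground truth ---------------------------------------


def _kelvin_terms(params: ModelParams) -> Tuple[float, Tuple[Tuple[float, float], ...]]:
    """Common (k_inf, branches) view of the Kelvin-solid families."""
    if isinstance(params, SLSParams):
        return params.k_parallel, ((params.k_maxwell, params.tau),)
    if isinstance(params, PronyParams):
        return params.k_inf, params.branches
    raise ValueError("hereditary integral requires a Kelvin-solid (SLS/Prony) model")


def scale_stiffness(params: ModelParams, factor: float) -> ModelParams:
    """Scale every stiffness (time constants untouched) by ``factor``."""
    if isinstance(params, SLSParams):
        return SLSParams.from_tau(params.k_maxwell * factor,
                                  params.k_parallel * factor, params.tau)
    if isinstance(params, PronyParams):
        return PronyParams(params.k_inf * factor,
                           tuple((k * factor, tau) for k, tau in params.branches))
    raise ValueError("stiffness scaling is defined for Kelvin-solid models only")


def _effective_deformation(angle: np.ndarray, truth: GroundTruthSpec) -> np.ndarray:
    """Map the measured angle to the deformation driving the material.

    Inside the neutral zone (angle < nz_width) the slope is only
    ``nz_slope_fraction``; beyond it the slope is 1.  The map is static and
    piecewise linear, so it preserves the elastic/viscous character of the
    material it feeds.
    """
    nz = truth.nz_width
    f = truth.nz_slope_fraction
    return f * np.minimum(angle, nz) + np.maximum(angle - nz, 0.0)


def truth_moment(truth: GroundTruthSpec, time: np.ndarray, angle: np.ndarray,
                 apply_nz: bool = True) -> np.ndarray:
    """Moment (Nm) of the ground-truth material under an angle history.

    Discrete hereditary integral: each Maxwell branch carries state
    ``h_i[n] = k_i * int exp(-(t_n - s)/tau_i) dq`` advanced by the
    recursion ``h[n] = a h[n-1] + b (q[n] - q[n-1])`` with
    ``a = exp(-dt/tau)`` and ``b = k tau (1 - a) / dt`` — exact when ``q``
    is linear within each step.  The history is assumed to start from rest
    except for an instantaneous step to ``angle[0]`` at ``t[0]``.  Negative
    totals are clamped at zero (the harness pushes only).

    Requires a uniform time grid and a Kelvin-solid ``truth.params``.
    """
    time = np.asarray(time, dtype=float)
    angle = np.asarray(angle, dtype=float)
    if time.shape != angle.shape or time.ndim != 1 or len(time) < 2:
        raise ValueError("time and angle must be equal-length 1-D arrays (n >= 2)")
    steps = np.diff(time)
    dt = steps[0]
    if dt <= 0 or not np.allclose(steps, dt, rtol=1e-6, atol=1e-12):
        raise ValueError("angle history must be sampled on a uniform time grid")
    k_inf, branches = _kelvin_terms(truth.params)

    q = _effective_deformation(angle, truth) if apply_nz else angle
    moment = k_inf * q
    dq = np.diff(q)
    for k_i, tau_i in branches:
        a = math.exp(-dt / tau_i)
        b = k_i * tau_i * (1.0 - a) / dt
        h0 = k_i * q[0]  # instantaneous step response at t[0]
        rest, _ = lfilter([b], [1.0, -a], dq, zi=np.array([a * h0]))
        moment = moment + np.concatenate(([h0], rest))
    return np.maximum(moment, 0.0)


# -- trial and cohort generation --------------------------------------------


def trapezoid_profile(time: np.ndarray, protocol: ProtocolSpec) -> np.ndarray:
    """Noise-free trapezoidal angle profile (deg) on the given time grid."""
    t_up = protocol.ramp_duration
    t_down = t_up + protocol.hold_duration
    knots = np.array([0.0, t_up, t_down, protocol.total_duration])
    vals = np.array([0.0, protocol.hold_angle, protocol.hold_angle, 0.0])
    return np.interp(time, knots, vals)


def generate_trial(protocol: ProtocolSpec, truth: GroundTruthSpec,
                   seed: Optional[int] = None) -> TrialRecording:
    """Synthesize one exposure trial.

    The angle profile is built on the force grid, passed through the
    hereditary integral (with per-trial stiffness scaled by
    ``exp(stiffness_angle_gain * theta0)``), converted to force via the
    moment arm, and then both streams receive independent Gaussian noise.
    Identical seed -> bit-identical output.

    Raises ``ValueError`` when the hold angle does not exceed the neutral
    zone: such trials carry no measurable viscoelastic response (the in
    vivo analogue is a discarded low-exposure trial).
    """
    theta0 = protocol.hold_angle
    if theta0 <= truth.nz_width:
        raise ValueError(
            f"hold angle {theta0:.1f} deg does not exceed the neutral zone "
            f"({truth.nz_width:.1f} deg): no measurable viscoelastic response"
        )
    if seed is None:
        seed = truth.seed
    rng = np.random.default_rng(seed)

    total = protocol.total_duration
    n_force = int(round(total * protocol.force_rate_hz)) + 1
    force_time = np.arange(n_force) / protocol.force_rate_hz
    n_angle = int(round(total * protocol.angle_rate_hz)) + 1
    angle_time = np.arange(n_angle) / protocol.angle_rate_hz

    profile_f = trapezoid_profile(force_time, protocol)
    scaled = replace(truth, params=scale_stiffness(
        truth.params, math.exp(truth.stiffness_angle_gain * theta0)))
    moment = truth_moment(scaled, force_time, profile_f)

    angle = trapezoid_profile(angle_time, protocol)
    if truth.angle_noise_sd > 0:
        angle = angle + rng.normal(0.0, truth.angle_noise_sd, n_angle)
    angle = np.clip(angle, 0.0, None)

    force = moment / protocol.moment_arm
    if truth.force_noise_sd > 0:
        force = force + rng.normal(0.0, truth.force_noise_sd, n_force)

    meta = {
        "seed": int(seed),
        "theta0_deg": theta0,
        "fr_angle_deg": protocol.fr_angle,
        "target_fraction_fr": protocol.target_fraction_fr,
        "t_loading_end_s": protocol.ramp_duration,
        "t_relaxation_end_s": protocol.ramp_duration + protocol.hold_duration,
        "protocol": protocol,
        "truth": truth,
    }
    return TrialRecording(angle_time, angle, force_time, force,
                          protocol.moment_arm, meta)


def draw_fr_angles(n: int, rng: np.random.Generator,
                   mean: float = FR_ANGLE_MEAN_DEG,
                   sd: float = FR_ANGLE_SD_DEG) -> np.ndarray:
    """Per-subject FR angles (deg) from a normal truncated to positives."""
    if n < 1:
        raise ValueError("need at least one subject")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if sd == 0:
        return np.full(n, float(mean))
    out = np.empty(n)
    for i in range(n):
        x = rng.normal(mean, sd)
        while x <= 0:  # truncate at zero; negligible mass for the defaults
            x = rng.normal(mean, sd)
        out[i] = x
    return out


def generate_cohort(n_subjects: int,
                    fractions: Sequence[float] = DEFAULT_FRACTIONS,
                    truth_template: Optional[GroundTruthSpec] = None,
                    seed: int = 0,
                    protocol_template: Optional[ProtocolSpec] = None,
                    fr_mean: float = FR_ANGLE_MEAN_DEG,
                    fr_sd: float = FR_ANGLE_SD_DEG,
                    on_infeasible: str = "error") -> List[TrialRecording]:
    """One trial per subject x exposure fraction, subject-major order.

    Per-subject FR angles are drawn from a truncated normal; every trial
    gets its own child seed, so the cohort is reproducible as a whole.
    ``on_infeasible`` controls trials whose hold angle falls inside the
    neutral zone: ``"error"`` raises, ``"skip"`` drops them silently.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    fractions = list(fractions)
    if not fractions:
        raise ValueError("fractions must be non-empty")
    if on_infeasible not in ("error", "skip"):
        raise ValueError("on_infeasible must be 'error' or 'skip'")
    if truth_template is None:
        truth_template = default_truth()
    if protocol_template is None:
        protocol_template = ProtocolSpec(target_fraction_fr=fractions[0])

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    fr_angles = draw_fr_angles(n_subjects, rng, fr_mean, fr_sd)
    trial_seeds = rng.integers(0, 2**31 - 1, size=n_subjects * len(fractions))

    trials: List[TrialRecording] = []
    i = 0
    for subject, fr in enumerate(fr_angles):
        for frac in fractions:
            protocol = replace(protocol_template,
                               target_fraction_fr=float(frac), fr_angle=float(fr))
            try:
                trial = generate_trial(protocol, truth_template,
                                       seed=int(trial_seeds[i]))
            except ValueError:
                if on_infeasible == "error":
                    raise
                i += 1
                continue
            trial.metadata["subject"] = subject
            trials.append(trial)
            i += 1
    return trials
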