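"""Raw streams -> aligned moment-angle record -> phase segmentation ->
windowed relaxation summary measures.

The protocol has three phases: loading (legs raised, angle ramps up),
load-relaxation (constant-angle hold) and unloading (angle ramps down).
Phases are located from the smoothed angle rate.  Initial and final moments
of the hold are means over 3-s windows at the start and end of the
relaxation phase; their difference is the moment drop, and ``t90`` is the
time after hold onset at which 90% of the total drop has occurred.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.ndimage import uniform_filter1d

from .synthetic import TrialRecording

__all__ = [
    "UnusableTrialError",
    "AlignedTrial",
    "PhaseSegmentation",
    "RelaxationSummary",
    "RelaxationSegment",
    "compute_moment",
    "resample_align",
    "segment_phases",
    "summarize_relaxation",
    "extract_relaxation_segment",
]


class UnusableTrialError(ValueError):
    """The trial cannot yield relaxation measures (no plateau, hold too
    short, ...); the in vivo analogue is a discarded trial."""


@dataclass(frozen=True)
class AlignedTrial:
    """Moment and angle on one uniform time grid (default 100 Hz)."""

    time: np.ndarray  # s
    angle: np.ndarray  # deg
    moment: np.ndarray  # Nm, clamped >= 0
    fr_angle: float  # deg

    def __post_init__(self) -> None:
        for name in ("time", "angle", "moment"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.time)
        if len(self.angle) != n or len(self.moment) != n:
            raise ValueError("time, angle and moment must have equal length")
        if n < 2:
            raise ValueError("aligned trial needs at least two samples")
        steps = np.diff(self.time)
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
            raise ValueError("aligned time grid must be uniform")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass(frozen=True)
class PhaseSegmentation:
    """Half-open sample intervals [start, stop) for the three phases."""

    loading: Tuple[int, int]
    relaxation: Tuple[int, int]
    unloading: Tuple[int, int]

    def __post_init__(self) -> None:
        lo, rel, un = self.loading, self.relaxation, self.unloading
        for a, b in (lo, rel, un):
            if a < 0 or b < a:
                raise ValueError("phase intervals must be non-negative and ordered")
        if not (lo[1] <= rel[0] and rel[1] <= un[0]):
            raise ValueError("phases must be ordered and non-overlapping")
        if rel[1] <= rel[0]:
            raise ValueError("relaxation phase must be non-empty")


@dataclass(frozen=True)
class RelaxationSummary:
    initial_moment: float  # Nm, first-window mean
    final_moment: float  # Nm, last-window mean
    moment_drop: float  # Nm
    moment_drop_pct: float  # % of initial
    t90: float  # s from hold onset; NaN when unresolved
    t90_resolved: bool


@dataclass(frozen=True)
class RelaxationSegment:
    """Hold-phase data for model fitting: time zeroed at hold onset."""

    time: np.ndarray  # s
    moment: np.ndarray  # Nm
    theta0: float  # deg, mean hold angle

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "moment", np.asarray(self.moment, dtype=float))
        if len(self.time) != len(self.moment):
            raise ValueError("time and moment must have equal length")
        if self.theta0 <= 0:
            raise ValueError("theta0 must be positive")


def compute_moment(force: np.ndarray, moment_arm: float) -> np.ndarray:
    """Trunk moment (Nm) = force (N) x moment arm (m), clamped at zero.

    The harness can only push, so negative (noise-driven) values are
    physically meaningless and are clamped.
    """
    if moment_arm <= 0:
        raise ValueError("moment_arm must be positive")
    return np.maximum(np.asarray(force, dtype=float) * moment_arm, 0.0)


def resample_align(trial: TrialRecording) -> AlignedTrial:
    """Block-average the fast force stream onto the slower angle grid.

    With the default rates (1000 Hz force, 100 Hz angle) each angle sample
    receives the mean of the 10 force samples in its interval, attenuating
    load-cell noise by sqrt(10).  Only the overlapping time span is kept.
    Equal-rate streams pass through on the span intersection.
    """
    ta, tf = trial.angle_time, trial.force_time
    t0 = max(ta[0], tf[0])
    t1 = min(ta[-1], tf[-1])
    if t1 <= t0:
        raise ValueError("angle and force streams have disjoint time spans")

    dt_a = float(np.median(np.diff(ta)))
    dt_f = float(np.median(np.diff(tf)))
    ratio = int(round(dt_a / dt_f))
    if ratio < 1:
        raise ValueError("force stream must be at least as fast as the angle stream")

    ia0 = int(np.searchsorted(ta, t0 - 1e-12))
    ia1 = int(np.searchsorted(ta, t1 + 1e-12, side="right"))
    time = ta[ia0:ia1]
    angle = trial.angle[ia0:ia1]

    if ratio == 1:
        force = np.interp(time, tf, trial.force)
    else:
        # mean of force samples in [t_k, t_k + dt_a) for each angle time t_k
        if0 = np.searchsorted(tf, time[0] - 1e-12)
        n_full = min(len(time), (len(tf) - if0) // ratio)
        if n_full < 2:
            raise ValueError("overlap too short to align the streams")
        time = time[:n_full]
        angle = angle[:n_full]
        block = trial.force[if0:if0 + n_full * ratio].reshape(n_full, ratio)
        force = block.mean(axis=1)

    moment = compute_moment(force, trial.moment_arm)
    fr = float(trial.metadata.get("fr_angle_deg", np.nan)) if trial.metadata else np.nan
    return AlignedTrial(time=time, angle=angle, moment=moment, fr_angle=fr)


def _runs(mask: np.ndarray) -> list[Tuple[int, int]]:
    """Half-open [start, stop) intervals of contiguous True runs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[0::2], idx[1::2]))


def segment_phases(aligned: AlignedTrial, rate_threshold: float = 0.5,
                   smooth_window_s: float = 1.0) -> PhaseSegmentation:
    """Locate loading / load-relaxation / unloading phases.

    The angle is smoothed with a moving average (default 1 s, much shorter
    than the ramps) and differentiated; loading is the first contiguous run
    with rate > +threshold, unloading the last run with rate < -threshold,
    and the hold is everything in between.  The default threshold of
    0.5 deg/s sits well between plateau noise and the ~3 deg/s ramps.
    """
    if rate_threshold <= 0:
        raise ValueError("rate_threshold must be positive")
    n_win = max(1, int(round(smooth_window_s / aligned.dt)))
    smooth = uniform_filter1d(aligned.angle, size=n_win, mode="nearest")
    rate = np.gradient(smooth, aligned.time)

    up_runs = _runs(rate > rate_threshold)
    down_runs = _runs(rate < -rate_threshold)
    if not up_runs:
        raise UnusableTrialError("no loading phase detected (angle never ramps up)")
    if not down_runs:
        raise UnusableTrialError("no unloading phase detected (angle never ramps down)")
    loading = tuple(int(i) for i in up_runs[0])
    unloading = tuple(int(i) for i in down_runs[-1])
    if unloading[0] <= loading[1]:
        raise UnusableTrialError("phases out of order: no plateau between ramps")
    relaxation = (loading[1], unloading[0])
    return PhaseSegmentation(loading=loading, relaxation=relaxation,
                             unloading=unloading)


def summarize_relaxation(aligned: AlignedTrial, seg: PhaseSegmentation,
                         window_s: float = 3.0) -> RelaxationSummary:
    """Windowed summary of the hold phase.

    Initial (final) moment is the mean over the half-open 3-s window at the
    start (end) of the hold.  ``t90`` is the first time, measured from hold
    onset, at which the moment falls to ``initial - 0.9 * drop``; when the
    drop is non-positive the trial shows no relaxation and ``t90`` is
    flagged unresolved (NaN).
    """
    i0, i1 = seg.relaxation
    t = aligned.time[i0:i1]
    m = aligned.moment[i0:i1]
    if len(t) == 0:
        raise UnusableTrialError("empty relaxation phase")
    rel_t = t - t[0]
    duration = rel_t[-1]
    if duration < 2.0 * window_s:
        raise UnusableTrialError(
            f"hold of {duration:.1f} s is shorter than two {window_s:.0f}-s windows"
        )
    first = rel_t < window_s
    last = rel_t >= duration - window_s
    initial = float(m[first].mean())
    final = float(m[last].mean())
    drop = initial - final
    pct = 100.0 * drop / initial if initial > 0 else math.nan

    if drop > 0:
        threshold = initial - 0.9 * drop
        below = np.flatnonzero(m <= threshold)
        if below.size:
            t90 = float(rel_t[below[0]])
            resolved = bool(t90 <= duration)
        else:
            t90, resolved = math.nan, False
    else:
        t90, resolved = math.nan, False
    return RelaxationSummary(initial_moment=initial, final_moment=final,
                             moment_drop=drop, moment_drop_pct=pct,
                             t90=t90, t90_resolved=resolved)


def extract_relaxation_segment(aligned: AlignedTrial, seg: PhaseSegmentation,
                               decimate_hz: Optional[float] = None) -> RelaxationSegment:
    """Hold-phase segment for fitting, optionally block-mean decimated.

    Decimation to ~1 Hz keeps nonlinear fits cheap without biasing them:
    block means preserve the slowly varying relaxation signal while
    averaging down sensor noise.
    """
    i0, i1 = seg.relaxation
    t = aligned.time[i0:i1]
    m = aligned.moment[i0:i1]
    theta0 = float(aligned.angle[i0:i1].mean())
    rel_t = t - t[0]
    if decimate_hz is not None:
        factor = max(1, int(round(1.0 / (decimate_hz * aligned.dt))))
        n_full = len(rel_t) // factor
        if n_full < 2:
            raise UnusableTrialError("relaxation too short for requested decimation")
        rel_t = rel_t[:n_full * factor].reshape(n_full, factor).mean(axis=1)
        m = m[:n_full * factor].reshape(n_full, factor).mean(axis=1)
    return RelaxationSegment(time=rel_t, moment=m, theta0=theta0)
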