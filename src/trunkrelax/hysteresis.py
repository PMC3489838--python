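"""Hysteresis loop, neutral zone and energy measures.

The loading and unloading phases of a trial trace an angle-moment loop
whose enclosed area is the energy dissipated by viscous processes.  Three
derived measures are computed:

* Neutral zone (NZ): the low-resistance region around upright posture,
  operationalized as the contiguous angle extent starting at 0 deg over
  which the local angle-moment slope is < 0.1 Nm/deg *and* the moment is
  < 7 Nm.
* Loading / unloading energies E1 and E2 (Nm*deg): areas under the two
  curves; dissipated energy dE = E1 - E2.
* Viscoelastic state RE = dE / E1, 0 for a purely elastic response and 1
  for a purely viscous one (no energy recovered on unloading).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .preprocess import AlignedTrial, PhaseSegmentation

__all__ = [
    "HysteresisLoop",
    "NZResult",
    "EnergyResult",
    "build_loop",
    "neutral_zone",
    "nz_change",
    "energies",
    "DEFAULT_BIN_DEG",
    "NZ_SLOPE_THRESHOLD",
    "NZ_MOMENT_THRESHOLD",
]

DEFAULT_BIN_DEG = 0.25
NZ_SLOPE_THRESHOLD = 0.1  # Nm/deg
NZ_MOMENT_THRESHOLD = 7.0  # Nm


@dataclass(frozen=True)
class HysteresisLoop:
    """Loading and unloading angle-moment curves on per-curve angle grids
    (bin centres, ascending)."""

    loading_angle: np.ndarray  # deg
    loading_moment: np.ndarray  # Nm
    unloading_angle: np.ndarray  # deg
    unloading_moment: np.ndarray  # Nm

    def __post_init__(self) -> None:
        for name in ("loading_angle", "loading_moment",
                     "unloading_angle", "unloading_moment"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if len(self.loading_angle) != len(self.loading_moment):
            raise ValueError("loading curve arrays must have equal length")
        if len(self.unloading_angle) != len(self.unloading_moment):
            raise ValueError("unloading curve arrays must have equal length")
        for ang in (self.loading_angle, self.unloading_angle):
            if len(ang) > 1 and np.any(np.diff(ang) <= 0):
                raise ValueError("curve angles must be strictly increasing")


def _bin_curve(angle: np.ndarray, moment: np.ndarray,
               bin_deg: float) -> Tuple[np.ndarray, np.ndarray]:
    """Within-bin moment means on a uniform angle grid of width ``bin_deg``."""
    idx = np.floor(angle / bin_deg + 0.5).astype(int)  # nearest bin centre
    order = np.argsort(idx, kind="stable")
    idx_s, m_s = idx[order], moment[order]
    uniq, starts = np.unique(idx_s, return_index=True)
    sums = np.add.reduceat(m_s, starts)
    counts = np.diff(np.concatenate((starts, [len(m_s)])))
    return uniq * bin_deg, sums / counts


def build_loop(aligned: AlignedTrial, seg: PhaseSegmentation,
               bin_deg: float = DEFAULT_BIN_DEG) -> HysteresisLoop:
    """Loop from the loading and unloading phases of an aligned trial,
    each re-binned onto a uniform angle grid by within-bin averaging."""
    if bin_deg <= 0:
        raise ValueError("bin_deg must be positive")
    la, lb = seg.loading
    ua, ub = seg.unloading
    load_ang, load_m = _bin_curve(aligned.angle[la:lb], aligned.moment[la:lb], bin_deg)
    unload_ang, unload_m = _bin_curve(aligned.angle[ua:ub], aligned.moment[ua:ub], bin_deg)
    if len(load_ang) < 5 or len(unload_ang) < 5:
        raise ValueError("fewer than 5 angle bins: angle excursion too small for a loop")
    return HysteresisLoop(load_ang, load_m, unload_ang, unload_m)


def neutral_zone(angle: np.ndarray, moment: np.ndarray,
                 slope_thresh: float = NZ_SLOPE_THRESHOLD,
                 moment_thresh: float = NZ_MOMENT_THRESHOLD,
                 window_deg: float = 1.0,
                 anchor_tol_deg: float = DEFAULT_BIN_DEG,
                 persistence: int = 2) -> float:
    """Neutral-zone extent (deg) of one angle-moment curve.

    Walks outward from the upright posture; a point passes while the local
    slope (linear regression over the trailing ``window_deg`` of curve) is
    below ``slope_thresh`` and its moment is below ``moment_thresh``.  The
    NZ ends at the first *sustained* violation — ``persistence``
    consecutive failing points (a run truncated by the end of the curve
    also counts), so one noisy bin cannot terminate the zone.  The curve
    must be anchored at angle 0 (within ``anchor_tol_deg``).
    """
    angle = np.asarray(angle, dtype=float)
    moment = np.asarray(moment, dtype=float)
    if angle.size < 2:
        raise ValueError("curve needs at least two points")
    if angle[0] > anchor_tol_deg:
        raise ValueError("curve is not anchored at the neutral posture (angle 0)")
    if persistence < 1:
        raise ValueError("persistence must be >= 1")

    n = len(angle)
    fails = np.zeros(n, dtype=bool)
    for j in range(1, n):
        sel = (angle >= angle[j] - window_deg) & (angle <= angle[j])
        x, y = angle[sel], moment[sel]
        if x.size >= 2:
            slope = float(np.polyfit(x, y, 1)[0])
        else:
            slope = (moment[j] - moment[j - 1]) / (angle[j] - angle[j - 1])
        fails[j] = slope >= slope_thresh or moment[j] >= moment_thresh

    nz = float(angle[0])
    for j in range(1, n):
        if fails[j]:
            run_end = min(j + persistence, n)
            if np.all(fails[j:run_end]):
                break
        nz = float(angle[j])
    return nz


@dataclass(frozen=True)
class NZResult:
    """Pre/post neutral-zone comparison for one trial."""

    nz_pre_deg: float
    nz_post_deg: float
    nz_pre_normalized: float  # % of FR angle
    nz_post_normalized: float  # % of FR angle
    pct_change: float  # % change post vs pre; NaN when pre is zero
    defined: bool


def nz_change(pre_nz: float, post_nz: float, fr_angle: float) -> NZResult:
    """Normalize NZ extents by the FR angle and compute the % change."""
    if fr_angle <= 0:
        raise ValueError("fr_angle must be positive")
    if pre_nz < 0 or post_nz < 0:
        raise ValueError("NZ extents must be non-negative")
    pre_norm = 100.0 * pre_nz / fr_angle
    post_norm = 100.0 * post_nz / fr_angle
    if pre_nz > 0:
        return NZResult(pre_nz, post_nz, pre_norm, post_norm,
                        100.0 * (post_nz - pre_nz) / pre_nz, True)
    return NZResult(pre_nz, post_nz, pre_norm, post_norm, math.nan, False)


@dataclass(frozen=True)
class EnergyResult:
    e1: float  # Nm*deg, loading energy
    e2: float  # Nm*deg, unloading (recovered) energy
    de: float  # Nm*deg, dissipated energy E1 - E2
    re: float  # dimensionless viscoelastic state dE/E1; NaN if E1 = 0
    defined: bool


def energies(loop: HysteresisLoop) -> EnergyResult:
    """Trapezoidal E1, E2 over the angle grids; RE = (E1 - E2)/E1.

    Moments are floored at zero before integration so that E2 counts only
    recovered (positive) work — this makes RE reach exactly 1 for a pure
    damper whose unloading moment is clamped at zero by the one-sided
    harness contact.
    """
    e1 = float(np.trapezoid(np.maximum(loop.loading_moment, 0.0), loop.loading_angle))
    e2 = float(np.trapezoid(np.maximum(loop.unloading_moment, 0.0), loop.unloading_angle))
    de = e1 - e2
    if e1 > 0:
        return EnergyResult(e1, e2, de, de / e1, True)
    return EnergyResult(e1, e2, de, math.nan, False)
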