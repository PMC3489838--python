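"""Dimensionless parameter-sensitivity coefficients and angle trends.

For a model-predicted outcome R (initial moment or moment drop) and a
parameter p with nominal value ``p_nom`` (mean across trials) and observed
range ``(low, high)`` (range across trials), the sensitivity coefficient is

    sc = (delta_R / R_nom) / ((high - low) / p_nom)

where ``delta_R`` is the change in the predicted outcome as p sweeps from
``low`` to ``high`` with every other parameter held at nominal.  The two
normalizations (delta_R/R_nom)/(delta_p/p_nom) and
(delta_R/delta_p)*(p_nom/R_nom) are algebraically identical, so only one
is implemented.

Outcomes are evaluated from the closed-form relaxation equations at the
endpoints of the hold: initial moment = M(t_start) and moment drop =
M(t_start) - M(horizon), with t_start = 0 for the Kelvin-solid models and
t_start = 1 s for the power-law models (whose forms diverge at t = 0).
Point evaluation at t_start makes the initial moment of any Kelvin-solid
model exactly independent of its time constants, so their sensitivity
coefficients are exact zeros — the analytic signature this analysis checks.

Angle trends: cohort-mean outcomes against exposure level are fit with
linear, exponential, or exponential-through-origin (a*(exp(b*x) - 1))
families, the last because zero flexion must give zero moment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .models import (POWER_LAW_T_MIN, ModelParams, MSMParams, PronyParams,
                     SchaperyParams, SLSParams, model_kind, predict)

__all__ = [
    "SensitivitySpec",
    "SensitivityResult",
    "TrendFit",
    "OUTCOMES",
    "param_ids",
    "get_param",
    "set_param",
    "model_outcome",
    "sensitivity_coefficient",
    "sensitivity_table",
    "fit_angle_trend",
]

OUTCOMES = ("initial_moment", "moment_drop")


# -- generic parameter addressing -------------------------------------------


def param_ids(params: ModelParams) -> Tuple[str, ...]:
    """Addressable parameter names for one parameter set.

    Prony branches are addressed as ``k_1, tau_1, ...`` in ascending-tau
    order; the SLS viscous parameter is the damping coefficient
    ``c_damper`` (its time constant is derived, mirroring how the damper —
    not tau — is treated as the physical parameter)."""
    if isinstance(params, SLSParams):
        return ("k_maxwell", "k_parallel", "c_damper")
    if isinstance(params, PronyParams):
        names = ["k_inf"]
        for i in range(1, params.n + 1):
            names += [f"k_{i}", f"tau_{i}"]
        return tuple(names)
    if isinstance(params, SchaperyParams):
        return ("k_eq", "c1", "c2")
    if isinstance(params, MSMParams):
        return ("k0", "beta")
    raise TypeError(f"unknown parameter type: {type(params)!r}")


def get_param(params: ModelParams, param_id: str) -> float:
    if isinstance(params, PronyParams) and (param_id.startswith("k_")
                                            or param_id.startswith("tau_")):
        if param_id != "k_inf":
            kind, idx = param_id.rsplit("_", 1)
            i = int(idx) - 1
            if not 0 <= i < params.n:
                raise KeyError(param_id)
            return params.branches[i][0] if kind == "k" else params.branches[i][1]
    if param_id not in params.__dataclass_fields__:
        raise KeyError(param_id)
    return getattr(params, param_id)


def set_param(params: ModelParams, param_id: str, value: float) -> ModelParams:
    """Return a copy with one parameter replaced."""
    if isinstance(params, PronyParams) and param_id != "k_inf":
        kind, idx = param_id.rsplit("_", 1)
        if kind in ("k", "tau") and idx.isdigit():
            i = int(idx) - 1
            if not 0 <= i < params.n:
                raise KeyError(param_id)
            branches = [list(b) for b in params.branches]
            branches[i][0 if kind == "k" else 1] = value
            # a swept tau may break the ascending order; rebuild sorted
            branches.sort(key=lambda b: b[1])
            return PronyParams(params.k_inf, tuple(tuple(b) for b in branches))
    if param_id not in params.__dataclass_fields__:
        raise KeyError(param_id)
    return replace(params, **{param_id: value})


# -- outcomes and Eq.-5-style coefficients ----------------------------------


def _t_start(params: ModelParams) -> float:
    return 0.0 if isinstance(params, (SLSParams, PronyParams)) else POWER_LAW_T_MIN


def model_outcome(params: ModelParams, outcome: str, theta0: float,
                  horizon: float) -> float:
    """Closed-form outcome of one parameter set at hold angle ``theta0``.

    ``horizon`` is the hold duration (s) at which the final moment is
    taken for the moment drop.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"outcome must be one of {OUTCOMES}")
    t0 = _t_start(params)
    if horizon <= t0:
        raise ValueError("horizon must exceed the evaluation start time")
    m_start = float(predict(np.array([t0]), theta0, params)[0])
    if outcome == "initial_moment":
        return m_start
    m_end = float(predict(np.array([horizon]), theta0, params)[0])
    return m_start - m_end


@dataclass(frozen=True)
class SensitivitySpec:
    """One (model parameter, outcome) sensitivity computation."""

    nominal_params: ModelParams  # nominal = mean across trials
    param_id: str
    outcome: str  # "initial_moment" or "moment_drop"
    param_range: Tuple[float, float]  # (low, high), observed range
    theta0: float  # deg
    horizon: float  # s, hold duration

    def __post_init__(self) -> None:
        low, high = self.param_range
        if not low < high:
            raise ValueError("param_range must satisfy low < high")
        if self.outcome not in OUTCOMES:
            raise ValueError(f"outcome must be one of {OUTCOMES}")
        if self.horizon <= 0 or self.theta0 <= 0:
            raise ValueError("theta0 and horizon must be positive")
        get_param(self.nominal_params, self.param_id)  # existence check


@dataclass(frozen=True)
class SensitivityResult:
    sc: float  # dimensionless, absolute value; NaN when undefined
    delta_r: float  # outcome units (Nm)
    r_nominal: float  # Nm
    defined: bool


def sensitivity_coefficient(spec: SensitivitySpec) -> SensitivityResult:
    """Dimensionless sensitivity of one outcome to one parameter."""
    p_nom = get_param(spec.nominal_params, spec.param_id)
    r_nom = model_outcome(spec.nominal_params, spec.outcome, spec.theta0,
                          spec.horizon)
    low, high = spec.param_range
    r_low = model_outcome(set_param(spec.nominal_params, spec.param_id, low),
                          spec.outcome, spec.theta0, spec.horizon)
    r_high = model_outcome(set_param(spec.nominal_params, spec.param_id, high),
                           spec.outcome, spec.theta0, spec.horizon)
    delta_r = abs(r_high - r_low)
    if r_nom == 0 or p_nom == 0:
        return SensitivityResult(math.nan, delta_r, r_nom, False)
    sc = (delta_r / abs(r_nom)) / ((high - low) / abs(p_nom))
    return SensitivityResult(sc, delta_r, r_nom, True)


def sensitivity_table(nominal_params: ModelParams,
                      ranges: Dict[str, Tuple[float, float]],
                      theta0: float, horizon: float) -> pd.DataFrame:
    """Sensitivity coefficients of every listed parameter with respect to
    both outcomes; one row per parameter."""
    rows = []
    for pid in param_ids(nominal_params):
        if pid not in ranges:
            continue
        row: dict = {"model": model_kind(nominal_params), "param": pid,
                     "nominal": get_param(nominal_params, pid),
                     "low": ranges[pid][0], "high": ranges[pid][1]}
        for outcome, col in (("initial_moment", "sc_initial"),
                             ("moment_drop", "sc_drop")):
            spec = SensitivitySpec(nominal_params, pid, outcome,
                                   ranges[pid], theta0, horizon)
            row[col] = sensitivity_coefficient(spec).sc
        rows.append(row)
    return pd.DataFrame(rows)


# -- angle-dependence trend fits --------------------------------------------

TREND_FAMILIES = ("linear", "exponential", "exponential_through_origin")


@dataclass(frozen=True)
class TrendFit:
    family: str
    coefficients: Dict[str, float]
    r2: float
    degenerate: bool = False  # flat data or vanishing curvature

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        c = self.coefficients
        if self.family == "linear":
            return c["slope"] * x + c["intercept"]
        if self.family == "exponential":
            return c["a"] * np.exp(c["b"] * x)
        return c["a"] * (np.exp(c["b"] * x) - 1.0)


def _r2(y: np.ndarray, pred: np.ndarray) -> Tuple[float, bool]:
    sst = float(np.sum((y - y.mean()) ** 2))
    sse = float(np.sum((y - pred) ** 2))
    if sst == 0:
        return math.nan, True
    return 1.0 - sse / sst, False


def fit_angle_trend(x: Sequence[float], y: Sequence[float], family: str,
                    include_origin: bool = False) -> TrendFit:
    """Least-squares trend of a cohort-mean outcome vs exposure level.

    ``x`` is the exposure level (%FR), ``y`` the cohort-mean outcome.  With
    ``include_origin`` the point (0, 0) is appended before fitting, for
    outcomes that must vanish at zero flexion.
    """
    if family not in TREND_FAMILIES:
        raise ValueError(f"family must be one of {TREND_FAMILIES}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be finite")
    if include_origin:
        x = np.concatenate(([0.0], x))
        y = np.concatenate(([0.0], y))
    if len(x) < 3:
        raise ValueError("need at least 3 points (after origin augmentation)")

    if family == "linear":
        slope, intercept = np.polyfit(x, y, 1)
        fit = TrendFit("linear", {"slope": float(slope),
                                  "intercept": float(intercept)}, 0.0)
        r2, degen = _r2(y, fit.predict(x))
        return TrendFit(fit.family, fit.coefficients, r2,
                        degenerate=bool(degen or abs(slope) < 1e-12))

    if family == "exponential":
        def f(xv, a, b):
            return a * np.exp(b * xv)
    else:
        def f(xv, a, b):
            return a * (np.exp(b * xv) - 1.0)

    # curvature start from endpoint ratios; fall back over a small p0 grid
    span = x.max() - x.min()
    b0s = [0.5 / max(span, 1e-9), 0.02, 0.001]
    pos = y[np.nonzero(x)[0]]
    a0 = float(np.abs(pos).max()) if pos.size else 1.0
    a0 = a0 if a0 > 0 else 1.0
    best = None
    for b0 in b0s:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # flat data: singular covariance
                popt, _ = curve_fit(f, x, y, p0=[a0 * 0.1, b0], maxfev=20000)
        except Exception:
            continue
        pred = f(x, *popt)
        sse = float(np.sum((y - pred) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        return TrendFit(family, {"a": math.nan, "b": math.nan}, math.nan,
                        degenerate=True)
    a, b = (float(v) for v in best[1])
    fit = TrendFit(family, {"a": a, "b": b}, 0.0)
    r2, degen = _r2(y, fit.predict(x))
    return TrendFit(family, {"a": a, "b": b}, r2,
                    degenerate=bool(degen or abs(b) < 1e-10))
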