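"""Least-squares estimation of relaxation-model parameters.

Each model is fit to a hold-phase segment by bounded nonlinear least
squares (scipy ``least_squares``, trust-region reflective) from multiple
seeded starts; relaxation fits are multi-modal in the time constants, so
initial taus are drawn log-uniformly over [~1 s, hold duration].  The best
start wins by SSE, ties broken by smaller parameter norm so results are
deterministic.  Exponential (Kelvin-solid) models are fit on the full
segment with t = 0 at hold onset; the power-law models only on t >= 1 s
where their forms are finite.

Fit quality is summarized by R^2 = 1 - SSE/SST and the RMSE (Nm) over the
fitted samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .models import (POWER_LAW_T_MIN, ModelParams, MSMParams, PronyParams,
                     SchaperyParams, SLSParams, predict_msm, predict_prony,
                     predict_schapery, predict_sls)
from .preprocess import RelaxationSegment

__all__ = [
    "FitOptions",
    "FitResult",
    "fit_relaxation",
    "fit_many",
    "compare_models",
    "MODEL_KINDS",
]

MODEL_KINDS = ("sls", "prony", "schapery", "msm")


@dataclass(frozen=True)
class FitOptions:
    """Optimizer configuration (the study this emulates reported none, so
    everything here is declared, seeded configuration)."""

    n_starts: int = 8
    seed: int = 0
    prony_n: int = 2
    stiffness_max: float = 100.0  # Nm/deg upper bound
    tau_min: float = 0.1  # s
    tau_max_factor: float = 10.0  # upper tau bound = factor x hold duration
    power_t_min: float = POWER_LAW_T_MIN  # s
    fix_k_eq: bool = False  # pin Schapery k_eq to final-window stiffness
    window_s: float = 3.0  # window used when fix_k_eq estimates k_eq
    ftol: float = 1e-12
    xtol: float = 1e-12


@dataclass(frozen=True)
class FitResult:
    model_kind: str
    params: ModelParams
    r2: float
    rmse: float  # Nm
    sse: float
    converged: bool
    n_starts_used: int


def _segment_anchors(segment: RelaxationSegment, window_s: float) -> Tuple[float, float]:
    """First/last ``window_s`` mean moments, used to seed starts."""
    t, m = segment.time, segment.moment
    dur = t[-1] - t[0]
    w = min(window_s, dur / 2)
    first = m[t - t[0] <= w].mean()
    last = m[t - t[0] >= dur - w].mean()
    return float(first), float(last)


def _best_of(residual_fn, starts: Sequence[np.ndarray], lower: np.ndarray,
             upper: np.ndarray, options: FitOptions):
    best = None
    for x0 in starts:
        x0 = np.clip(x0, lower + 1e-12, upper - 1e-12)
        try:
            res = least_squares(residual_fn, x0, bounds=(lower, upper),
                                method="trf", ftol=options.ftol,
                                xtol=options.xtol, gtol=1e-12)
        except Exception:
            continue
        sse = float(2.0 * res.cost)
        key = (sse, float(np.linalg.norm(res.x)))
        if best is None or key < best[0]:
            best = (key, res)
    if best is None:
        raise RuntimeError("all optimizer starts failed")
    return best[1]


def _quality(m: np.ndarray, pred: np.ndarray) -> Tuple[float, float, float]:
    resid = pred - m
    sse = float(np.dot(resid, resid))
    sst = float(np.sum((m - m.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else math.nan
    rmse = math.sqrt(sse / len(m))
    return r2, rmse, sse


def _fit_sls(segment: RelaxationSegment, options: FitOptions,
             rng: np.random.Generator) -> FitResult:
    t, m, theta0 = segment.time, segment.moment, segment.theta0
    dur = max(t[-1] - t[0], 1.0)
    m0, m_end = _segment_anchors(segment, options.window_s)
    k2_0 = np.clip(m_end / theta0, 1e-4, options.stiffness_max / 2)
    k1_0 = np.clip((m0 - m_end) / theta0, 1e-4, options.stiffness_max / 2)
    taus = np.exp(rng.uniform(math.log(max(1.0, options.tau_min)),
                              math.log(dur), options.n_starts))
    starts = [np.array([k1_0, k2_0, tau]) for tau in taus]

    lower = np.array([1e-8, 1e-8, options.tau_min])
    upper = np.array([options.stiffness_max, options.stiffness_max,
                      options.tau_max_factor * dur])

    def residual(x):
        return theta0 * (x[1] + x[0] * np.exp(-t / x[2])) - m

    res = _best_of(residual, starts, lower, upper, options)
    params = SLSParams.from_tau(*res.x)
    r2, rmse, sse = _quality(m, theta0 * (res.x[1] + res.x[0] * np.exp(-t / res.x[2])))
    return FitResult("sls", params, r2, rmse, sse, bool(res.success), len(starts))


def _fit_prony(segment: RelaxationSegment, options: FitOptions,
               rng: np.random.Generator) -> FitResult:
    t, m, theta0 = segment.time, segment.moment, segment.theta0
    n = options.prony_n
    dur = max(t[-1] - t[0], 1.0)
    m0, m_end = _segment_anchors(segment, options.window_s)
    k_inf0 = np.clip(m_end / theta0, 1e-4, options.stiffness_max / 2)
    k_each = np.clip((m0 - m_end) / theta0 / n, 1e-4, options.stiffness_max / 2)

    starts = []
    log_lo, log_hi = math.log(max(1.0, options.tau_min)), math.log(dur)
    for _ in range(options.n_starts):
        taus = np.sort(np.exp(rng.uniform(log_lo, log_hi, n)))
        starts.append(np.concatenate(([k_inf0], np.full(n, k_each), taus)))
    # nested start seeded from an SLS solution: the Prony fit can then never
    # be meaningfully worse than the SLS fit on the same segment
    sls_opts = FitOptions(n_starts=min(3, options.n_starts), seed=options.seed,
                          tau_min=options.tau_min,
                          tau_max_factor=options.tau_max_factor,
                          stiffness_max=options.stiffness_max)
    sls = _fit_sls(segment, sls_opts, np.random.default_rng(options.seed))
    ks = np.full(n, 1e-6)
    taus = np.geomspace(sls.params.tau, min(sls.params.tau * 50.0,
                                            options.tau_max_factor * dur * 0.99), n)
    taus = np.maximum.accumulate(taus + np.arange(n) * 1e-6)
    ks[0] = sls.params.k_maxwell
    starts.append(np.concatenate(([sls.params.k_parallel], ks, taus)))

    lower = np.concatenate(([1e-8], np.full(n, 1e-8), np.full(n, options.tau_min)))
    upper = np.concatenate(([options.stiffness_max],
                            np.full(n, options.stiffness_max),
                            np.full(n, options.tau_max_factor * dur)))

    def residual(x):
        stiff = np.full_like(t, x[0])
        for i in range(n):
            stiff = stiff + x[1 + i] * np.exp(-t / x[1 + n + i])
        return theta0 * stiff - m

    res = _best_of(residual, starts, lower, upper, options)
    ks, taus = res.x[1:1 + n], res.x[1 + n:]
    order = np.argsort(taus)
    taus = taus[order].copy()
    for i in range(1, n):  # fitted taus may coincide; nudge into valid order
        if taus[i] <= taus[i - 1]:
            taus[i] = taus[i - 1] * (1 + 1e-9)
    params = PronyParams(res.x[0], tuple(zip(ks[order], taus)))
    r2, rmse, sse = _quality(m, residual(res.x) + m)
    return FitResult("prony", params, r2, rmse, sse, bool(res.success), len(starts))


def _fit_schapery(segment: RelaxationSegment, options: FitOptions,
                  rng: np.random.Generator) -> FitResult:
    mask = segment.time >= options.power_t_min
    t, m = segment.time[mask], segment.moment[mask]
    theta0 = segment.theta0
    if len(t) < 3:
        raise ValueError("too few samples at t >= t_min for a power-law fit")
    m0, m_end = _segment_anchors(segment, options.window_s)
    k_end = max(m_end / theta0, 0.0)
    c2s = np.exp(rng.uniform(math.log(0.02), math.log(1.0), options.n_starts))

    if options.fix_k_eq:
        k_eq = k_end

        def residual(x):
            return theta0 * (k_eq + x[0] * t ** (-x[1])) - m

        starts = [np.array([max((m0 / theta0 - k_eq) * t[0] ** c2, 1e-4), c2])
                  for c2 in c2s]
        lower = np.array([0.0, 0.0])
        upper = np.array([options.stiffness_max, 5.0])
        res = _best_of(residual, starts, lower, upper, options)
        params = SchaperyParams(k_eq, res.x[0], res.x[1])
        pred = theta0 * (k_eq + res.x[0] * t ** (-res.x[1]))
    else:
        def residual(x):
            return theta0 * (x[0] + x[1] * t ** (-x[2])) - m

        starts = []
        for c2 in c2s:
            for k_frac in (0.5, 0.9):
                k0 = k_end * k_frac
                starts.append(np.array(
                    [k0, max((m0 / theta0 - k0) * t[0] ** c2, 1e-4), c2]))
        lower = np.array([0.0, 0.0, 0.0])
        upper = np.array([options.stiffness_max, options.stiffness_max, 5.0])
        res = _best_of(residual, starts, lower, upper, options)
        params = SchaperyParams(*res.x)
        pred = theta0 * (res.x[0] + res.x[1] * t ** (-res.x[2]))
    r2, rmse, sse = _quality(m, pred)
    return FitResult("schapery", params, r2, rmse, sse, bool(res.success), len(starts))


def _fit_msm(segment: RelaxationSegment, options: FitOptions,
             rng: np.random.Generator) -> FitResult:
    mask = segment.time >= options.power_t_min
    t, m = segment.time[mask], segment.moment[mask]
    theta0 = segment.theta0
    if len(t) < 2:
        raise ValueError("too few samples at t >= t_min for a power-law fit")

    starts = []
    if np.all(m > 0):  # log-linear regression gives a near-exact start
        slope, intercept = np.polyfit(np.log(t), np.log(m / theta0), 1)
        starts.append(np.array([math.exp(intercept), max(-slope, 1e-6)]))
    k0_0 = max(m[0] / theta0, 1e-4)
    for beta in np.exp(rng.uniform(math.log(0.005), math.log(1.0),
                                   options.n_starts - len(starts))):
        starts.append(np.array([k0_0, beta]))

    lower = np.array([1e-8, 0.0])
    upper = np.array([options.stiffness_max, 5.0])

    def residual(x):
        return theta0 * x[0] * t ** (-x[1]) - m

    res = _best_of(residual, starts, lower, upper, options)
    params = MSMParams(res.x[0], res.x[1])
    r2, rmse, sse = _quality(m, theta0 * res.x[0] * t ** (-res.x[1]))
    return FitResult("msm", params, r2, rmse, sse, bool(res.success), len(starts))


_FITTERS = {"sls": _fit_sls, "prony": _fit_prony,
            "schapery": _fit_schapery, "msm": _fit_msm}


def fit_relaxation(segment: RelaxationSegment, model_kind: str,
                   options: Optional[FitOptions] = None) -> FitResult:
    """Fit one model family to one relaxation segment.

    ``model_kind`` is one of ``sls``, ``prony``, ``schapery``, ``msm``;
    the Prony branch count comes from ``options.prony_n`` (default 2).
    """
    if model_kind not in _FITTERS:
        raise ValueError(f"unknown model kind {model_kind!r}; expected one of {MODEL_KINDS}")
    if options is None:
        options = FitOptions()
    if len(segment.time) < 2:
        raise ValueError("segment too short to fit")
    rng = np.random.default_rng(options.seed)
    return _FITTERS[model_kind](segment, options, rng)


def fit_many(segments: Sequence[RelaxationSegment],
             model_kinds: Sequence[str] = MODEL_KINDS,
             options: Optional[FitOptions] = None,
             labels: Optional[Sequence] = None) -> pd.DataFrame:
    """Fit every model to every segment; one tidy row per segment x model."""
    if options is None:
        options = FitOptions()
    rows = []
    for i, seg in enumerate(segments):
        label = labels[i] if labels is not None else i
        for kind in model_kinds:
            fr = fit_relaxation(seg, kind, options)
            rows.append({"segment": label, "model": kind, "r2": fr.r2,
                         "rmse": fr.rmse, "converged": fr.converged,
                         "theta0_deg": seg.theta0,
                         "params": fr.params})
    return pd.DataFrame(rows)


def compare_models(segments_by_group: Mapping[object, Sequence[RelaxationSegment]],
                   model_kinds: Sequence[str] = MODEL_KINDS,
                   options: Optional[FitOptions] = None) -> pd.DataFrame:
    """Mean fit quality per model per group (e.g. %FR exposure level).

    Empty groups are dropped.  Returns a tidy frame with columns
    ``group, model, n_trials, mean_r2, mean_rmse``.
    """
    rows = []
    for group, segments in segments_by_group.items():
        if not segments:
            continue
        fits = fit_many(segments, model_kinds, options)
        for kind in model_kinds:
            sub = fits[fits["model"] == kind]
            rows.append({"group": group, "model": kind, "n_trials": len(sub),
                         "mean_r2": float(sub["r2"].mean()),
                         "mean_rmse": float(sub["rmse"].mean())})
    return pd.DataFrame(rows)
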