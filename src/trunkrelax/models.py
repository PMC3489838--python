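"""Closed-form load-relaxation models for the flexed trunk.

All four models predict the passive trunk extension moment ``M(t)`` (Nm)
during a hold at a constant lumbar flexion angle ``theta0`` (deg), with time
``t`` (s) zeroed at the onset of the hold:

* Standard linear solid (SLS): a torsional spring in parallel with one
  Maxwell (spring + damper in series) branch,
  ``M(t) = theta0 * (k_parallel + k_maxwell * exp(-t / tau))``.
* Prony series (Wiechert model): a parallel spring plus ``n`` Maxwell
  branches, ``M(t) = theta0 * (k_inf + sum_i k_i * exp(-t / tau_i))``.
* Schapery-type power law, ``M(t) = theta0 * (k_eq + c1 * t**(-c2))``.
* Modified superposition (MSM) power law, ``M(t) = theta0 * k0 * t**(-beta)``.

Angles are degrees and stiffnesses Nm/deg throughout; no radian conversion
is performed anywhere in the package.  The power-law forms diverge at
``t = 0`` and are only defined for ``t >= POWER_LAW_T_MIN``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence, Tuple, Union

import numpy as np

__all__ = [
    "POWER_LAW_T_MIN",
    "SLSParams",
    "PronyParams",
    "SchaperyParams",
    "MSMParams",
    "ModelParams",
    "predict_sls",
    "predict_prony",
    "predict_schapery",
    "predict_msm",
    "predict",
    "params_to_json",
    "params_from_json",
]

#: Earliest time (s after hold onset) at which the power-law models are
#: evaluated or fit; both diverge as t -> 0.
POWER_LAW_T_MIN = 1.0


@dataclass(frozen=True)
class SLSParams:
    """Standard-linear-solid parameters.

    ``c_damper`` (Nm*s/deg) is stored as the primary viscous parameter; the
    relaxation time constant ``tau = c_damper / k_maxwell`` is derived.
    """

    k_maxwell: float  # Nm/deg, Maxwell-branch spring
    k_parallel: float  # Nm/deg, parallel (steady-state) spring
    c_damper: float  # Nm*s/deg, Maxwell-branch damper

    def __post_init__(self) -> None:
        if not (self.k_maxwell > 0 and self.k_parallel > 0 and self.c_damper > 0):
            raise ValueError("SLS parameters must be strictly positive")

    @property
    def tau(self) -> float:
        """Relaxation time constant (s)."""
        return self.c_damper / self.k_maxwell

    @classmethod
    def from_tau(cls, k_maxwell: float, k_parallel: float, tau: float) -> "SLSParams":
        return cls(k_maxwell=k_maxwell, k_parallel=k_parallel, c_damper=k_maxwell * tau)


@dataclass(frozen=True)
class PronyParams:
    """Prony-series (Wiechert) parameters: parallel spring ``k_inf`` plus
    ``(k_i, tau_i)`` Maxwell branches with time constants sorted ascending."""

    k_inf: float  # Nm/deg
    branches: Tuple[Tuple[float, float], ...]  # ((k_i Nm/deg, tau_i s), ...)

    def __post_init__(self) -> None:
        branches = tuple((float(k), float(tau)) for k, tau in self.branches)
        object.__setattr__(self, "branches", branches)
        if not self.k_inf > 0:
            raise ValueError("k_inf must be strictly positive")
        if not 1 <= len(branches) <= 4:
            raise ValueError("number of Maxwell branches must be between 1 and 4")
        taus = [tau for _, tau in branches]
        if any(k <= 0 or tau <= 0 for k, tau in branches):
            raise ValueError("branch stiffnesses and time constants must be positive")
        if any(t2 <= t1 for t1, t2 in zip(taus, taus[1:])):
            raise ValueError("branch time constants must be strictly increasing")

    @property
    def n(self) -> int:
        return len(self.branches)


@dataclass(frozen=True)
class SchaperyParams:
    """Schapery-type power-law parameters: equilibrium stiffness ``k_eq``
    (Nm/deg) plus fitted constants ``c1`` (Nm/deg*s^c2) and ``c2`` (-)."""

    k_eq: float
    c1: float
    c2: float

    def __post_init__(self) -> None:
        if self.k_eq < 0 or self.c1 < 0 or self.c2 < 0:
            raise ValueError("Schapery parameters must be non-negative")


@dataclass(frozen=True)
class MSMParams:
    """Modified-superposition power-law parameters: stiffness ``k0``
    (Nm/deg) at the start of relaxation and initial relaxation rate
    ``beta`` (-)."""

    k0: float
    beta: float

    def __post_init__(self) -> None:
        if not self.k0 > 0:
            raise ValueError("k0 must be strictly positive")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")


ModelParams = Union[SLSParams, PronyParams, SchaperyParams, MSMParams]

_KIND_BY_TYPE = {
    SLSParams: "sls",
    PronyParams: "prony",
    SchaperyParams: "schapery",
    MSMParams: "msm",
}


def _check_time(t: np.ndarray, t_min: float) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < t_min):
        raise ValueError(f"time values must be >= {t_min} s")
    return t


def _check_theta0(theta0: float) -> float:
    theta0 = float(theta0)
    if theta0 <= 0:
        raise ValueError("theta0 must be strictly positive")
    return theta0


def predict_sls(t, theta0: float, p: SLSParams) -> np.ndarray:
    """SLS relaxation moment at constant hold angle ``theta0``."""
    t = _check_time(t, 0.0)
    theta0 = _check_theta0(theta0)
    return theta0 * (p.k_parallel + p.k_maxwell * np.exp(-t / p.tau))


def predict_prony(t, theta0: float, p: PronyParams) -> np.ndarray:
    """Prony-series relaxation moment at constant hold angle ``theta0``."""
    t = _check_time(t, 0.0)
    theta0 = _check_theta0(theta0)
    stiff = np.full_like(t, p.k_inf, dtype=float)
    for k_i, tau_i in p.branches:
        stiff = stiff + k_i * np.exp(-t / tau_i)
    return theta0 * stiff


def predict_schapery(t, theta0: float, p: SchaperyParams,
                     t_min: float = POWER_LAW_T_MIN) -> np.ndarray:
    """Schapery-type power-law relaxation moment; requires ``t >= t_min``."""
    t = _check_time(t, t_min)
    theta0 = _check_theta0(theta0)
    return theta0 * (p.k_eq + p.c1 * t ** (-p.c2))


def predict_msm(t, theta0: float, p: MSMParams,
                t_min: float = POWER_LAW_T_MIN) -> np.ndarray:
    """Modified-superposition power-law relaxation moment; ``t >= t_min``."""
    t = _check_time(t, t_min)
    theta0 = _check_theta0(theta0)
    return theta0 * p.k0 * t ** (-p.beta)


def predict(t, theta0: float, params: ModelParams) -> np.ndarray:
    """Dispatch on the parameter type."""
    if isinstance(params, SLSParams):
        return predict_sls(t, theta0, params)
    if isinstance(params, PronyParams):
        return predict_prony(t, theta0, params)
    if isinstance(params, SchaperyParams):
        return predict_schapery(t, theta0, params)
    if isinstance(params, MSMParams):
        return predict_msm(t, theta0, params)
    raise TypeError(f"unknown parameter type: {type(params)!r}")


def model_kind(params: ModelParams) -> str:
    return _KIND_BY_TYPE[type(params)]


# -- JSON round trip with explicit unit strings ------------------------------

_UNITS = {
    "sls": {"k_maxwell": "Nm/deg", "k_parallel": "Nm/deg", "c_damper": "Nm*s/deg"},
    "prony": {"k_inf": "Nm/deg", "branch_k": "Nm/deg", "branch_tau": "s"},
    "schapery": {"k_eq": "Nm/deg", "c1": "Nm/deg*s^c2", "c2": "-"},
    "msm": {"k0": "Nm/deg", "beta": "-"},
}


def params_to_dict(params: ModelParams) -> dict:
    kind = model_kind(params)
    d: dict = {"model_kind": kind, "units": _UNITS[kind]}
    if isinstance(params, PronyParams):
        d["k_inf"] = params.k_inf
        d["branches"] = [list(b) for b in params.branches]
    else:
        for name in params.__dataclass_fields__:
            d[name] = getattr(params, name)
    return d


def params_from_dict(d: dict) -> ModelParams:
    kind = d["model_kind"]
    if kind == "sls":
        return SLSParams(d["k_maxwell"], d["k_parallel"], d["c_damper"])
    if kind == "prony":
        return PronyParams(d["k_inf"], tuple(tuple(b) for b in d["branches"]))
    if kind == "schapery":
        return SchaperyParams(d["k_eq"], d["c1"], d["c2"])
    if kind == "msm":
        return MSMParams(d["k0"], d["beta"])
    raise ValueError(f"unknown model kind: {kind!r}")


def params_to_json(params: ModelParams) -> str:
    return json.dumps(params_to_dict(params), indent=2, sort_keys=True)


def params_from_json(text: str) -> ModelParams:
    return params_from_dict(json.loads(text))
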