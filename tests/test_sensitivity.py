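"""Dimensionless sensitivity coefficients and angle-trend fits."""

import math

import numpy as np
import pytest

from trunkrelax.models import PronyParams, SchaperyParams, SLSParams
from trunkrelax.sensitivity import (SensitivitySpec, fit_angle_trend,
                                    model_outcome, sensitivity_coefficient,
                                    sensitivity_table, set_param)

SLS_NOM = SLSParams.from_tau(0.5, 1.0, 100.0)
PRONY_NOM = PronyParams(0.34, ((0.23, 8.8), (0.36, 1704.5)))


class TestAnalyticZeros:
    """Initial moment of a Kelvin solid is M(0) = theta0 * (sum of
    stiffnesses): exactly independent of every viscous parameter."""

    @pytest.mark.parametrize("params, pid, rng", [
        (PRONY_NOM, "tau_1", (4.0, 20.0)),
        (PRONY_NOM, "tau_2", (600.0, 3000.0)),
        (SLS_NOM, "c_damper", (20.0, 90.0)),
        (PronyParams(1.3, ((0.5, 2.0), (0.4, 50.0), (0.3, 900.0))),
         "tau_3", (500.0, 2000.0)),
    ])
    def test_time_constants_do_not_move_initial_moment(self, params, pid, rng):
        spec = SensitivitySpec(params, pid, "initial_moment", rng,
                               theta0=58.0, horizon=960.0)
        res = sensitivity_coefficient(spec)
        assert res.sc == 0.0
        assert res.delta_r == 0.0

    def test_sls_parallel_stiffness_drop_zero(self):
        """The parallel spring contributes equally to M(0) and M(horizon),
        so it cancels exactly from the moment drop."""
        spec = SensitivitySpec(SLS_NOM, "k_parallel", "moment_drop",
                               (0.5, 1.5), theta0=10.0, horizon=960.0)
        assert sensitivity_coefficient(spec).sc == 0.0


def test_sls_maxwell_stiffness_drop_matches_direct_evaluation():
    """Check against a hand computation: with c fixed, sweeping K1 changes
    both the amplitude and the rate (tau = c/K1) of the drop."""
    theta0, horizon, c = 10.0, 960.0, 50.0
    low, high, nom = 0.25, 0.75, 0.5

    def drop(k1):
        return theta0 * k1 * (1.0 - math.exp(-horizon * k1 / c))

    expected_delta = abs(drop(high) - drop(low))
    expected_sc = (expected_delta / drop(nom)) / ((high - low) / nom)
    spec = SensitivitySpec(SLS_NOM, "k_maxwell", "moment_drop", (low, high),
                           theta0=theta0, horizon=horizon)
    res = sensitivity_coefficient(spec)
    assert res.delta_r == pytest.approx(expected_delta, rel=1e-12)
    assert res.sc == pytest.approx(expected_sc, rel=1e-12)


def test_dimensionless_under_unit_change():
    """Re-expressing stiffness per radian (and the hold angle in radians)
    leaves the coefficient unchanged — sc is genuinely dimensionless."""
    deg2rad = math.pi / 180.0
    spec_deg = SensitivitySpec(SLS_NOM, "k_maxwell", "moment_drop",
                               (0.25, 0.75), theta0=10.0, horizon=960.0)
    nom_rad = SLSParams(SLS_NOM.k_maxwell / deg2rad,
                        SLS_NOM.k_parallel / deg2rad,
                        SLS_NOM.c_damper / deg2rad)
    spec_rad = SensitivitySpec(nom_rad, "k_maxwell",
                               "moment_drop",
                               (0.25 / deg2rad, 0.75 / deg2rad),
                               theta0=10.0 * deg2rad, horizon=960.0)
    a = sensitivity_coefficient(spec_deg)
    b = sensitivity_coefficient(spec_rad)
    assert a.sc == pytest.approx(b.sc, rel=1e-12)


def test_power_law_outcomes_evaluated_from_one_second():
    p = SchaperyParams(k_eq=1.0, c1=0.5, c2=0.3)
    assert model_outcome(p, "initial_moment", 10.0, 960.0) == pytest.approx(15.0)
    spec = SensitivitySpec(p, "c2", "initial_moment", (0.1, 0.5),
                           theta0=10.0, horizon=960.0)
    # at t = 1 s the power term is c1 regardless of c2: exact zero again
    assert sensitivity_coefficient(spec).sc == 0.0


def test_zero_nominal_outcome_flagged():
    p = SchaperyParams(k_eq=0.0, c1=0.0, c2=0.3)
    spec = SensitivitySpec(p, "c2", "initial_moment", (0.1, 0.5),
                           theta0=10.0, horizon=960.0)
    res = sensitivity_coefficient(spec)
    assert not res.defined and math.isnan(res.sc)


def test_sensitivity_table_layout():
    table = sensitivity_table(SLS_NOM,
                              {"k_maxwell": (0.25, 0.75),
                               "k_parallel": (0.5, 1.5),
                               "c_damper": (20.0, 90.0)},
                              theta0=10.0, horizon=960.0)
    t = table.set_index("param")
    assert list(table.columns[:2]) == ["model", "param"]
    assert t.loc["c_damper", "sc_initial"] == 0.0
    assert t.loc["k_parallel", "sc_drop"] == 0.0
    assert t.loc["k_maxwell", "sc_initial"] > 0


class TestTrendFits:
    X = np.array([30.0, 40.0, 60.0, 80.0, 100.0])

    def test_exponential_through_origin_exact_recovery(self):
        y = 2.0 * (np.exp(0.03 * self.X) - 1.0)
        fit = fit_angle_trend(self.X, y, "exponential_through_origin",
                              include_origin=True)
        assert fit.coefficients["a"] == pytest.approx(2.0, rel=1e-6)
        assert fit.coefficients["b"] == pytest.approx(0.03, rel=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_plain_exponential_exact_recovery(self):
        y = 1.5 * np.exp(0.02 * self.X)
        fit = fit_angle_trend(self.X, y, "exponential")
        assert fit.coefficients["a"] == pytest.approx(1.5, rel=1e-6)
        assert fit.coefficients["b"] == pytest.approx(0.02, rel=1e-6)

    def test_constant_data_degenerate(self):
        y = np.full_like(self.X, 4.0)
        lin = fit_angle_trend(self.X, y, "linear")
        assert lin.coefficients["slope"] == pytest.approx(0.0, abs=1e-12)
        exp = fit_angle_trend(self.X, y, "exponential")
        assert exp.degenerate

    def test_non_finite_rejected(self):
        y = np.array([1.0, np.nan, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError):
            fit_angle_trend(self.X, y, "linear")

    def test_exponential_beats_linear_on_curved_cohort_means(self):
        """Cohort means produced by the generator's exponential stiffness
        gain are better described by the through-origin exponential."""
        from trunkrelax.preprocess import (resample_align, segment_phases,
                                           summarize_relaxation)
        from trunkrelax.synthetic import (ProtocolSpec, default_truth,
                                          generate_trial)
        fractions = (0.3, 0.4, 0.6, 0.8, 1.0)
        means = []
        for frac in fractions:
            proto = ProtocolSpec(target_fraction_fr=frac, fr_angle=58.2,
                                 hold_duration=30.0)
            trial = generate_trial(proto, default_truth(), seed=21)
            al = resample_align(trial)
            s = summarize_relaxation(al, segment_phases(al))
            means.append(s.initial_moment)
        x = 100.0 * np.asarray(fractions)
        lin = fit_angle_trend(x, np.array(means), "linear", include_origin=True)
        exp = fit_angle_trend(x, np.array(means), "exponential_through_origin",
                              include_origin=True)
        assert exp.r2 > lin.r2
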