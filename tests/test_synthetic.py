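"""Synthetic-trial generator and hereditary-integral oracle."""

import numpy as np
import pytest

from trunkrelax.models import PronyParams, SLSParams, predict_prony, predict_sls
from trunkrelax.preprocess import resample_align, segment_phases, summarize_relaxation
from trunkrelax.synthetic import (GroundTruthSpec, ProtocolSpec, default_truth,
                                  draw_fr_angles, generate_cohort,
                                  generate_trial, trapezoid_profile,
                                  truth_moment)
from conftest import make_noiseless_truth


class TestTruthMoment:
    def test_step_matches_sls_closed_form(self, sls_params):
        truth = make_noiseless_truth(sls_params)
        t = np.arange(0.0, 600.0, 0.01)
        m = truth_moment(truth, t, np.full_like(t, 10.0))
        expected = predict_sls(t, 10.0, sls_params)
        np.testing.assert_allclose(m, expected, rtol=1e-6)

    def test_step_matches_prony_closed_form(self, prony_params):
        truth = make_noiseless_truth(prony_params)
        t = np.arange(0.0, 600.0, 0.01)
        m = truth_moment(truth, t, np.full_like(t, 25.0))
        np.testing.assert_allclose(m, predict_prony(t, 25.0, prony_params),
                                   rtol=1e-6)

    def test_zero_angle_gives_zero_moment(self, prony_params):
        truth = make_noiseless_truth(prony_params)
        t = np.arange(0.0, 10.0, 0.01)
        assert np.all(truth_moment(truth, t, np.zeros_like(t)) == 0.0)

    def test_elastic_limit_loading_equals_unloading(self):
        # vanishing Maxwell stiffness -> pure parallel spring: the moment is
        # a function of angle only, so the triangular loop closes exactly
        params = PronyParams(k_inf=1.0, branches=((1e-12, 10.0),))
        truth = make_noiseless_truth(params)
        t = np.arange(0.0, 20.0, 0.01)
        angle = np.minimum(3.0 * t, 3.0 * (t[-1] - t))
        m = truth_moment(truth, t, angle)
        peak = np.argmax(angle)
        up = np.interp(np.linspace(0, 29, 100), angle[:peak + 1], m[:peak + 1])
        down = np.interp(np.linspace(0, 29, 100), angle[-1:peak - 1:-1],
                         m[-1:peak - 1:-1])
        np.testing.assert_allclose(up, down, atol=1e-9)

    def test_grid_halving_converges(self, prony_params):
        """Ramp-and-hold history: refining the time grid barely moves the
        hereditary integral (the recursion is exact for piecewise-linear
        angle histories)."""
        truth = make_noiseless_truth(prony_params)
        protocol = ProtocolSpec(target_fraction_fr=1.0, fr_angle=30.0,
                                hold_duration=60.0)
        t1 = np.arange(0.0, 80.0, 0.02)
        t2 = np.arange(0.0, 80.0, 0.01)
        m1 = truth_moment(truth, t1, trapezoid_profile(t1, protocol))
        m2 = truth_moment(truth, t2, trapezoid_profile(t2, protocol))
        scale = m2.max()
        np.testing.assert_allclose(m1, m2[::2], atol=1e-4 * scale)

    def test_rejects_non_uniform_grid(self, sls_params):
        truth = make_noiseless_truth(sls_params)
        t = np.array([0.0, 0.1, 0.3, 0.35])
        with pytest.raises(ValueError, match="uniform"):
            truth_moment(truth, t, np.full_like(t, 5.0))

    def test_rejects_power_law_truth(self):
        from trunkrelax.models import MSMParams
        with pytest.raises(ValueError, match="Kelvin"):
            GroundTruthSpec(params=MSMParams(1.0, 0.05))


class TestGenerateTrial:
    PROTO = ProtocolSpec(target_fraction_fr=0.6, fr_angle=58.2,
                         hold_duration=60.0)

    def test_seed_determinism(self):
        truth = default_truth()
        a = generate_trial(self.PROTO, truth, seed=1)
        b = generate_trial(self.PROTO, truth, seed=1)
        np.testing.assert_array_equal(a.angle, b.angle)
        np.testing.assert_array_equal(a.force, b.force)

    def test_recording_timing(self):
        trial = generate_trial(self.PROTO, default_truth(), seed=2)
        expected = 2 * self.PROTO.ramp_duration + 60.0
        assert trial.angle_time[-1] == pytest.approx(expected, abs=1 / 100)
        assert trial.force_time[-1] == pytest.approx(expected, abs=1 / 1000)
        assert len(trial.force) == pytest.approx(10 * len(trial.angle), abs=10)

    def test_noiseless_hold_matches_closed_form(self, sls_params):
        """During the hold the generated moment follows the constant-angle
        closed form driven by the effective (NZ-reduced, angle-gained)
        deformation."""
        truth = make_noiseless_truth(sls_params)
        trial = generate_trial(self.PROTO, truth, seed=0)
        theta0 = self.PROTO.hold_angle
        t_hold0 = self.PROTO.ramp_duration
        mask = (trial.force_time >= t_hold0 + 200.0)  # past ramp transients
        t_rel = trial.force_time[mask] - t_hold0
        moment = trial.force[mask] * self.PROTO.moment_arm
        expected = predict_sls(t_rel, theta0, sls_params)
        np.testing.assert_allclose(moment, expected, rtol=2e-2)

    def test_hold_angle_inside_nz_rejected(self):
        proto = ProtocolSpec(target_fraction_fr=0.15, fr_angle=58.2,
                             hold_duration=60.0)
        with pytest.raises(ValueError, match="neutral zone"):
            generate_trial(proto, default_truth(), seed=0)


class TestCohort:
    def test_trial_count(self):
        trials = generate_cohort(3, (0.6, 1.0), seed=1,
                                 protocol_template=ProtocolSpec(
                                     target_fraction_fr=1.0, hold_duration=30.0))
        assert len(trials) == 6
        assert [t.metadata["subject"] for t in trials] == [0, 0, 1, 1, 2, 2]

    def test_fr_sd_zero_degenerate(self):
        rng = np.random.default_rng(0)
        fr = draw_fr_angles(5, rng, mean=58.2, sd=0.0)
        np.testing.assert_array_equal(fr, 58.2)

    def test_empty_fractions_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(2, (), seed=0)

    def test_mean_initial_moment_increases_with_fraction(self):
        """Exponential stiffness-angle gain makes cohort-mean initial moment
        strictly increasing across the five exposure levels."""
        truth = default_truth(force_noise_sd=0.0, angle_noise_sd=0.0)
        proto = ProtocolSpec(target_fraction_fr=1.0, hold_duration=30.0)
        trials = generate_cohort(3, (0.3, 0.4, 0.6, 0.8, 1.0), truth, seed=5,
                                 protocol_template=proto, fr_sd=0.0)
        by_frac = {}
        for trial in trials:
            al = resample_align(trial)
            seg = segment_phases(al)
            s = summarize_relaxation(al, seg, window_s=3.0)
            frac = trial.metadata["target_fraction_fr"]
            by_frac.setdefault(frac, []).append(s.initial_moment)
        means = [np.mean(by_frac[f]) for f in sorted(by_frac)]
        assert np.all(np.diff(means) > 0)


def test_two_phase_relaxation_property():
    """Default ground truth exhibits distinct fast and slow phases: at least
    30% of the total hold-phase moment drop happens in the first 60 s."""
    proto = ProtocolSpec(target_fraction_fr=1.0, fr_angle=58.2,
                         hold_duration=960.0)
    trial = generate_trial(proto, default_truth(force_noise_sd=0.0,
                                                angle_noise_sd=0.0), seed=3)
    t0 = proto.ramp_duration
    t = trial.force_time
    m = trial.force * proto.moment_arm
    m_start = m[np.searchsorted(t, t0)]
    m_60 = m[np.searchsorted(t, t0 + 60.0)]
    m_end = m[np.searchsorted(t, t0 + 960.0) - 1]
    total_drop = m_start - m_end
    assert total_drop > 0
    assert (m_start - m_60) / total_drop >= 0.30
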