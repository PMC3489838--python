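"""Shared fixtures: canonical parameter sets and small synthetic trials.

Expensive artifacts (full-protocol trials, cohorts) are session-scoped;
everything is seeded so the suite is deterministic.
"""

import numpy as np
import pytest

from trunkrelax.models import PronyParams, SLSParams
from trunkrelax.preprocess import resample_align, segment_phases
from trunkrelax.synthetic import (GroundTruthSpec, ProtocolSpec, default_truth,
                                  generate_trial)


@pytest.fixture(scope="session")
def sls_params():
    """Canonical SLS set: K1 = 0.5, K2 = 1.0 Nm/deg, tau = 100 s."""
    return SLSParams.from_tau(k_maxwell=0.5, k_parallel=1.0, tau=100.0)


@pytest.fixture(scope="session")
def prony_params():
    """Two-branch Prony set with fast (10 s) and slow (1000 s) phases."""
    return PronyParams(k_inf=1.0, branches=((0.3, 10.0), (0.2, 1000.0)))


def make_noiseless_truth(params, nz_width=0.0):
    return GroundTruthSpec(params=params, nz_width=nz_width,
                           stiffness_angle_gain=0.0,
                           force_noise_sd=0.0, angle_noise_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_sls_truth(sls_params):
    return make_noiseless_truth(sls_params)


@pytest.fixture(scope="session")
def sls_full_trial(noiseless_sls_truth):
    """Noise-free full protocol: ramp to 10 deg at 3 deg/s, 960-s hold."""
    protocol = ProtocolSpec(target_fraction_fr=1.0, fr_angle=10.0,
                            hold_duration=960.0)
    return generate_trial(protocol, noiseless_sls_truth, seed=0)


@pytest.fixture(scope="session")
def sls_full_aligned(sls_full_trial):
    aligned = resample_align(sls_full_trial)
    seg = segment_phases(aligned)
    return aligned, seg


@pytest.fixture(scope="session")
def noisy_trial():
    """Default-noise trial at 60% FR with a short (120 s) hold."""
    protocol = ProtocolSpec(target_fraction_fr=0.6, fr_angle=58.2,
                            hold_duration=120.0)
    return generate_trial(protocol, default_truth(), seed=7)
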