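"""Shared fixtures: reference ground-truth models and simulated sessions.

Full-protocol simulations (10 x 10 s at 10 kHz) are the costly part of
the suite, so they are module- or session-scoped and shared wherever the
same conditions apply.
"""

import dataclasses

import numpy as np
import pytest

from sacsyn.synthetic import reference_models, simulate_wn_session
from sacsyn.traces import SampledTrace, StimulusProtocol


@pytest.fixture(scope="session")
def ref_models():
    return reference_models(seed=0)


@pytest.fixture(scope="session")
def small_protocol():
    """Reduced protocol for cheap structural tests (4 x 4 s at 2 kHz)."""
    return StimulusProtocol(
        n_trials=4,
        trial_duration_s=4.0,
        unique_duration_s=3.0,
        repeat_duration_s=1.0,
        cutoff_hz=30.0,
        sample_rate_hz=2000.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def dsgc_session(ref_models):
    dsgc, _ = ref_models
    session, truth = simulate_wn_session(
        dataclasses.replace(dsgc, seed=3), StimulusProtocol(seed=3)
    )
    return session, truth


@pytest.fixture(scope="session")
def sac_session(ref_models):
    _, sac = ref_models
    session, truth = simulate_wn_session(
        dataclasses.replace(sac, seed=3), StimulusProtocol(seed=3)
    )
    return session, truth


def make_trace(values, dt=1e-4, units="pA"):
    return SampledTrace(np.asarray(values, float), dt, 0.0, units)
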