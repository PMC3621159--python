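"""Shared fixtures: one reference subject simulated once per session."""

import warnings

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from cvsid import CirculationParams, steady_state_beat
from cvsid.features import extract_setpoints

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

warnings.filterwarnings("ignore", message="lsoda")


@pytest.fixture(scope="session")
def default_params() -> CirculationParams:
    return CirculationParams()


@pytest.fixture(scope="session")
def truth_beat(default_params):
    """Periodic steady-state beat of the default closed-loop model."""
    beat = steady_state_beat(default_params)
    assert beat.meta["converged"]
    return beat


@pytest.fixture(scope="session")
def truth_setpoints(truth_beat):
    return extract_setpoints(truth_beat)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20261001)
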