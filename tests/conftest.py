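import warnings

import numpy as np
import pytest

from thermorun.cohort import reference_cohort
from thermorun.synthdata import SceneConfig, PhysioParams, generate_session
from thermorun.physio import build_protocol

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def cohort11():
    return reference_cohort()


@pytest.fixture(scope="session")
def noiseless_params():
    """Physiology with every stochastic term switched off (pure dynamics)."""
    return PhysioParams(noise_hr=0.0, noise_vo2=0.0, noise_tcore=0.0, ou_sigma=0.0)


@pytest.fixture(scope="session")
def protocol_t1():
    return build_protocol("T1", 12.2)


@pytest.fixture(scope="session")
def short_session():
    """A 5-min T1 session at default noise (shared across tests)."""
    return generate_session("T1", seed=11, duration=300.0)


@pytest.fixture(scope="session")
def full_session_t1():
    """A full 49-min T1 session at default noise (shared across tests)."""
    return generate_session("T1", seed=5)
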