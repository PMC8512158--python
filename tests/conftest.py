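import warnings

import numpy as np
import pytest

from myobelt.calibration import BELT_CURVE
from myobelt.simulate import SimulationConfig, concat_sessions, generate_session


@pytest.fixture(scope="session")
def belt_curve():
    return BELT_CURVE


@pytest.fixture(scope="session")
def walk_session():
    """Short walking session with ground truth, shared across tests."""
    return generate_session(SimulationConfig(condition="walk", n_cycles=8, seed=0))


@pytest.fixture(scope="session")
def protocol_session_factory():
    """Sessions mirroring the model-evaluation protocol: a block of maximal
    seated co-contractions followed by squats (~60 s at 1 kHz)."""

    def make(seed: int, noise_sd: float = 1.8):
        a = generate_session(SimulationConfig(
            condition="cocontraction_sitting", n_cycles=4,
            circumference_noise_sd_mm=noise_sd, seed=seed))
        b = generate_session(SimulationConfig(
            condition="squat", n_cycles=10,
            circumference_noise_sd_mm=noise_sd, seed=seed + 7919))
        return concat_sessions(a, b)

    return make


@pytest.fixture(autouse=True)
def _quiet_extrapolation_warnings():
    """Sessions with 1.8 mm circumference noise routinely dip below the
    calibration sweep's lower edge; the extrapolation warning is expected."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*outside the calibration range.*")
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
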