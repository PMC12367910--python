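import numpy as np
import pytest

from rphmri.calibration import reconstructed_sensor_calibration
from rphmri.phantom import make_phantom, simulate_session


@pytest.fixture(scope="session")
def sensor_cal():
    return reconstructed_sensor_calibration()


@pytest.fixture(scope="session")
def small_phantom():
    """A compact tumor phantom for fast unit tests."""
    return make_phantom(shape=(24, 32, 6), tumor_semiaxes=(7.0, 9.0, 2.0))


@pytest.fixture(scope="session")
def noiseless_session(small_phantom):
    return simulate_session(small_phantom, noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def noisy_session(small_phantom):
    return simulate_session(small_phantom, baseline_snr=50.0, seed=1)
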