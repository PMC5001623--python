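import numpy as np
import pytest

from mlgoc.goc import GOCParams, build_interaction_kernel, calibrate_for_radius
from mlgoc.intensity import ImageFormationParams

_CAL_CACHE: dict = {}


def calibrated(r_hat: float) -> GOCParams:
    """Session-wide cache: numeric calibration is ~seconds per radius."""
    if r_hat not in _CAL_CACHE:
        _CAL_CACHE[r_hat] = calibrate_for_radius(r_hat)
    return _CAL_CACHE[r_hat]


@pytest.fixture(scope="session")
def goc15() -> GOCParams:
    return calibrated(15.0)


@pytest.fixture(scope="session")
def kernel15(goc15):
    return build_interaction_kernel(goc15.d, goc15.epsilon)


@pytest.fixture(scope="session")
def small_goc() -> GOCParams:
    """Uncalibrated small-range parameters for cheap gradient checks."""
    return GOCParams(D=1.0, lambda_f=1.0, alpha_f=0.3, beta_f=0.2, d=5.0, epsilon=2.5, r_hat=5.0)


@pytest.fixture(scope="session")
def small_kernel(small_goc):
    return build_interaction_kernel(small_goc.d, small_goc.epsilon)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def imaging_basic() -> ImageFormationParams:
    return ImageFormationParams(mu_minus=40.0, sigma2_minus=25.0, delta_mu=60.0, delta_sigma2=24.0)
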