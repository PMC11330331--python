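import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

from prepscore import (
    CavityParams,
    ToothParams,
    carve_cavity,
    default_landmarks,
    generate_tooth,
)

# coarse parameters keep the registration tests fast; the measurement
# fixtures use the full default resolution (8 vertices/mm)
COARSE = ToothParams(resolution=4.0)
FINE = ToothParams()


@pytest.fixture(scope="session")
def coarse_params():
    return COARSE


@pytest.fixture(scope="session")
def fine_params():
    return FINE


@pytest.fixture(scope="session")
def coarse_reference():
    return generate_tooth(COARSE)


@pytest.fixture(scope="session")
def fine_reference():
    return generate_tooth(FINE)


@pytest.fixture(scope="session")
def fine_prepared_ideal(fine_reference):
    """Ideally prepared tooth (1.50 mm deep, 1.25 mm wide channel), already
    in the reference frame, with its analytic ground truth."""
    return carve_cavity(fine_reference, CavityParams(), FINE)


@pytest.fixture(scope="session")
def landmarks():
    return default_landmarks(FINE, CavityParams())


@pytest.fixture(scope="session")
def coarse_landmarks():
    return default_landmarks(COARSE, CavityParams())


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
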