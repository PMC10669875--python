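import numpy as np
import pytest

from crosshairsim import FixtureConfig, build_calibration_sphere, build_rig, make_fixture


@pytest.fixture(scope="session")
def small_fixture():
    """Coarse head fixture (subdivision 3) for fast deployment tests."""
    return make_fixture(FixtureConfig(subdivisions=3), seed=3)


@pytest.fixture(scope="session")
def default_fixture():
    """Default-resolution head fixture used by the end-to-end checks."""
    return make_fixture(seed=3)


@pytest.fixture(scope="session")
def nominal_rig():
    return build_rig()


@pytest.fixture(scope="session")
def sphere():
    return build_calibration_sphere()


@pytest.fixture()
def rng():
    return np.random.default_rng(20231107)
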