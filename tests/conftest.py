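import numpy as np
import pytest

from retisim.eye_iol import packaged_eye
from retisim.scene import SpectralSamplingPlan


@pytest.fixture(scope="session")
def d65_plan():
    return SpectralSamplingPlan.d65()


@pytest.fixture(scope="session")
def mono_eye():
    """Packaged monofocal pseudophakic eye, 3 mm pupil."""
    return packaged_eye("monofocal", 3.0)


@pytest.fixture(scope="session")
def plateau_eye():
    return packaged_eye("plateau-edof", 3.0)


@pytest.fixture(scope="session")
def zonal_eye():
    return packaged_eye("zonal-sa-edof", 3.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
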