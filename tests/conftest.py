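import numpy as np
import pytest

from hypercsi.core import AcquisitionProtocol, default_peaks
from hypercsi.phantom import make_brain_phantom


@pytest.fixture(scope="session")
def protocol():
    return AcquisitionProtocol()


@pytest.fixture(scope="session")
def peaks():
    return default_peaks()


@pytest.fixture(scope="session")
def phantom64():
    """Default 64-grid phantom with the pre-treatment ratio targets."""
    return make_brain_phantom(seed=1, grid=64,
                              target_ratios={"lactate/pyruvate": 0.256,
                                             "bicarbonate/pyruvate": 0.138})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
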