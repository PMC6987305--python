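import numpy as np
import pytest

from inexa import CultureGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def geometry():
    return CultureGeometry()


@pytest.fixture
def small_geometry():
    # shrunken culture for fast network-construction tests
    return CultureGeometry(extent=(300.0, 300.0, 10.0))
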