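import numpy as np
import pytest

from nascentfold import Protocol, table1_presets


@pytest.fixture(scope="session")
def presets():
    return table1_presets()


@pytest.fixture(scope="session")
def delta_c(presets):
    """SFVP dC construct and its uniform 3.9 AA/s schedule."""
    return presets["SFVP_dC"]


@pytest.fixture(scope="session")
def protocol():
    """Default 45 s pulse / 360 s chase / 10 s delay protocol."""
    return Protocol()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
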