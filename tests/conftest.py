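import numpy as np
import pytest

import tdfe

#: desk-scale study conditions: same signal strength and sample grid as the
#: full benchmark, fewer null features so unit tests stay fast
SMALL = tdfe.SyntheticConfig(n_features=4000, n_signal=40, seed=11)


@pytest.fixture(scope="session")
def small_config():
    return SMALL


@pytest.fixture(scope="session")
def small_tensor():
    return tdfe.generate_synthetic(SMALL)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
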