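import numpy as np
import pytest

from xhpi import io as xio


@pytest.fixture(scope="session")
def toy_params():
    return xio.load_toy_params()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
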