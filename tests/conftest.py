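import numpy as np
import pytest

from paoximetry.phantom import make_fixture
from paoximetry.unmixing import default_extinction_table


@pytest.fixture(scope="session")
def ext():
    return default_extinction_table()


@pytest.fixture(scope="session")
def hfr_small():
    """Compact HFR recording: full 30-min protocol on a 96x96 grid.

    96 px keeps the tumor clear of the 20x20 noise-floor corner patches.
    """
    return make_fixture("HFR", seed=1, shape=(96, 96))


@pytest.fixture(scope="session")
def lfr_small():
    return make_fixture("LFR", seed=1, shape=(96, 96))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
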