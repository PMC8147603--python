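import numpy as np
import pytest

from beemito.repeat_typing import default_library
from beemito.synthetic_data import SimConfig, simulate


@pytest.fixture(scope="session")
def lib():
    return default_library()


@pytest.fixture(scope="session")
def study(lib):
    """One full synthetic study at the default conditions (444 bees, 17 kin pairs)."""
    return simulate(SimConfig(seed=11), lib)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
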