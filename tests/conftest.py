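import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")

from pahmix.pbpk import load_config
from pahmix.refdata import MICROSOMAL_BASELINE


@pytest.fixture(scope="session")
def bap_spec():
    return MICROSOMAL_BASELINE["BaP"]


@pytest.fixture(scope="session")
def dbc_spec():
    return MICROSOMAL_BASELINE["DBC"]


@pytest.fixture(scope="session")
def pbpk_defaults():
    phys, compounds = load_config()
    return phys, compounds


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
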