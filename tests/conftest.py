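import numpy as np
import pytest
from hypothesis import settings

from rcflow.model import PRESETS, RateParameters

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def pool_scan() -> RateParameters:
    """Donor-pool titration parameter set (pufC-like, p = 0.3)."""
    return PRESETS["pool_scan"]


@pytest.fixture(scope="session")
def qa_redox() -> RateParameters:
    """Parameter set for the QA- rise/decay kinetics (pool = 2)."""
    return PRESETS["qa_redox"]


@pytest.fixture(scope="session")
def grid_xp():
    """(x, p) evaluation grid for yield-map identities."""
    x = np.linspace(0.0, 1.0, 21)
    p = np.array([0.0, 0.1, 0.22, 0.3, 0.5, 0.8, 0.95])
    return x, p
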