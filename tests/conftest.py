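import numpy as np
import pytest

from letfoci import A549_LET_LAWS, HTERT_UNHIT_LAW, GeneratorConfig


@pytest.fixture
def laws():
    """The linear mu/sigma-vs-LET laws for A549 monoenergetic data."""
    return A549_LET_LAWS


@pytest.fixture
def unhit_law():
    """The quadratic unhit law for 1BR hTERT occupancy data."""
    return HTERT_UNHIT_LAW


@pytest.fixture
def config():
    """Default study conditions with a fixed seed."""
    return GeneratorConfig(seed=1234)


@pytest.fixture
def rng():
    return np.random.default_rng(98765)


LET_PANEL = (13.0, 20.0, 40.0, 60.0, 80.0, 100.0)
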