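import numpy as np
import pytest

from aphidtrack.core import ArenaGeometry
from aphidtrack.probes import M_PERSICAE, N_RIBISNIGRI


@pytest.fixture
def arena():
    return ArenaGeometry()


@pytest.fixture
def profile():
    return M_PERSICAE


@pytest.fixture
def rng():
    return np.random.default_rng(0)
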