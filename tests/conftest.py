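import numpy as np
import pytest

from avatumor.fields import DomainGrid


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def small_grid():
    """Tiny 2-D grid for field tests (21x21 over 0.02 cm)."""
    return DomainGrid(extent=0.02, nodes=21, dim=2)


@pytest.fixture
def box_grid():
    """Rectangular grid without the circular mask (boundary = array edge)."""
    return DomainGrid(extent=0.02, nodes=21, dim=2, circular=False)
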