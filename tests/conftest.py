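import numpy as np
import pytest

from glioshadow import generate_phantom
from glioshadow.tissue_geometry import TissueGrid


@pytest.fixture(scope="session")
def phantom48():
    """Small brain phantom shared across tests."""
    return generate_phantom(48, 48, 7)


@pytest.fixture(scope="session")
def phantom96():
    return generate_phantom(96, 96, 1)


@pytest.fixture()
def open_grid():
    """A 12x12 all-white grid: the simplest brain domain (no obstacles)."""
    labels = np.full((12, 12), 3, dtype=np.int16)
    labels[0, :] = labels[-1, :] = labels[:, 0] = labels[:, -1] = 0
    return TissueGrid(labels)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
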