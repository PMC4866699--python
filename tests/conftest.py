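import numpy as np
import pytest

from infodim import BinaryLattice


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_blob(rng):
    """A sparse random 3D lattice, guaranteed non-empty."""
    cells = (rng.random((30, 30, 30)) < 0.2).astype(np.uint8)
    cells[15, 15, 15] = 1
    return BinaryLattice(cells)
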