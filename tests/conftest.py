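import numpy as np
import pytest

from purkinje_ca import CellGeometry, Model


@pytest.fixture(scope="session")
def geometry():
    return CellGeometry()


@pytest.fixture(scope="session")
def small_geometry():
    return CellGeometry(n_discs=4, n_layers=21, n_core_coupling_layers=3)


@pytest.fixture
def model():
    return Model()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
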