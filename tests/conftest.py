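import numpy as np
import pytest

from paninsim.io_cli.fixtures import make_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def two_cell_tissue():
    return make_fixture("two_cell")


@pytest.fixture
def lattice_tissue():
    return make_fixture("lattice")


@pytest.fixture
def perturbed_hex_tissue():
    return make_fixture("perturbed_hex", seed=3)


@pytest.fixture
def random_tissue():
    return make_fixture("random", seed=0)
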