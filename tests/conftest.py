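import numpy as np
import pytest

import hesnotch as hn


@pytest.fixture(scope="session")
def params():
    return hn.default_parameters()


@pytest.fixture(scope="session")
def ab(params):
    return hn.compute_ab(params)


@pytest.fixture(scope="session")
def two_cell():
    return hn.build_hex_lattice(1, 2, "periodic")


@pytest.fixture(scope="session")
def grid_9x9_periodic():
    return hn.build_hex_lattice(9, 9, "periodic")


@pytest.fixture(scope="session")
def grid_10x10_zero():
    return hn.build_hex_lattice(10, 10, "zero")
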