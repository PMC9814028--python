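import numpy as np
import pytest

from carfield.lattice import _graph_from_edges, build_grid


@pytest.fixture(scope="session")
def path2():
    """Two areas sharing one border."""
    return _graph_from_edges(2, [(0, 1)])


@pytest.fixture(scope="session")
def triangle():
    """Complete graph on three areas."""
    return _graph_from_edges(3, [(0, 1), (1, 2), (0, 2)])


@pytest.fixture(scope="session")
def path5():
    return build_grid(1, 5, "rook")


@pytest.fixture(scope="session")
def path30():
    return build_grid(1, 30, "rook")


@pytest.fixture(scope="session")
def grid33():
    return build_grid(3, 3, "rook")


@pytest.fixture(scope="session")
def grid44():
    return build_grid(4, 4, "rook")


@pytest.fixture(scope="session")
def grid66():
    return build_grid(6, 6, "rook")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
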