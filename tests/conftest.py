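import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("det", derandomize=True, deadline=None)
_hyp_settings.load_profile("det")

from graphsh.graphs import Network, generate_ba, generate_er, single_node_network


def net_from_edges(n, edges):
    rows = [e[0] for e in edges] + [e[1] for e in edges]
    cols = [e[1] for e in edges] + [e[0] for e in edges]
    a = sp.csr_array((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    a.data[:] = 1.0
    return Network(node_count=n, adjacency=a)


@pytest.fixture
def path3():
    """Path graph 0-1-2."""
    return net_from_edges(3, [(0, 1), (1, 2)])


@pytest.fixture
def star4():
    """Star: center 0 with leaves 1,2,3."""
    return net_from_edges(4, [(0, 1), (0, 2), (0, 3)])


@pytest.fixture
def c4():
    """4-cycle."""
    return net_from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0)])


@pytest.fixture
def k3():
    """Triangle."""
    return net_from_edges(3, [(0, 1), (1, 2), (0, 2)])


@pytest.fixture
def single_node():
    return single_node_network()


@pytest.fixture(scope="session")
def ba50():
    return generate_ba(50, 1, 2)


@pytest.fixture(scope="session")
def er60():
    return generate_er(60, 4.0, 5)


@pytest.fixture(scope="session")
def ba200():
    """The snaking-study fixture: BA tree, N=200, min degree 1."""
    return generate_ba(200, 1, 7)
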