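import numpy as np
import pytest

import surflight as sl


@pytest.fixture(scope="session")
def ico():
    return sl.base_icosahedron()


@pytest.fixture(scope="session")
def small_pair(ico):
    """High-res / low-res template pair small enough for exhaustive oracles."""
    return sl.subdivide(ico, 8), sl.subdivide(ico, 2)


@pytest.fixture(scope="session")
def small_layout(small_pair):
    high, low = small_pair
    mapping = sl.nearest_assignment(high, low)
    adj = sl.build_adjacency(low)
    return sl.build_layout(high, low, mapping, adj, sl.GridSpec())


@pytest.fixture(scope="session")
def test_pair(ico):
    """The template pair used for pipeline-level synthetic studies."""
    return sl.subdivide(ico, 16), sl.subdivide(ico, 4)


@pytest.fixture(scope="session")
def test_layout(test_pair):
    high, low = test_pair
    mapping = sl.nearest_assignment(high, low)
    adj = sl.build_adjacency(low)
    return sl.build_layout(high, low, mapping, adj, sl.GridSpec()), adj


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)
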