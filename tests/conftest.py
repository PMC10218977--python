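import numpy as np
import pytest

from pupilmark.graph import build_graph
from pupilmark.priors import ConditionalPrior, PriorBank


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def toy_bank(graph, grid_shape_2x, maker):
    """Build a PriorBank with grids from maker(edge) for every edge."""
    priors = {}
    for e in graph.edges:
        grid = np.asarray(maker(e), dtype=float)
        assert grid.shape == grid_shape_2x
        priors[e] = ConditionalPrior(e, None, None, None, 1, grid)
    return PriorBank(priors, grid_shape_2x)


@pytest.fixture
def triangle_graph():
    """Three landmarks, complete directed graph (2 neighbors each)."""
    ids = ("A", "B", "C")
    coords = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
    return build_graph(ids, coords, r=5.0, global_set=())
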