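import numpy as np
import pytest

from geoadditive import AdjacencyGraph, make_lattice_graph


@pytest.fixture
def two_region_graph() -> AdjacencyGraph:
    return AdjacencyGraph(labels=("a", "b"), edges=frozenset({(0, 1)}))


@pytest.fixture
def path3_graph() -> AdjacencyGraph:
    return AdjacencyGraph(labels=("a", "b", "c"), edges=frozenset({(0, 1), (1, 2)}))


@pytest.fixture
def lattice22() -> AdjacencyGraph:
    return make_lattice_graph(2, 2)


@pytest.fixture
def lattice66() -> AdjacencyGraph:
    return make_lattice_graph(6, 6)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230917)
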