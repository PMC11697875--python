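import numpy as np
import pytest

from spatialmotif.graph import CellMap, NeighborhoodGraph


@pytest.fixture
def triangle():
    """3-cycle with coordinates forming a triangle."""
    coords = np.array([[0.0, 0.0], [2.0, 0.0], [1.0, 2.0]])
    return NeighborhoodGraph(coords, np.array([1, 2, 3]), [(0, 1), (1, 2), (0, 2)], "t")


@pytest.fixture
def path3():
    """Path graph 0-1-2 on a line."""
    coords = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
    return NeighborhoodGraph(coords, np.array([1, 1, 2]), [(0, 1), (1, 2)], "p")


@pytest.fixture
def k4():
    """Complete graph on 4 vertices in general position."""
    coords = np.array([[0.0, 0.0], [1.0, 0.0], [0.3, 1.0], [0.9, 0.9]])
    edges = [(i, j) for i in range(4) for j in range(i + 1, 4)]
    return NeighborhoodGraph(coords, np.ones(4, dtype=int), edges, "k4")


def random_graph(n, p_edge, seed, L=4):
    """Erdos-Renyi labeled graph with random coordinates (for oracles)."""
    rng = np.random.default_rng(seed)
    edges = [
        (i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < p_edge
    ]
    if not edges:
        edges = [(0, 1)]
    return NeighborhoodGraph(
        rng.random((n, 2)), rng.integers(1, L + 1, n).astype(np.int32), edges, seed
    )


@pytest.fixture
def two_section_cells():
    rng = np.random.default_rng(0)
    n = 40
    return CellMap(
        positions=rng.random((2 * n, 2)) * 100,
        cell_types=rng.integers(1, 4, 2 * n),
        sections=np.array(["a"] * n + ["b"] * n),
    )
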