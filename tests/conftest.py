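import numpy as np
import pytest

from flagtopo import DirectedGraph, known_complex


@pytest.fixture
def octahedron():
    return known_complex("octahedron-sphere")


@pytest.fixture
def cycle3():
    return known_complex("cycle-3")


@pytest.fixture
def tournament4():
    """Acyclic tournament on 4 vertices: a solid directed 3-simplex."""
    return known_complex("simplex-3")


@pytest.fixture
def graph_factory():
    """Random DirectedGraph factory with a deterministic seed."""

    def make(n, p, seed):
        rng = np.random.default_rng(seed)
        edges = [
            (i, j)
            for i in range(n)
            for j in range(n)
            if i != j and rng.random() < p
        ]
        return DirectedGraph.from_edges(n, edges)

    return make
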