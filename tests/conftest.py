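import io

import numpy as np
import pytest

from vesselmorph.io import SkeletonGraph, SkeletonNode


def build_chain(points, radii=None, metadata=None) -> SkeletonGraph:
    """A simple open-chain skeleton from a point list."""
    points = np.asarray(points, dtype=float)
    if radii is None:
        radii = np.full(len(points), 4.0)
    g = SkeletonGraph(metadata=metadata or {})
    for i, (p, r) in enumerate(zip(points, radii), start=1):
        g.add_node(SkeletonNode(i, p, float(r)))
        if i > 1:
            g.add_edge(i - 1, i)
    return g


def random_tree_graph(rng: np.random.Generator, n: int) -> SkeletonGraph:
    """A random labelled tree with random coordinates and radii."""
    g = SkeletonGraph()
    for i in range(1, n + 1):
        g.add_node(SkeletonNode(i, rng.uniform(0, 100, 3), rng.uniform(0.5, 8)))
    for i in range(2, n + 1):
        g.add_edge(i, int(rng.integers(1, i)))
    return g


@pytest.fixture
def swc_two_nodes():
    return io.StringIO("1 2 0 0 0 4.0 -1\n2 2 10 0 0 4.0 1\n")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
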