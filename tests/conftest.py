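from __future__ import annotations

import networkx as nx
import pytest

from netprio.network_io import Network


def make_network(edges, extra_vertices=()) -> Network:
    """Build a simplified Network from an iterable of 2-tuples."""
    norm = {(a, b) if a < b else (b, a) for a, b in edges if a != b}
    vertices = {v for e in norm for v in e} | set(extra_vertices)
    for a, b in edges:
        vertices.add(a)
        vertices.add(b)
    return Network(vertices=vertices, edges=norm)


def from_networkx(g: nx.Graph) -> Network:
    """Convert a networkx graph to a Network with string vertex names."""
    relabel = {v: f"N{v:04d}" if isinstance(v, int) else str(v) for v in g.nodes}
    edges = {(relabel[a], relabel[b]) for a, b in g.edges if a != b}
    return make_network(edges, extra_vertices=relabel.values())


@pytest.fixture
def triangle() -> Network:
    return make_network([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def path3() -> Network:
    """Path A - B - C."""
    return make_network([("A", "B"), ("B", "C")])


@pytest.fixture
def star3() -> Network:
    """Star K1,3: center c, leaves l1..l3."""
    return make_network([("c", "l1"), ("c", "l2"), ("c", "l3")])


@pytest.fixture
def star4() -> Network:
    """Star K1,4: center c, leaves l1..l4."""
    return make_network([("c", f"l{i}") for i in range(1, 5)])
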