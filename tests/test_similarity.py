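from __future__ import annotations

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netprio.similarity import (
    SimilarityMatrix,
    build_similarity_matrix,
    brute_force_matrix,
    combined,
    dice,
    jaccard,
    neighbors,
)

from conftest import from_networkx, make_network


class TestNeighbors:
    def test_triangle(self, triangle):
        idx = neighbors(triangle)
        assert idx == {"A": {"B", "C"}, "B": {"A", "C"}, "C": {"A", "B"}}

    def test_star(self, star3):
        idx = neighbors(star3)
        assert idx["c"] == {"l1", "l2", "l3"}
        assert idx["l1"] == {"c"}

    def test_isolated_vertex(self):
        net = make_network([("A", "B")], extra_vertices=["Z"])
        assert neighbors(net)["Z"] == set()

    def test_closed_includes_self(self, triangle):
        idx = neighbors(triangle, closed=True)
        assert idx["A"] == {"A", "B", "C"}


class TestPairScores:
    def test_triangle_pair(self):
        na, nb = {"B", "C"}, {"A", "C"}
        assert jaccard(na, nb) == pytest.approx(1 / 3)
        assert dice(na, nb) == pytest.approx(1 / 2)
        assert combined(na, nb) == pytest.approx(5 / 12)

    def test_identical_sets(self):
        s = {"X", "Y"}
        assert jaccard(s, s) == 1.0
        assert dice(s, s) == 1.0
        assert combined(s, s) == 1.0

    def test_both_empty_convention(self):
        assert jaccard(set(), set()) == 0.0
        assert dice(set(), set()) == 0.0
        assert combined(set(), set()) == 0.0

    def test_disjoint(self):
        assert dice({"A"}, {"B"}) == 0.0
        assert combined({"A"}, {"B"}) == 0.0

    @given(
        st.sets(st.integers(0, 30)).map(lambda s: {str(x) for x in s}),
        st.sets(st.integers(0, 30)).map(lambda s: {str(x) for x in s}),
    )
    @settings(max_examples=300, deadline=None)
    def test_identities(self, na, nb):
        j, d, c = jaccard(na, nb), dice(na, nb), combined(na, nb)
        assert 0 <= j <= d <= 1
        assert d == pytest.approx(2 * j / (1 + j), abs=1e-12)
        assert c == (j + d) / 2
        assert (jaccard(nb, na), dice(nb, na), combined(nb, na)) == (j, d, c)


class TestBuildMatrix:
    def test_path_stores_only_endpoints(self, path3):
        m = build_similarity_matrix(path3)
        assert len(m) == 1
        pair = m.get("A", "C")
        assert pair.jaccard == pair.dice == pair.combined == 1.0
        assert m.get("A", "B").combined == 0.0

    def test_star4_leaf_pairs(self, star4):
        m = build_similarity_matrix(star4)
        assert len(m) == 6
        for a, b in [("l1", "l2"), ("l3", "l4"), ("l2", "l4")]:
            assert m.get(a, b).combined == 1.0
        assert ("c", "l1") not in m

    def test_edgeless(self):
        net = make_network([], extra_vertices=[f"V{i}" for i in range(5)])
        assert len(build_similarity_matrix(net)) == 0

    def test_empty_network_is_error(self):
        from netprio.network_io import Network
        with pytest.raises(ValueError):
            build_similarity_matrix(Network(vertices=set(), edges=set()))

    def test_symmetric_lookup(self, triangle):
        m = build_similarity_matrix(triangle)
        ab, ba = m.get("A", "B"), m.get("B", "A")
        assert (ab.jaccard, ab.dice, ab.combined) == (ba.jaccard, ba.dice, ba.combined)


class TestBruteForce:
    def test_triangle_all_pairs(self, triangle):
        m = brute_force_matrix(triangle)
        for a, b in [("A", "B"), ("B", "C"), ("A", "C")]:
            assert m.get(a, b).jaccard == pytest.approx(1 / 3)

    def test_path_adjacent_pair_zero(self, path3):
        m = brute_force_matrix(path3)
        assert m.get("A", "B").jaccard == 0.0

    def test_cap(self):
        net = make_network([], extra_vertices=[f"V{i}" for i in range(11)])
        with pytest.raises(ValueError, match="cap"):
            brute_force_matrix(net, cap=10)

    @pytest.mark.parametrize("seed,n,p", [(0, 25, 0.1), (1, 40, 0.05), (2, 30, 0.3)])
    def test_matches_builder(self, seed, n, p):
        net = from_networkx(nx.gnp_random_graph(n, p, seed=seed))
        fast = build_similarity_matrix(net)
        slow = brute_force_matrix(net)
        assert {(p_.gene_a, p_.gene_b) for p_ in fast.pairs()} == \
            {(p_.gene_a, p_.gene_b) for p_ in slow.pairs()}
        for pair in slow.pairs():
            got = fast.get(pair.gene_a, pair.gene_b)
            assert got.jaccard == pytest.approx(pair.jaccard, abs=1e-12)
            assert got.dice == pytest.approx(pair.dice, abs=1e-12)
            assert got.combined == pytest.approx(pair.combined, abs=1e-12)

    def test_closed_variant_matches_builder(self):
        net = from_networkx(nx.gnp_random_graph(20, 0.2, seed=7))
        fast = build_similarity_matrix(net, closed=True)
        slow = brute_force_matrix(net, closed=True)
        assert {(p.gene_a, p.gene_b) for p in fast.pairs()} == \
            {(p.gene_a, p.gene_b) for p in slow.pairs()}


class TestSparsitySupport:
    def test_support_is_distance_two_shared_neighbor(self):
        g = nx.gnp_random_graph(30, 0.1, seed=3)
        net = from_networkx(g)
        idx = neighbors(net)
        m = build_similarity_matrix(net)
        expected = {
            (a, b)
            for a in net.vertices
            for b in net.vertices
            if a < b and idx[a] & idx[b]
        }
        assert {(p.gene_a, p.gene_b) for p in m.pairs()} == expected


class TestPersistence:
    def test_round_trip(self, tmp_path, star4):
        m = build_similarity_matrix(star4)
        path = tmp_path / "matrix.tsv"
        m.write_tsv(path)
        loaded = SimilarityMatrix.read_tsv(path, vertices=m.vertices)
        assert loaded.vertices == m.vertices
        assert len(loaded) == len(m)
        for pair in m.pairs():
            got = loaded.get(pair.gene_a, pair.gene_b)
            assert got.combined == pair.combined

    def test_rows_sorted(self, tmp_path, star4):
        path = tmp_path / "matrix.tsv"
        build_similarity_matrix(star4).write_tsv(path)
        rows = [ln.split("\t")[:2] for ln in path.read_text().splitlines()[1:]]
        assert rows == sorted(rows)
        assert all(a < b for a, b in rows)

    def test_byte_identical_rewrite(self, tmp_path, star4):
        m = build_similarity_matrix(star4)
        p1, p2 = tmp_path / "m1.tsv", tmp_path / "m2.tsv"
        m.write_tsv(p1)
        m.write_tsv(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_unstored_pair_is_zero(self, star4):
        m = build_similarity_matrix(star4)
        pair = m.get("c", "l1")
        assert (pair.jaccard, pair.dice, pair.combined) == (0.0, 0.0, 0.0)


@given(st.integers(0, 10_000))
@settings(max_examples=40, deadline=None)
def test_random_graph_identities(seed):
    rng_graph = nx.gnp_random_graph(15, 0.25, seed=seed)
    net = from_networkx(rng_graph)
    if net.n_vertices == 0:
        return
    idx = neighbors(net)
    m = build_similarity_matrix(net)
    for pair in m.pairs():
        assert 0 <= pair.jaccard <= pair.dice <= 1
        assert pair.dice == pytest.approx(2 * pair.jaccard / (1 + pair.jaccard), abs=1e-12)
        assert pair.combined == (pair.jaccard + pair.dice) / 2
    for v in net.vertices:
        if idx[v]:
            assert combined(idx[v], idx[v]) == 1.0
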