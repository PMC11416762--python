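"""Pairwise neighborhood similarity and the sparse similarity matrix.

For a pair of vertices with open neighborhoods ``na``, ``nb``:

* Jaccard       ``J  = |na & nb| / |na | nb|``
* Sorensen-Dice ``SI = 2 |na & nb| / (|na| + |nb|)``
* combined      ``S  = (J + SI) / 2``

Degenerate pairs (empty union / both neighborhoods empty) score 0 rather than
NaN so the matrix stays total-ordered for ranking. Only pairs with at least
one shared neighbor have non-zero scores, so the matrix stores exactly the
vertex pairs at graph distance <= 2 that share a neighbor; lookups of
unstored pairs return all-zero scores.
"""

from __future__ import annotations

from itertools import combinations
from pathlib import Path
from typing import Iterator, NamedTuple

from netprio.network_io import Network

__all__ = [
    "PairSimilarity",
    "SimilarityMatrix",
    "neighbors",
    "jaccard",
    "dice",
    "combined",
    "build_similarity_matrix",
    "brute_force_matrix",
]

_TSV_HEADER = "gene_a\tgene_b\tjaccard\tdice\tcombined"


class PairSimilarity(NamedTuple):
    gene_a: str
    gene_b: str
    jaccard: float
    dice: float
    combined: float


def neighbors(network: Network, closed: bool = False) -> dict[str, set[str]]:
    """Neighbor index for every vertex; open neighborhoods by default.

    With ``closed=True`` each vertex is included in its own neighborhood
    (an alternative convention, not the default).
    """
    index: dict[str, set[str]] = {v: set() for v in network.vertices}
    for a, b in network.edges:
        index[a].add(b)
        index[b].add(a)
    if closed:
        for v, ns in index.items():
            ns.add(v)
    return index


def jaccard(na: set[str], nb: set[str]) -> float:
    """|na & nb| / |na | nb|; 0 when the union is empty."""
    union = len(na | nb)
    if union == 0:
        return 0.0
    return len(na & nb) / union


def dice(na: set[str], nb: set[str]) -> float:
    """2 |na & nb| / (|na| + |nb|); 0 when both sets are empty."""
    total = len(na) + len(nb)
    if total == 0:
        return 0.0
    return 2 * len(na & nb) / total


def combined(na: set[str], nb: set[str]) -> float:
    """Arithmetic mean of the Jaccard and Sorensen-Dice scores."""
    return (jaccard(na, nb) + dice(na, nb)) / 2


class SimilarityMatrix:
    """Sparse symmetric store of pairwise similarity scores.

    Entries are keyed by the sorted gene pair; querying an unstored pair
    (including pairs farther than distance 2 apart) returns zeros.
    """

    def __init__(self, vertices: Iterator[str] | list[str]) -> None:
        self.vertices: list[str] = sorted(vertices)
        self._vertex_set = set(self.vertices)
        self._data: dict[tuple[str, str], tuple[float, float, float]] = {}

    @property
    def vertex_set(self) -> set[str]:
        return self._vertex_set

    def __len__(self) -> int:
        return len(self._data)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        a, b = pair
        return ((a, b) if a < b else (b, a)) in self._data

    def set(self, a: str, b: str, j: float, d: float, s: float) -> None:
        if a == b:
            raise ValueError("diagonal entries are not stored")
        key = (a, b) if a < b else (b, a)
        self._data[key] = (j, d, s)

    def get(self, a: str, b: str) -> PairSimilarity:
        key = (a, b) if a < b else (b, a)
        j, d, s = self._data.get(key, (0.0, 0.0, 0.0))
        return PairSimilarity(a, b, j, d, s)

    def pairs(self) -> Iterator[PairSimilarity]:
        for (a, b), (j, d, s) in self._data.items():
            yield PairSimilarity(a, b, j, d, s)

    def write_tsv(self, path: str | Path) -> None:
        """Persist as a sorted triplet TSV (deterministic byte-for-byte)."""
        with open(path, "w") as fh:
            fh.write(_TSV_HEADER + "\n")
            for (a, b) in sorted(self._data):
                j, d, s = self._data[(a, b)]
                fh.write(f"{a}\t{b}\t{j:.17g}\t{d:.17g}\t{s:.17g}\n")

    @classmethod
    def read_tsv(cls, path: str | Path, vertices: list[str] | None = None) -> "SimilarityMatrix":
        """Load a triplet TSV; ``vertices`` restores isolated vertices that
        have no stored pair (pass the full vertex list when available)."""
        entries: list[tuple[str, str, float, float, float]] = []
        seen: set[str] = set(vertices or [])
        with open(path) as fh:
            header = fh.readline().rstrip("\n")
            if header != _TSV_HEADER:
                raise ValueError(f"{path}: unexpected header {header!r}")
            for line in fh:
                a, b, j, d, s = line.rstrip("\n").split("\t")
                entries.append((a, b, float(j), float(d), float(s)))
                seen.add(a)
                seen.add(b)
        matrix = cls(seen)
        for a, b, j, d, s in entries:
            matrix.set(a, b, j, d, s)
        return matrix


def _candidate_pairs(index: dict[str, set[str]], closed: bool) -> set[tuple[str, str]]:
    # Two vertices can share a neighbor only if both are adjacent to some
    # common vertex, i.e. both appear in somebody's neighborhood.
    pairs: set[tuple[str, str]] = set()
    for v, ns in index.items():
        members = sorted(ns)  # with closed=True, v itself is already included
        for a, b in combinations(members, 2):
            pairs.add((a, b))
    return pairs


def build_similarity_matrix(network: Network, closed: bool = False) -> SimilarityMatrix:
    """Compute all non-zero pairwise similarities via shared-neighbor pruning.

    Candidate pairs are enumerated by pairing each vertex's neighbors, which
    covers every pair with a non-empty neighborhood intersection; all other
    pairs are exactly zero and stay implicit.
    """
    if network.n_vertices == 0:
        raise ValueError("cannot build a similarity matrix for an empty network")
    index = neighbors(network, closed=closed)
    matrix = SimilarityMatrix(network.vertices)
    for a, b in _candidate_pairs(index, closed):
        na, nb = index[a], index[b]
        j = jaccard(na, nb)
        d = dice(na, nb)
        matrix.set(a, b, j, d, (j + d) / 2)
    return matrix


def brute_force_matrix(network: Network, cap: int = 500, closed: bool = False) -> SimilarityMatrix:
    """Test oracle: evaluate every one of the C(n,2) pairs directly.

    Refuses networks above ``cap`` vertices. Zero-valued pairs are not stored
    so the result is directly comparable with :func:`build_similarity_matrix`.
    """
    if network.n_vertices > cap:
        raise ValueError(f"brute force capped at {cap} vertices, got {network.n_vertices}")
    if network.n_vertices == 0:
        raise ValueError("cannot build a similarity matrix for an empty network")
    index = neighbors(network, closed=closed)
    matrix = SimilarityMatrix(network.vertices)
    for a, b in combinations(sorted(network.vertices), 2):
        na, nb = index[a], index[b]
        j = jaccard(na, nb)
        d = dice(na, nb)
        if j > 0 or d > 0:
            matrix.set(a, b, j, d, (j + d) / 2)
    return matrix
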