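"""Read, validate, simplify, and write interaction networks and gene sets.

Supported formats:

* edge lists — generic two/three column whitespace-separated files, or the
  STRING ``protein.links`` dialect (header ``protein1 protein2 combined_score``,
  integer confidence 0-1000);
* gene sets — GMT (one set per line: name, description, member genes);
* graph export — GraphML;
* identifier mapping — two-column TSV (source id TAB symbol).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeRecord",
    "Network",
    "GeneSetCollection",
    "ParseError",
    "read_edge_list",
    "read_mapping",
    "simplify",
    "read_gmt",
    "write_gmt",
    "restrict_to_network",
    "export_graphml",
]


class ParseError(ValueError):
    """Malformed input file; message includes the offending line number."""


@dataclass(frozen=True)
class EdgeRecord:
    """One raw edge as read from a file, before simplification."""

    gene_a: str
    gene_b: str
    weight: float | None = None

    def __post_init__(self) -> None:
        if not self.gene_a or not self.gene_b:
            raise ValueError("edge endpoints must be non-empty strings")
        if self.weight is not None and self.weight < 0:
            raise ValueError(f"negative edge weight {self.weight!r}")


@dataclass
class Network:
    """A simple undirected graph over gene symbols.

    Invariants: no self-loops, no duplicate edges, each edge stored once as a
    lexicographically sorted tuple, every edge endpoint is in ``vertices``.
    Isolated vertices are allowed (e.g. left over from self-loop removal).
    """

    vertices: set[str]
    edges: set[tuple[str, str]]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop {a!r} in simplified network")
            if a > b:
                raise ValueError(f"edge ({a!r}, {b!r}) not stored in sorted order")
            if a not in self.vertices or b not in self.vertices:
                raise ValueError(f"edge ({a!r}, {b!r}) has endpoint outside vertex set")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def has_edge(self, a: str, b: str) -> bool:
        return (a, b) in self.edges if a < b else (b, a) in self.edges

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.vertices))
        g.add_edges_from(sorted(self.edges))
        return g


class GeneSetCollection:
    """Ordered, named gene sets (the GMT abstraction).

    Set names are unique; genes within a set are de-duplicated keeping the
    first occurrence; empty sets are rejected.
    """

    def __init__(self, sets: Iterable[tuple[str, str, Sequence[str]]] = ()) -> None:
        self._sets: dict[str, tuple[str, list[str]]] = {}
        for name, description, genes in sets:
            self.add(name, description, genes)

    def add(self, name: str, description: str, genes: Sequence[str]) -> None:
        if name in self._sets:
            raise ValueError(f"duplicate gene set name {name!r}")
        deduped = list(dict.fromkeys(genes))
        if not deduped:
            raise ValueError(f"gene set {name!r} is empty")
        self._sets[name] = (description, deduped)

    def names(self) -> list[str]:
        return list(self._sets)

    def description(self, name: str) -> str:
        return self._sets[name][0]

    def genes(self, name: str) -> list[str]:
        return list(self._sets[name][1])

    def items(self) -> Iterator[tuple[str, str, list[str]]]:
        for name, (description, genes) in self._sets.items():
            yield name, description, list(genes)

    def __getitem__(self, name: str) -> list[str]:
        if name not in self._sets:
            raise KeyError(
                f"unknown gene set {name!r}; available: {', '.join(self._sets) or '(none)'}"
            )
        return list(self._sets[name][1])

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __len__(self) -> int:
        return len(self._sets)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self._sets == other._sets

    def __repr__(self) -> str:
        return f"GeneSetCollection({len(self)} sets)"


def simplify(raw_edges: Iterable[EdgeRecord], provenance: dict | None = None) -> Network:
    """Collapse duplicate/reversed edges and drop self-loops.

    Endpoints that appeared only in self-loops are kept as isolated vertices
    so vertex counts stay stable.
    """
    vertices: set[str] = set()
    edges: set[tuple[str, str]] = set()
    for rec in raw_edges:
        vertices.add(rec.gene_a)
        vertices.add(rec.gene_b)
        if rec.gene_a == rec.gene_b:
            continue
        edges.add((rec.gene_a, rec.gene_b) if rec.gene_a < rec.gene_b else (rec.gene_b, rec.gene_a))
    return Network(vertices=vertices, edges=edges, provenance=dict(provenance or {}))


def read_mapping(path: str | Path) -> dict[str, str]:
    """Read a two-column identifier mapping (source_id TAB symbol)."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            mapping[fields[0]] = fields[1]
    return mapping


def _parse_edge_line(
    fields: list[str], path: str | Path, lineno: int, require_weight: bool
) -> EdgeRecord:
    if len(fields) not in (2, 3):
        raise ParseError(f"{path}:{lineno}: expected 2-3 columns, got {len(fields)}")
    weight: float | None = None
    if len(fields) == 3:
        try:
            weight = float(fields[2])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-numeric weight {fields[2]!r}") from None
    elif require_weight:
        raise ParseError(f"{path}:{lineno}: expected 3 columns (weight required), got 2")
    try:
        return EdgeRecord(fields[0], fields[1], weight)
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: {exc}") from None


def read_edge_list(
    path: str | Path,
    dialect: str = "generic",
    min_weight: float | None = None,
    mapping: Mapping[str, str] | None = None,
) -> Network:
    """Read an edge-list file and return the simplified network.

    Parameters
    ----------
    path
        Edge-list file. Lines starting with ``#`` are skipped.
    dialect
        ``"generic"`` (2-3 whitespace/tab columns, optional numeric weight) or
        ``"string-links"`` (STRING protein.links; header line required, third
        column is the integer combined_score).
    min_weight
        Drop edges with weight strictly below this threshold before
        simplification. Unweighted edges are never dropped.
    mapping
        Optional id -> symbol translation applied before simplification;
        identifiers without a mapping entry pass through unchanged. Two ids
        collapsing onto one symbol merge their neighborhoods.
    """
    if dialect not in ("generic", "string-links"):
        raise ValueError(f"unknown dialect {dialect!r}")
    records: list[EdgeRecord] = []
    n_dropped = 0
    with open(path) as fh:
        first_data_line = True
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if dialect == "string-links" and first_data_line:
                first_data_line = False
                if fields[:2] == ["protein1", "protein2"]:
                    continue  # header
                # STRING files always carry the header; tolerate its absence
            rec = _parse_edge_line(fields, path, lineno, require_weight=dialect == "string-links")
            if min_weight is not None and rec.weight is not None and rec.weight < min_weight:
                n_dropped += 1
                continue
            records.append(rec)
    if mapping:
        records = [
            EdgeRecord(mapping.get(r.gene_a, r.gene_a), mapping.get(r.gene_b, r.gene_b), r.weight)
            for r in records
        ]
    net = simplify(
        records,
        provenance={
            "source": str(path),
            "dialect": dialect,
            "min_weight": min_weight,
            "mapped": mapping is not None,
            "edges_read": len(records) + n_dropped,
            "edges_below_threshold": n_dropped,
        },
    )
    if net.n_vertices == 0:
        raise ParseError(f"{path}: no edges survived parsing/filtering")
    logger.info(
        "read %s: %d raw edges (%d below threshold) -> %d vertices, %d edges",
        path, len(records) + n_dropped, n_dropped, net.n_vertices, net.n_edges,
    )
    return net


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file (name TAB description TAB gene TAB gene ...)."""
    collection = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
            try:
                collection.add(fields[0], fields[1], [g for g in fields[2:] if g])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return collection


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, description, genes in collection.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def restrict_to_network(
    genes: Sequence[str], network: Network
) -> tuple[list[str], list[str]]:
    """Split a gene list into (present-in-network, absent), preserving order."""
    present = [g for g in genes if g in network.vertices]
    absent = [g for g in genes if g not in network.vertices]
    if absent:
        logger.warning(
            "%d of %d genes absent from network (kept %d)", len(absent), len(genes), len(present)
        )
    return present, absent


def export_graphml(network: Network, path: str | Path) -> None:
    """Write the network as undirected GraphML with gene symbols as node ids."""
    nx.write_graphml(network.to_networkx(), path)
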