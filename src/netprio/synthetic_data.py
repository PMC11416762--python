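"""Planted-module synthetic networks for end-to-end pipeline testing.

A planted-partition graph: vertex pairs inside the same module are connected
with probability ``p_in``, every other pair with ``p_out``. Module members
share many neighbors, giving the cohesive-neighborhood structure that
seed-set scoring assumes, without requiring any database download. Part of
each module is withheld from the seed list so ranking recovery can be
measured against known ground truth.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from math import ceil
from pathlib import Path

import numpy as np

from netprio.network_io import GeneSetCollection, Network, write_gmt
from netprio.scoring import rank_genes
from netprio.similarity import build_similarity_matrix

__all__ = [
    "SyntheticNetworkSpec",
    "SyntheticTruth",
    "generate_planted_module_network",
    "write_truth",
    "recovery_experiment",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticNetworkSpec:
    """Parameters of one planted-module network draw."""

    n_background: int
    module_sizes: tuple[int, ...]
    p_in: float
    p_out: float
    n_heldout_per_module: int
    rng_seed: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "module_sizes", tuple(self.module_sizes))
        if self.n_background < 0:
            raise ValueError("n_background must be >= 0")
        if not self.module_sizes:
            raise ValueError("need at least one module")
        if any(m < 1 for m in self.module_sizes):
            raise ValueError("module sizes must be >= 1")
        if not (0.0 <= self.p_out <= self.p_in <= 1.0):
            raise ValueError(f"need 0 <= p_out <= p_in <= 1, got p_in={self.p_in}, p_out={self.p_out}")
        if self.n_heldout_per_module < 0:
            raise ValueError("n_heldout_per_module must be >= 0")
        if any(self.n_heldout_per_module >= m for m in self.module_sizes):
            raise ValueError("n_heldout_per_module must be smaller than every module")

    @property
    def n_total(self) -> int:
        return self.n_background + sum(self.module_sizes)

    def background_genes(self) -> list[str]:
        return [f"G{i:06d}" for i in range(1, self.n_background + 1)]

    def module_genes(self, module: int) -> list[str]:
        """1-based module index."""
        return [f"M{module}_{j:03d}" for j in range(1, self.module_sizes[module - 1] + 1)]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticNetworkSpec":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(**{k: tuple(v) if k == "module_sizes" else v for k, v in payload.items()})


@dataclass(frozen=True)
class ModuleTruth:
    seed: tuple[str, ...]
    heldout: tuple[str, ...]


@dataclass(frozen=True)
class SyntheticTruth:
    modules: tuple[ModuleTruth, ...]
    background: tuple[str, ...]
    spec: SyntheticNetworkSpec = field(repr=False)

    def all_seed(self) -> list[str]:
        return [g for m in self.modules for g in m.seed]

    def all_heldout(self) -> list[str]:
        return [g for m in self.modules for g in m.heldout]


def generate_planted_module_network(
    spec: SyntheticNetworkSpec,
) -> tuple[Network, SyntheticTruth]:
    """Sample one planted-partition network; deterministic given the spec.

    Each module's last ``n_heldout_per_module`` members (deterministic by
    name order) are withheld from the seed list.
    """
    genes = spec.background_genes()
    membership = [0] * spec.n_background
    modules: list[ModuleTruth] = []
    for m, _size in enumerate(spec.module_sizes, start=1):
        members = spec.module_genes(m)
        genes.extend(members)
        membership.extend([m] * len(members))
        cut = len(members) - spec.n_heldout_per_module
        modules.append(ModuleTruth(seed=tuple(members[:cut]), heldout=tuple(members[cut:])))

    n = len(genes)
    mem = np.asarray(membership)
    rng = np.random.default_rng(spec.rng_seed)
    ia, ib = np.triu_indices(n, k=1)
    intra = (mem[ia] == mem[ib]) & (mem[ia] > 0)
    probs = np.where(intra, spec.p_in, spec.p_out)
    keep = rng.random(ia.size) < probs
    edges = {
        (genes[a], genes[b]) if genes[a] < genes[b] else (genes[b], genes[a])
        for a, b in zip(ia[keep], ib[keep])
    }
    network = Network(
        vertices=set(genes),
        edges=edges,
        provenance={"generator": "planted-partition", **asdict(spec)},
    )
    truth = SyntheticTruth(
        modules=tuple(modules),
        background=tuple(spec.background_genes()),
        spec=spec,
    )
    return network, truth


def write_truth(truth: SyntheticTruth, gmt_path: str | Path, tsv_path: str | Path) -> None:
    """Persist seed/held-out sets as GMT and per-gene labels as TSV."""
    collection = GeneSetCollection()
    for m, module in enumerate(truth.modules, start=1):
        collection.add(f"module{m}_seed", f"seed genes of planted module {m}", list(module.seed))
        if module.heldout:
            collection.add(
                f"module{m}_heldout", f"held-out genes of planted module {m}", list(module.heldout)
            )
    write_gmt(collection, gmt_path)
    with open(tsv_path, "w") as fh:
        fh.write("gene\tlabel\n")
        for gene in truth.background:
            fh.write(f"{gene}\tbackground\n")
        for m, module in enumerate(truth.modules, start=1):
            for gene in module.seed:
                fh.write(f"{gene}\tmodule{m}_seed\n")
            for gene in module.heldout:
                fh.write(f"{gene}\tmodule{m}_heldout\n")


def recovery_experiment(
    spec: SyntheticNetworkSpec, n_reps: int, top_fraction: float
) -> dict:
    """Held-out recovery across replicates.

    Per replicate: generate a network (seed ``spec.rng_seed + rep``), build
    the similarity matrix, rank non-seed genes against the seed list, and
    record the fraction of held-out genes inside the top
    ``ceil(top_fraction * n_ranked)`` ranks.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if not (0.0 < top_fraction <= 1.0):
        raise ValueError("top_fraction must be in (0, 1]")
    if spec.n_heldout_per_module < 1:
        raise ValueError("recovery requires at least one held-out gene per module")
    per_rep: list[float] = []
    for rep in range(n_reps):
        rep_spec = replace(spec, rng_seed=spec.rng_seed + rep)
        network, truth = generate_planted_module_network(rep_spec)
        matrix = build_similarity_matrix(network)
        table = rank_genes(matrix, truth.all_seed(), exclude_seed=True)
        k = ceil(top_fraction * len(table))
        top = set(table.head(k)["gene"])
        heldout = truth.all_heldout()
        per_rep.append(sum(g in top for g in heldout) / len(heldout))
    arr = np.asarray(per_rep)
    return {
        "per_rep": per_rep,
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if n_reps > 1 else 0.0,
        "n_reps": n_reps,
        "top_fraction": top_fraction,
        "spec": asdict(spec),
    }
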