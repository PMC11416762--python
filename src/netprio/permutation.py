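"""Permutation test of a gene's mean similarity to a pathway gene set.

The observed statistic is the mean combined similarity between the query
gene and the pathway members present in the network. The null resamples
equal-size gene sets uniformly without replacement from the network vertices
(minus the query gene) and recomputes the mean; the empirical p-value uses
the plus-one convention p = (1 + #{null >= observed}) / (1 + n_perm), so the
smallest attainable p is 1/(n_perm + 1) and significance means the pathway's
similarity exceeds that of random gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Iterable

import numpy as np

from netprio.similarity import SimilarityMatrix

__all__ = [
    "PermutationResult",
    "mean_similarity_to_set",
    "permutation_test",
    "exact_permutation_p",
]


@dataclass
class PermutationResult:
    query_gene: str
    pathway_name: str
    observed_mean: float
    null_means: np.ndarray = field(repr=False)
    p_empirical: float
    n_perm: int
    set_size: int
    n_pathway_used: int
    rng_seed: int

    def to_dict(self) -> dict:
        return {
            "query_gene": self.query_gene,
            "pathway_name": self.pathway_name,
            "observed_mean": self.observed_mean,
            "p_empirical": self.p_empirical,
            "n_perm": self.n_perm,
            "set_size": self.set_size,
            "n_pathway_used": self.n_pathway_used,
            "rng_seed": self.rng_seed,
            "null_mean_of_means": float(self.null_means.mean()),
            "null_sd_of_means": float(self.null_means.std(ddof=1)) if self.n_perm > 1 else 0.0,
        }


def _effective_set(matrix: SimilarityMatrix, gene: str, gene_set: Iterable[str]) -> list[str]:
    members = [s for s in dict.fromkeys(gene_set) if s in matrix.vertex_set and s != gene]
    if not members:
        raise ValueError(f"no usable gene-set members in the network for query {gene!r}")
    return members


def mean_similarity_to_set(
    matrix: SimilarityMatrix, gene: str, gene_set: Iterable[str]
) -> float:
    """Mean combined similarity between ``gene`` and the set members present
    in the network (the gene itself is excluded if it is a member)."""
    if gene not in matrix.vertex_set:
        raise KeyError(f"gene {gene!r} is not in the network")
    members = _effective_set(matrix, gene, gene_set)
    return float(np.mean([matrix.get(gene, s).combined for s in members]))


def _similarity_vector(
    matrix: SimilarityMatrix, gene: str, pool: list[str]
) -> np.ndarray:
    return np.array([matrix.get(gene, s).combined for s in pool], dtype=float)


def _build_pool(
    matrix: SimilarityMatrix, gene: str, exclude: set[str] | None = None
) -> list[str]:
    exclude = exclude or set()
    return sorted(v for v in matrix.vertex_set if v != gene and v not in exclude)


def permutation_test(
    matrix: SimilarityMatrix,
    gene: str,
    pathway: Iterable[str],
    pathway_name: str = "",
    n_perm: int = 10_000,
    set_size: int = 50,
    rng_seed: int = 0,
    exclude_pathway_from_pool: bool = False,
) -> PermutationResult:
    """Monte-Carlo permutation test; fully reproducible given ``rng_seed``.

    ``set_size`` may be the string ``"match"`` to draw null sets matching the
    pathway's effective size instead of the default fixed 50.
    """
    if gene not in matrix.vertex_set:
        raise KeyError(f"gene {gene!r} is not in the network")
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    members = _effective_set(matrix, gene, pathway)
    if set_size == "match":
        set_size = len(members)
    if int(set_size) < 1:
        raise ValueError(f"set_size must be >= 1, got {set_size}")
    set_size = int(set_size)
    pool = _build_pool(matrix, gene, set(members) if exclude_pathway_from_pool else None)
    if set_size > len(pool):
        raise ValueError(f"set_size {set_size} exceeds sampling pool of {len(pool)} genes")

    sims = _similarity_vector(matrix, gene, pool)
    pool_index = {g: i for i, g in enumerate(pool)}
    if all(m in pool_index for m in members):
        # same float path as the null means, keeps >= tie handling consistent
        observed = float(sims[[pool_index[m] for m in members]].mean())
    else:
        observed = mean_similarity_to_set(matrix, gene, members)

    rng = np.random.default_rng(rng_seed)
    null_means = np.empty(n_perm, dtype=float)
    n_pool = len(pool)
    for i in range(n_perm):
        null_means[i] = sims[rng.choice(n_pool, size=set_size, replace=False)].mean()
    p = (1 + int(np.sum(null_means >= observed))) / (1 + n_perm)
    return PermutationResult(
        query_gene=gene,
        pathway_name=pathway_name,
        observed_mean=observed,
        null_means=null_means,
        p_empirical=p,
        n_perm=n_perm,
        set_size=set_size,
        n_pathway_used=len(members),
        rng_seed=rng_seed,
    )


def exact_permutation_p(
    matrix: SimilarityMatrix,
    gene: str,
    pathway: Iterable[str],
    set_size: int,
    max_subsets: int = 1_000_000,
) -> float:
    """Test oracle: exact tail probability by exhaustive subset enumeration.

    Applies the same >= comparison and plus-one convention to the full
    enumeration: p = (1 + #{subsets with mean >= observed}) / (1 + C(pool, k)).
    """
    if gene not in matrix.vertex_set:
        raise KeyError(f"gene {gene!r} is not in the network")
    members = _effective_set(matrix, gene, pathway)
    pool = _build_pool(matrix, gene)
    if set_size < 1 or set_size > len(pool):
        raise ValueError(f"set_size {set_size} invalid for pool of {len(pool)}")
    n_subsets = comb(len(pool), set_size)
    if n_subsets > max_subsets:
        raise ValueError(f"enumeration of {n_subsets} subsets exceeds cap {max_subsets}")

    sims = _similarity_vector(matrix, gene, pool)
    pool_index = {g: i for i, g in enumerate(pool)}
    observed = float(sims[[pool_index[m] for m in members]].mean())
    count = 0
    for subset in combinations(range(len(pool)), set_size):
        if sims[list(subset)].mean() >= observed:
            count += 1
    return (1 + count) / (1 + n_subsets)
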