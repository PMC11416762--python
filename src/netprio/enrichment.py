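"""Minimal over-representation analysis with Benjamini-Hochberg adjustment.

One hypergeometric upper-tail test per annotation set, BH-adjusted across
the emitted rows of a single collection (run collections such as separate
ontologies independently).
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from netprio.network_io import GeneSetCollection

__all__ = ["hypergeom_tail", "bh_adjust", "ora"]

logger = logging.getLogger(__name__)


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric arguments k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Sort ascending, multiply p_(i) by m/i, enforce monotonicity from the
    largest rank down, cap at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    # p*(m/m) can round one ulp below p; adjusted >= raw holds mathematically
    adjusted_sorted = np.maximum(adjusted_sorted, p[order])
    adjusted = np.empty(m, dtype=float)
    adjusted[order] = adjusted_sorted
    return adjusted.tolist()


def ora(
    query: Iterable[str],
    annotations: GeneSetCollection,
    universe: Iterable[str],
    alpha: float = 0.01,
    min_overlap: int = 1,
) -> pd.DataFrame:
    """Over-representation of a query gene list in each annotation set.

    Genes outside the universe are dropped (with a warning) from both the
    query and the annotation sets. Rows with overlap below ``min_overlap``
    are omitted; BH adjustment runs over exactly the emitted rows. Output is
    sorted by raw p-value, then term name.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("universe is empty")
    query_list = list(dict.fromkeys(query))
    query_set = {g for g in query_list if g in universe_set}
    dropped = len(query_list) - len(query_set)
    if dropped:
        logger.warning("%d query genes outside the universe were dropped", dropped)
    if not query_set:
        raise ValueError("no query genes remain after restriction to the universe")

    N = len(universe_set)
    n = len(query_set)
    rows = []
    for term, _description, genes in annotations.items():
        term_genes = {g for g in genes if g in universe_set}
        K = len(term_genes)
        k = len(term_genes & query_set)
        if k < min_overlap:
            continue
        rows.append((term, k, K, n, N, hypergeom_tail(k, K, n, N)))
    table = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p_raw"])
    if len(table):
        table["p_adjusted"] = bh_adjust(table["p_raw"].tolist())
        table["significant"] = table["p_adjusted"] < alpha
        table = table.sort_values(["p_raw", "term"], kind="stable").reset_index(drop=True)
    else:
        table["p_adjusted"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
    return table
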