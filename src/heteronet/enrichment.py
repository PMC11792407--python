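"""Hypergeometric over-representation tests against user-supplied gene-set
collections (GMT), with Benjamini-Hochberg adjustment.

Given a query gene list, a collection of sets and a background universe, the
enrichment p-value for a set of size K is the upper hypergeometric tail
P(X >= k) with X ~ Hypergeom(N, K, n) for overlap k and query size n.
Sets with adjusted p below alpha are flagged significant; an optional
gene-ratio screen (k / n below a threshold) can drop weakly covered sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gene_action import bh_fdr

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a background universe."""

    sets: dict
    universe: list
    dropped: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        universe = set(self.universe)
        if not universe:
            raise ValueError("empty universe")
        cleaned = {}
        for name, genes in self.sets.items():
            genes = list(dict.fromkeys(genes))  # dedupe, keep order
            inside = [g for g in genes if g in universe]
            n_dropped = len(genes) - len(inside)
            if n_dropped:
                self.dropped[name] = n_dropped
                logger.warning("set %s: %d gene(s) outside the universe dropped",
                               name, n_dropped)
            cleaned[name] = inside
        self.sets = cleaned


def hypergeometric_enrichment(query, collection: GeneSetCollection,
                              alpha: float = 0.05,
                              min_gene_ratio: float | None = None) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``query`` in every set.

    Query genes outside the universe are dropped with a log message. Returns
    one row per set with k, K, n, N, gene ratio, p, BH-adjusted p and the
    significance flag; when ``min_gene_ratio`` is given, sets with a smaller
    gene ratio are filtered out of the result.
    """
    universe = set(collection.universe)
    query = list(dict.fromkeys(query))
    if not query:
        raise ValueError("empty query gene list")
    inside = [g for g in query if g in universe]
    if len(inside) < len(query):
        logger.warning("%d query gene(s) outside the universe dropped",
                       len(query) - len(inside))
    if not inside:
        raise ValueError("no query genes inside the universe")
    n = len(inside)
    n_universe = len(universe)
    query_set = set(inside)
    rows = []
    for name, genes in collection.sets.items():
        k_set = len(genes)
        k = len(query_set.intersection(genes))
        p = float(stats.hypergeom.sf(k - 1, n_universe, k_set, n))
        rows.append({"set": name, "overlap": k, "set_size": k_set,
                     "query_size": n, "universe": n_universe,
                     "gene_ratio": k / n, "p": p})
    result = pd.DataFrame(rows)
    result["adjusted_p"] = bh_fdr(result["p"].to_numpy())
    result["significant"] = result["adjusted_p"] < alpha
    result = result.sort_values(["adjusted_p", "p", "set"]).reset_index(drop=True)
    if min_gene_ratio is not None:
        result = result[result["gene_ratio"] >= min_gene_ratio].reset_index(drop=True)
    return result
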