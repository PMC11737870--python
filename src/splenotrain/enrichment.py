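"""Gene-set over-representation analysis (hypergeometric ORA).

Given a discrete query list (e.g. training-induced DEGs), a background
universe (all genes surviving the expression floor in the relevant
dataset), and a GMT collection, each set is scored by the upper-tail
hypergeometric probability of its overlap with the query, BH-adjusted
across sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd
import scipy.stats

from .differential import bh_adjust
from .io import GeneSetCollection

__all__ = ["EnrichmentResult", "ora"]


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # per set: overlap, set_size, universe_size, query_size, p_value, q_value, genes
    fdr_q: float

    @property
    def significant(self) -> list[str]:
        return list(self.table.index[self.table["q_value"] <= self.fdr_q])

    def __len__(self) -> int:
        return len(self.table)


def ora(query: Sequence[str], universe: Sequence[str], sets: GeneSetCollection,
        fdr_q: float = 0.05) -> EnrichmentResult:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Query and sets are intersected with the universe first.  For a universe
    of N genes, a set of K, and a query of n, the p-value is
    P(overlap >= k) under sampling without replacement.  Results are sorted
    by (q, p, set name).
    """
    uni = list(dict.fromkeys(universe))
    uni_set = set(uni)
    q_genes = [g for g in dict.fromkeys(query) if g in uni_set]
    if not q_genes:
        raise ValueError("query is empty after intersection with the universe")
    N, n = len(uni), len(q_genes)
    q_set = set(q_genes)
    rows = []
    for name, genes in sets.sets.items():
        members = [g for g in genes if g in uni_set]
        K = len(members)
        overlap = sorted(g for g in members if g in q_set)
        k = len(overlap)
        p = float(scipy.stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"set": name, "overlap": k, "set_size": K,
                     "universe_size": N, "query_size": n, "p_value": min(p, 1.0),
                     "genes": ",".join(overlap)})
    table = pd.DataFrame(rows).set_index("set")
    table["q_value"] = bh_adjust(table["p_value"].to_numpy())
    table = table.sort_values(["q_value", "p_value", "set"], kind="stable")
    table = table[["overlap", "set_size", "universe_size", "query_size",
                   "p_value", "q_value", "genes"]]
    return EnrichmentResult(table=table, fdr_q=fdr_q)
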