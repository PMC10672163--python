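"""Hypergeometric overrepresentation analysis (ORA) of unranked gene lists.

Given a query gene list, a GMT collection, and a universe (by convention
all genes tested for differential expression), each set is scored by the
upper tail of the hypergeometric distribution, adjusted across sets by
Benjamini-Hochberg, and the top-k terms (default 12) are reported ranked by
statistical significance. No GO-hierarchy redundancy trimming is applied.
"""

from __future__ import annotations

import logging
from typing import Iterable

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import GeneSet

logger = logging.getLogger(__name__)

__all__ = ["hypergeom_p", "ora"]


def hypergeom_p(x: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= x).

    X counts query hits in a set of size ``K`` when ``n`` genes are drawn
    from a universe of ``N``. Computed from the survival function of
    ``scipy.stats.hypergeom`` (log-space stable for large N).
    """
    if not (0 <= x <= min(K, n)) or K > N or n > N or min(x, K, n, N) < 0:
        raise ValueError(f"inconsistent hypergeometric parameters x={x}, K={K}, n={n}, N={N}")
    if x == 0:
        return 1.0
    return float(stats.hypergeom.sf(x - 1, N, K, n))


def ora(
    query: Iterable[str],
    sets: list[GeneSet],
    universe: Iterable[str],
    top: int = 12,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Overrepresentation of ``query`` in each gene set, BH-adjusted.

    Query genes outside the universe are dropped with a logged count, and
    each set is intersected with the universe; sets empty after
    intersection are not tested. Returns the full result table and the
    top-``top`` slice, both sorted by ascending fdr with ties broken by
    pvalue then term_id.

    Columns: term_id, term_name, overlap, set_size, query_size,
    universe_size, pvalue, fdr, genes (sorted, semicolon-joined).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    outside = query - universe
    if outside:
        logger.info("ora: dropped %d query genes outside the universe", len(outside))
    query &= universe

    rows = []
    for gs in sets:
        members = gs.members & universe
        if not members:
            continue
        hit = query & members
        p = hypergeom_p(len(hit), len(members), len(query), len(universe))
        rows.append(
            {
                "term_id": gs.term_id,
                "term_name": gs.term_name,
                "overlap": len(hit),
                "set_size": len(members),
                "query_size": len(query),
                "universe_size": len(universe),
                "pvalue": p,
                "genes": ";".join(sorted(hit)),
            }
        )
    if not rows:
        empty = pd.DataFrame(
            columns=[
                "term_id", "term_name", "overlap", "set_size", "query_size",
                "universe_size", "pvalue", "fdr", "genes",
            ]
        )
        return empty, empty.copy()
    table = pd.DataFrame(rows)
    table["fdr"] = multipletests(table["pvalue"], method="fdr_bh")[1]
    table = table.sort_values(
        ["fdr", "pvalue", "term_id"], kind="mergesort"
    ).reset_index(drop=True)
    table = table[
        ["term_id", "term_name", "overlap", "set_size", "query_size",
         "universe_size", "pvalue", "fdr", "genes"]
    ]
    return table, table.head(top).copy()
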