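"""Hypergeometric over-representation of a query gene set.

Upper-tail hypergeometric test of a query set (e.g. the DE genes or the
literature-mined genes) against each term of a gene-set collection, with
BH correction across terms.  The universe defaults to the measured genes
rather than all annotated genes.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from .data_io import GeneSetCollection
from .differential import bh_adjust


def hypergeom_enrich(
    query: set[str],
    sets: GeneSetCollection,
    universe: set[str],
) -> pd.DataFrame:
    """Per-term over-representation p = P(X >= k), X ~ Hypergeom(N, K, n).

    N = universe size, K = term size within the universe, n = query size,
    k = overlap.  The query must be a subset of the universe; terms are
    intersected with the universe and empty intersections are dropped.
    Results carry BH-adjusted p across the tested terms, sorted by p.
    """
    if not universe:
        raise ValueError("empty universe")
    if not query:
        raise ValueError("empty query set")
    extra = query - universe
    if extra:
        raise ValueError(f"query genes outside the universe: {sorted(extra)[:5]}")
    restricted = sets.restricted_to(universe)
    n_universe = len(universe)
    n_query = len(query)
    rows = []
    for term, (name, members) in restricted:
        big_k = len(members)
        k = len(members & query)
        p = float(stats.hypergeom.sf(k - 1, n_universe, big_k, n_query))
        rows.append((term, name, big_k, k, n_query, n_universe, p))
    df = pd.DataFrame(
        rows, columns=["term", "name", "term_size", "overlap", "query_size", "universe_size", "p"]
    )
    df["p_adj"] = bh_adjust(df["p"].to_numpy()) if len(df) else []
    return df.sort_values(["p", "term"], ignore_index=True)
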