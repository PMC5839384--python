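"""Hypergeometric over-representation analysis of gene sets against a collection.

Each annotation term is tested for over-representation in a query gene set
relative to a background universe (by default, the genes that survived the
expression filter — the tested genes, not the whole annotation).  p-values
come from the same log-space hypergeometric upper tail used for the overlap
statistics; q-values are Benjamini-Hochberg adjusted across the tested terms
of one query only.
"""

from __future__ import annotations

import pandas as pd

from .de import bh_adjust
from .io import GeneSetCollection
from .overlap import hypergeom_overlap_pvalue

__all__ = ["overrepresentation_test"]

ENRICHMENT_COLUMNS = ["term_name", "k", "K", "n", "N", "expected", "p", "q"]


def overrepresentation_test(
    query,
    sets: GeneSetCollection,
    universe,
    min_term: int = 5,
    max_term: int = 2000,
) -> pd.DataFrame:
    """Test every eligible term for over-representation in ``query``.

    Terms are first intersected with the universe; terms whose intersected
    size falls outside ``[min_term, max_term]`` are skipped.  For a term of
    size K in a universe of N genes and a query of size n sharing k genes
    with the term, p = P(X >= k) for X ~ Hypergeometric(N, K, n).  Rows are
    sorted by (q, p, term id).

    Returns a DataFrame indexed by term id with columns
    ``term_name, k, K, n, N, expected, p, q``.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    stray = query - universe
    if stray:
        raise ValueError(f"query gene(s) not in universe: {sorted(stray)[:5]}")
    N, n = len(universe), len(query)

    rows = []
    for tid, (name, members) in sets:
        in_universe = set(members) & universe
        K = len(in_universe)
        if not (min_term <= K <= max_term):
            continue
        k = len(in_universe & query)
        p = hypergeom_overlap_pvalue(k, K, n, N)
        rows.append((tid, name, k, K, n, N, n * K / N, p))
    if not rows:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS, index=pd.Index([], name="term"))

    df = pd.DataFrame(
        rows, columns=["term", *ENRICHMENT_COLUMNS[:-1]]
    ).set_index("term")
    df["q"] = bh_adjust(df["p"].to_numpy())
    # sort by q, then p, then term id (stable sorts compose right-to-left)
    df = df.sort_index(kind="stable").sort_values(["q", "p"], kind="stable")
    return df
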