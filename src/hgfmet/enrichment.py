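"""Hypergeometric over-representation analysis with BH adjustment.

The query (screened differential genes) is tested against each gene set of
a collection within a fixed universe. The p-value is the upper tail
P(X >= k) of a hypergeometric draw of the query size from a universe
containing K set members; BH q-values are computed across all tested sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import GeneSetCollection
from .errors import InputError


def ora_test(query, gene_set, universe) -> tuple[int, int, int, int, float]:
    """Over-representation test of ``query`` against ``gene_set``.

    Returns (k, K, n, N, p): overlap, effective set size (set ∩ universe),
    query size, universe size and the hypergeometric upper-tail p-value.
    """
    universe = frozenset(universe)
    query = frozenset(query)
    if not universe:
        raise InputError("empty universe")
    if not query:
        raise InputError("empty query")
    if not query <= universe:
        raise InputError("query must be a subset of the universe")
    eff_set = frozenset(gene_set) & universe
    k = len(query & eff_set)
    K, n, N = len(eff_set), len(query), len(universe)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return k, K, n, N, min(max(p, 0.0), 1.0)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    query,
    collection: GeneSetCollection,
    universe,
    min_overlap: int = 2,
    top_n: int | None = None,
) -> pd.DataFrame:
    """ORA of a query against every set; one row per reported set.

    Sets overlapping the query by fewer than ``min_overlap`` genes are not
    reported. Rows are ordered by p ascending, then set size descending,
    then name; BH q-values are computed over all tested sets (including the
    unreported ones) so the adjustment is not biased by the overlap filter.
    """
    universe = frozenset(universe)
    rows = []
    for name, genes in collection:
        k, K, n, N, p = ora_test(query, genes, universe)
        overlap = sorted(frozenset(query) & frozenset(genes) & universe)
        rows.append((name, k, K, n, N, p, ",".join(overlap)))
    table = pd.DataFrame(
        rows,
        columns=["set_name", "overlap", "set_size", "query_size",
                 "universe_size", "p_value", "overlap_genes"],
    ).set_index("set_name")
    table["bh_q"] = bh_adjust(table["p_value"].to_numpy())
    table = table[table["overlap"] >= min_overlap]
    table = table.sort_values(
        ["p_value", "set_size", "set_name"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    if top_n is not None:
        table = table.head(top_n)
    return table
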