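"""Over-representation analysis of a gene set against an annotation collection.

For each annotation set the overlap k with the query is scored by the
hypergeometric upper tail P[X >= k] with X ~ Hypergeom(N, K, n), where N is
the universe size, K the annotated-set size inside the universe and n the
query size; p-values are BH-adjusted across all tested sets.  This is the
generic stand-in for pathway/GO enrichment of the disease-related genes
against the measured background.
"""

from __future__ import annotations

import logging

import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .errors import InputError
from .io_formats import GeneSetCollection

log = logging.getLogger(__name__)


def ora_test(query, annotations: GeneSetCollection, universe) -> pd.DataFrame:
    """One-sided over-representation test per annotation set.

    Returns a DataFrame indexed by set name with columns k, K, n, N,
    p_raw, fdr, sorted by p_raw.  Query genes outside the universe are
    dropped with a warning; annotation sets empty after intersection with
    the universe are skipped.
    """
    universe = set(universe)
    if not universe:
        raise InputError("empty universe")
    query = set(query)
    dropped = query - universe
    if dropped:
        log.warning("dropping %d query genes outside the universe", len(dropped))
    query &= universe
    if not query:
        raise InputError("query empty after intersection with universe")
    N, n = len(universe), len(query)
    rows = []
    for name, genes in annotations.items():
        members = set(genes) & universe
        K = len(members)
        if K == 0:
            continue
        k = len(members & query)
        # upper tail P[X >= k]
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((name, k, K, n, N, min(p, 1.0)))
    if not rows:
        raise InputError("no annotation set overlaps the universe")
    df = pd.DataFrame(rows, columns=["set", "k", "K", "n", "N", "p_raw"]).set_index("set")
    df["fdr"] = bh_adjust(df["p_raw"].to_numpy())
    return df.sort_values("p_raw", kind="mergesort")
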