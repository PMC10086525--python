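"""Over-representation tests and the Wilcoxon rank-sum utility.

Module enrichment follows the classic hypergeometric upper tail: for a query
of n genes drawn from a universe of N, of which K belong to the module and k
to the overlap, p = P(X >= k) with X ~ Hypergeometric(N, K, n). Only
over-representation is tested. BH adjustment runs across the collection and
modules are flagged enriched at fdr < 0.05.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from agesig.errors import AnalysisError

from agesig.diffassoc import bh_adjust

ENRICH_COLUMNS = ["set_name", "k", "K", "n", "N", "percent_overlap", "p", "fdr", "enriched"]


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrich(
    query: Iterable[str],
    collection: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query set in each module.

    Sets are intersected with the universe before testing; the query must be a
    subset of the universe. Returns one row per module with the overlap count,
    margins, percent overlap (of the module), p, BH fdr across the collection,
    and an ``enriched`` flag at fdr < ``fdr_max``.
    """
    universe = set(universe)
    query = set(query)
    if not universe:
        raise AnalysisError("empty universe")
    if not query:
        raise AnalysisError("empty query set")
    if not query <= universe:
        raise AnalysisError(
            f"query contains genes outside the universe: {sorted(query - universe)[:5]}"
        )
    N, n = len(universe), len(query)
    rows = []
    for name, members in collection.items():
        module = set(members) & universe
        K = len(module)
        k = len(module & query)
        p = hypergeom_upper_tail(k, N, K, n) if K else 1.0
        percent = 100.0 * k / K if K else 0.0
        rows.append((name, k, K, n, N, percent, p))
    out = pd.DataFrame(rows, columns=ENRICH_COLUMNS[:7])
    out["fdr"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    out["enriched"] = out["fdr"] < fdr_max
    return out


def overlap_test(set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]) -> pd.Series:
    """Upper-tail hypergeometric overlap of two sets within a universe.

    Query = A, module = B. Returns a Series with k, K, n, N, percent and p.
    """
    result = hypergeom_enrich(set_a, {"overlap": list(set_b)}, universe)
    return result.iloc[0]


def wilcoxon_rank_sum(x, y, exact_max_n: int = 10) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact by enumeration of rank assignments when the smaller sample has at
    most ``exact_max_n`` observations and the pooled data is tie-free;
    otherwise the normal approximation with midranks and tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise AnalysisError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if not has_ties and min(x.size, y.size) <= exact_max_n:
        method = "exact"
    else:
        method = "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)
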