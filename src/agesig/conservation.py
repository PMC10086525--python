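"""Cross-strain conservation scoring (MAG) and preranked GSEA.

The MAG (magnitude of association of genes) score summarizes how consistently
a gene associates with age across strains and tissues. Within each tissue t,
with per-strain significance ranks r_{g,s,t} (1 = most significant),

    m_{g,t} = (prod_s 1 / r_{g,s,t}) ** (1 / S)          (geometric mean of
                                                          inverse ranks)
    M_g     = sum_t m_{g,t}

and genes are finally ranked by descending M_g. The score is direction-blind;
a consensus direction (sign agreement of the per-stratum fold changes) is
tracked alongside. Genes filtered out of a stratum receive rank
n_tested + 1 there ("worst plus one"), so non-conservation is penalized
rather than silently dropped.

Preranked GSEA walks the MAG-descending gene list: set members increment the
running sum by |M_g|^w normalized over the set, non-members decrement by
1 / (N - n_set); ES is the maximum of the running sum (the walk ends at 0, so
ES >= 0). The null permutes gene labels (uniform placement of set positions),
p uses the add-one rule, and NES divides ES by the mean of the strictly
positive null ES values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd

from agesig.errors import AnalysisError, ValidationError

EXHAUSTIVE_LIMIT = 100_000


# ---------------------------------------------------------------------------
# ranking


def rank_stratum(results: pd.DataFrame) -> pd.DataFrame:
    """Rank one stratum's association results by significance.

    Ascending p-value; ties broken by larger |log2fc_span|, then lexicographic
    feature id. Returns a DataFrame indexed by feature with columns ``rank``
    (1 = most significant) and ``log2fc_span`` (kept for direction calls).
    """
    if len(results) == 0:
        raise AnalysisError("cannot rank an empty result table")
    if results["feature"].duplicated().any():
        dupes = results.loc[results["feature"].duplicated(), "feature"].tolist()
        raise ValidationError(f"duplicate feature ids in results: {dupes[:5]}")
    ordered = results.sort_values(
        by=["p", "log2fc_span", "feature"],
        key=lambda col: -col.abs() if col.name == "log2fc_span" else col,
    )
    table = pd.DataFrame(
        {
            "rank": np.arange(1, len(ordered) + 1),
            "log2fc_span": ordered["log2fc_span"].to_numpy(),
        },
        index=pd.Index(ordered["feature"], name="feature"),
    )
    return table


# ---------------------------------------------------------------------------
# MAG


def mag_scores(
    rank_tables: dict[str, pd.DataFrame],
    strains: list[str],
    tissues: list[str],
) -> pd.DataFrame:
    """Aggregate per-stratum ranks into per-gene MAG conservation scores.

    ``rank_tables`` maps stratum labels ``"strain:tissue"`` to the output of
    :func:`rank_stratum`; every (strain, tissue) combination must be present.
    Genes absent from a stratum get rank n_tested + 1 there. Returns a
    DataFrame indexed by gene with per-tissue scores ``m_<tissue>``,
    ``mag_total``, ``final_rank`` (descending total, ties lexicographic) and
    ``direction`` (+1 / -1 when the fold-change sign agrees across all strata
    where the gene was tested, else 0).
    """
    missing = [
        f"{s}:{t}" for s in strains for t in tissues if f"{s}:{t}" not in rank_tables
    ]
    if missing:
        raise AnalysisError(f"missing rank tables for strata: {missing}")

    universe = pd.Index(
        sorted(set().union(*(rank_tables[f"{s}:{t}"].index for s in strains for t in tissues))),
        name="gene",
    )
    n_strains = len(strains)

    out = pd.DataFrame(index=universe)
    log_m_total_by_tissue = {}
    for tissue in tissues:
        log_inv_sum = np.zeros(len(universe))
        for strain in strains:
            table = rank_tables[f"{strain}:{tissue}"]
            worst = len(table) + 1
            ranks = table["rank"].reindex(universe).fillna(worst).to_numpy()
            log_inv_sum += -np.log(ranks)
        m_t = np.exp(log_inv_sum / n_strains)
        log_m_total_by_tissue[tissue] = m_t
        out[f"m_{tissue}"] = m_t
    out["mag_total"] = sum(log_m_total_by_tissue.values())

    order = out.sort_values("mag_total", ascending=False, kind="mergesort").index
    # mergesort is stable; the index is pre-sorted lexicographically, so ties
    # resolve to lexicographic gene order
    final_rank = pd.Series(np.arange(1, len(order) + 1), index=order)
    out["final_rank"] = final_rank.reindex(universe).to_numpy()

    signs = pd.DataFrame(index=universe)
    for label, table in rank_tables.items():
        signs[label] = np.sign(table["log2fc_span"]).reindex(universe)
    pos = signs.gt(0) | signs.isna()
    neg = signs.lt(0) | signs.isna()
    tested_any = signs.notna().any(axis=1)
    direction = np.where(
        tested_any & pos.all(axis=1), 1, np.where(tested_any & neg.all(axis=1), -1, 0)
    )
    out["direction"] = direction
    return out


def mag_brute_force(
    rank_tables: dict[str, pd.DataFrame], strains: list[str], tissues: list[str]
) -> pd.Series:
    """Direct per-gene evaluation of the MAG formula (reference path for tests)."""
    universe = sorted(
        set().union(*(rank_tables[f"{s}:{t}"].index for s in strains for t in tissues))
    )
    totals = {}
    for gene in universe:
        total = 0.0
        for tissue in tissues:
            prod = 1.0
            for strain in strains:
                table = rank_tables[f"{strain}:{tissue}"]
                if gene in table.index:
                    r = float(table.loc[gene, "rank"])
                else:
                    r = len(table) + 1.0
                prod *= 1.0 / r
            total += prod ** (1.0 / len(strains))
        totals[gene] = total
    return pd.Series(totals)


# ---------------------------------------------------------------------------
# preranked GSEA


@dataclass
class GseaResult:
    """Result of a single preranked GSEA run."""

    set_name: str
    es: float
    nes: float
    p: float
    n_perm: int
    seed: int | None
    exhaustive: bool
    leading_edge: list[str]
    running: pd.DataFrame = field(repr=False)
    null_es: np.ndarray = field(repr=False, default=None)


def _es_from_positions(
    positions: np.ndarray, weights: np.ndarray, n_total: int
) -> np.ndarray:
    """ES for one or many placements of a gene set on a ranked list.

    ``positions``: (B, k) 0-based hit positions, sorted ascending per row;
    ``weights``: (B, k) matching |score|^w values. The running sum attains its
    maximum immediately after a hit or at the endpoint (value 0), so
    ES = max(0, max_i cumw_i - (pos_i - i) / (n_total - k)).
    """
    positions = np.atleast_2d(positions)
    weights = np.atleast_2d(weights).astype(float)
    k = positions.shape[1]
    wsum = weights.sum(axis=1, keepdims=True)
    uniform = wsum <= 0
    wnorm = np.where(uniform, 1.0 / k, weights / np.where(wsum > 0, wsum, 1.0))
    cum = np.cumsum(wnorm, axis=1)
    miss_step = 1.0 / (n_total - k)
    idx = np.arange(k)
    after_hit = cum - (positions - idx) * miss_step
    return np.maximum(after_hit.max(axis=1), 0.0)


def preranked_gsea(
    scores: pd.Series,
    gene_set,
    set_name: str = "gene_set",
    weight_exponent: float = 1.0,
    n_perm: int = 10_000,
    seed: int | None = 0,
    exhaustive: bool = False,
) -> GseaResult:
    """Preranked GSEA of one gene set against a score-ranked gene list.

    ``scores`` maps gene -> ranking score (e.g. ``mag_total``); the list is
    walked in descending score order (ties broken by gene id). The permutation
    null places the set's positions uniformly at random; with
    ``exhaustive=True`` and C(N, k) <= 100000 every placement is enumerated
    instead. p is one-sided for enrichment at the top with the add-one rule.
    """
    if scores.index.duplicated().any():
        raise ValidationError("duplicate gene ids in the ranked list")
    ordered = scores.sort_values(ascending=False, kind="mergesort")
    ordered = ordered.iloc[
        np.lexsort((ordered.index.to_numpy(), -ordered.to_numpy()))
    ]
    genes = ordered.index.to_numpy()
    values = np.abs(ordered.to_numpy(dtype=float)) ** weight_exponent
    n_total = len(genes)

    members = set(gene_set) & set(genes)
    if not members:
        raise AnalysisError(f"gene set {set_name!r} does not intersect the ranked list")
    if len(members) >= n_total:
        raise AnalysisError(f"gene set {set_name!r} covers the entire ranked list")
    hit_mask = np.isin(genes, list(members))
    positions = np.flatnonzero(hit_mask)
    k = len(positions)

    es_obs = float(_es_from_positions(positions, values[positions], n_total)[0])

    # running-score trace for reporting/plotting
    wsum = values[positions].sum()
    steps = np.where(
        hit_mask,
        (values / wsum) if wsum > 0 else (1.0 / k),
        0.0,
    )
    steps = np.where(hit_mask, steps, -1.0 / (n_total - k))
    running = np.cumsum(steps)
    running_df = pd.DataFrame(
        {"position": np.arange(1, n_total + 1), "gene": genes,
         "hit": hit_mask, "running_score": running}
    )
    peak = int(np.argmax(running)) if running.max() > 0 else int(np.argmax(running))
    leading_edge = [g for g in genes[: peak + 1][hit_mask[: peak + 1]]]

    if exhaustive and comb(n_total, k) <= EXHAUSTIVE_LIMIT:
        combos = np.array(list(itertools.combinations(range(n_total), k)))
        null_es = _es_from_positions(combos, values[combos], n_total)
        n_draws = len(combos)
        used_exhaustive = True
    else:
        if exhaustive:
            raise AnalysisError(
                f"exhaustive enumeration infeasible: C({n_total}, {k}) > {EXHAUSTIVE_LIMIT}"
            )
        rng = np.random.default_rng(seed)
        draws = np.empty((n_perm, k), dtype=int)
        for b in range(n_perm):
            draws[b] = np.sort(rng.choice(n_total, size=k, replace=False))
        null_es = _es_from_positions(draws, values[draws], n_total)
        n_draws = n_perm
        used_exhaustive = False

    p = (1.0 + np.sum(null_es >= es_obs)) / (1.0 + n_draws)
    positive = null_es[null_es > 0]
    nes = es_obs / positive.mean() if positive.size else float("nan")

    return GseaResult(
        set_name=set_name,
        es=es_obs,
        nes=float(nes),
        p=float(p),
        n_perm=n_draws,
        seed=seed,
        exhaustive=used_exhaustive,
        leading_edge=leading_edge,
        running=running_df,
        null_es=null_es,
    )
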