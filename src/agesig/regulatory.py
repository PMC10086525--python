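"""Peak- and footprint-level statistics for chromatin accessibility data.

All intervals are 0-based half-open; book-ended intervals ([100,200) and
[200,300)) do not overlap and are never merged. Footprint enrichment in
opening/closing peaks is a bias-naive hypergeometric test on
peak-contains-footprint indicators (binary, not count-weighted) against
age-stable background peaks; a TF is reported pan-stratum when its BH q-value
is below 0.05 in at least two strata.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd

from agesig.errors import AnalysisError
from agesig.diffassoc import bh_adjust
from agesig.settests import hypergeom_upper_tail

logger = logging.getLogger(__name__)

GROUP_COLS = ("strain", "tissue", "age_months")


# ---------------------------------------------------------------------------
# consensus peaks


def build_consensus_peaks(
    per_sample_peaks: dict[str, pd.DataFrame], min_support: int = 2
) -> pd.DataFrame:
    """Merge per-sample peaks into consensus regions with sample support.

    Intervals overlapping by >= 1 bp across any samples are merged into
    maximal regions; each region's support is the number of distinct samples
    contributing at least one interval. Regions with support below
    ``min_support`` are dropped. Output is sorted with columns
    chrom/start/end/name/support.
    """
    if not per_sample_peaks or all(len(df) == 0 for df in per_sample_peaks.values()):
        logger.warning("no input peaks; consensus set is empty")
        return pd.DataFrame(columns=["chrom", "start", "end", "name", "support"])
    frames = []
    for sample, df in per_sample_peaks.items():
        if len(df) == 0:
            continue
        frames.append(df[["chrom", "start", "end"]].assign(sample=sample))
    merged_rows = []
    stacked = pd.concat(frames, ignore_index=True)
    for chrom, group in stacked.groupby("chrom", sort=True):
        group = group.sort_values(["start", "end"], kind="mergesort")
        cur_start = cur_end = None
        cur_samples: set = set()
        for row in group.itertuples(index=False):
            if cur_start is None:
                cur_start, cur_end, cur_samples = row.start, row.end, {row.sample}
            elif row.start < cur_end:  # strict: book-ended intervals stay apart
                cur_end = max(cur_end, row.end)
                cur_samples.add(row.sample)
            else:
                merged_rows.append((chrom, cur_start, cur_end, len(cur_samples)))
                cur_start, cur_end, cur_samples = row.start, row.end, {row.sample}
        merged_rows.append((chrom, cur_start, cur_end, len(cur_samples)))
    out = pd.DataFrame(merged_rows, columns=["chrom", "start", "end", "support"])
    out = out[out["support"] >= min_support].reset_index(drop=True)
    out.insert(3, "name", [f"consensus_{i:05d}" for i in range(len(out))])
    return out


# ---------------------------------------------------------------------------
# nearest-TSS annotation


def annotate_nearest_tss(
    peaks: pd.DataFrame, tss: pd.DataFrame, promoter_window: int = 2000
) -> pd.DataFrame:
    """Assign each peak to the gene with the nearest TSS.

    Distance is measured from the peak center; the signed distance is
    (center - TSS) on + strand genes and (TSS - center) on - strand genes, so
    positive = downstream of the TSS. A peak is a promoter peak when
    |distance| <= ``promoter_window``. Exact distance ties resolve to the
    lexicographically smaller gene id; peaks on chromosomes absent from the
    TSS table are flagged unannotated.
    """
    if len(tss) == 0:
        raise AnalysisError("empty TSS table")
    by_chrom = {}
    for chrom, group in tss.reset_index().groupby("chrom"):
        group = group.sort_values(["pos", "gene"], kind="mergesort")
        by_chrom[chrom] = (
            group["pos"].to_numpy(dtype=float),
            group["gene"].to_numpy(dtype=object),
            group["strand"].to_numpy(dtype=object),
        )
    rows = []
    for row in peaks.itertuples(index=False):
        center = (row.start + row.end) / 2.0
        if row.chrom not in by_chrom:
            rows.append((row.name, np.nan, np.nan, False, False))
            continue
        pos, genes, strands = by_chrom[row.chrom]
        dmin = np.min(np.abs(pos - center))
        at_min = np.flatnonzero(np.abs(pos - center) == dmin)
        best = at_min[np.argmin(genes[at_min].astype(str))]
        sign = 1.0 if strands[best] == "+" else -1.0
        distance = (center - pos[best]) * sign
        rows.append((row.name, genes[best], distance, abs(distance) <= promoter_window, True))
    out = pd.DataFrame(
        rows, columns=["peak", "gene", "distance", "promoter", "annotated"]
    )
    return out


# ---------------------------------------------------------------------------
# footprints


def footprint_filter(calls: pd.DataFrame, min_purity: float = 0.9) -> pd.DataFrame:
    """Keep footprints with purity strictly above ``min_purity``."""
    return calls[calls["purity"] > min_purity].reset_index(drop=True)


def footprint_proportions(
    calls: pd.DataFrame, group_cols: tuple[str, ...] = GROUP_COLS
) -> pd.DataFrame:
    """Per-group TF footprint shares (counts normalized by the group total)."""
    if len(calls) == 0:
        logger.warning("no footprints; proportion table is empty")
        return pd.DataFrame(columns=[*group_cols, "tf", "count", "share"])
    counted = (
        calls.groupby([*group_cols, "tf"], sort=True).size().rename("count").reset_index()
    )
    totals = counted.groupby(list(group_cols))["count"].transform("sum")
    counted["share"] = counted["count"] / totals
    return counted


def _peaks_with_footprint(calls: pd.DataFrame, peaks: pd.DataFrame) -> dict[str, set]:
    """Map TF -> set of peak names containing >= 1 of its footprints."""
    hits: dict[str, set] = {}
    for chrom, peak_group in peaks.groupby("chrom"):
        peak_group = peak_group.sort_values("start", kind="mergesort")
        starts = peak_group["start"].to_numpy()
        ends = peak_group["end"].to_numpy()
        names = peak_group["name"].to_numpy(dtype=object)
        sub = calls[calls["chrom"] == chrom]
        if len(sub) == 0:
            continue
        fp_start = sub["start"].to_numpy()
        fp_end = sub["end"].to_numpy()
        tfs = sub["tf"].to_numpy(dtype=object)
        idx = np.searchsorted(starts, fp_start, side="right") - 1
        for j in range(len(sub)):
            for cand in (idx[j], idx[j] + 1):
                if 0 <= cand < len(starts) and fp_start[j] < ends[cand] and fp_end[j] > starts[cand]:
                    hits.setdefault(tfs[j], set()).add(names[cand])
    return hits


def footprint_peak_enrichment(
    calls: pd.DataFrame,
    opening_peaks: pd.DataFrame,
    closing_peaks: pd.DataFrame,
    background_peaks: pd.DataFrame,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric enrichment of TF footprints in opening/closing peaks.

    For each direction, foreground = the differential peak set and background
    = age-stable peaks. Per TF: N = fg + bg peaks, K = peaks containing the
    TF anywhere, n = fg peaks, k = fg peaks containing the TF; p is the upper
    tail, BH-adjusted across TFs within the direction.
    """
    if len(background_peaks) == 0:
        raise AnalysisError("background peak set is empty")
    out_frames = []
    for direction, fg in (("opening", opening_peaks), ("closing", closing_peaks)):
        if fg is None or len(fg) == 0:
            continue
        pool = pd.concat([fg, background_peaks], ignore_index=True)
        hits = _peaks_with_footprint(calls, pool)
        fg_names = set(fg["name"])
        N, n = len(pool), len(fg)
        rows = []
        for tf in sorted(set(calls["tf"])):
            tf_hits = hits.get(tf, set())
            K = len(tf_hits)
            k = len(tf_hits & fg_names)
            p = hypergeom_upper_tail(k, N, K, n)
            rows.append((direction, tf, k, K, n, N, p))
        df = pd.DataFrame(rows, columns=["direction", "tf", "k", "K", "n", "N", "p"])
        df["q"] = bh_adjust(df["p"].to_numpy())
        df["enriched"] = df["q"] < fdr_max
        out_frames.append(df)
    if not out_frames:
        return pd.DataFrame(columns=["direction", "tf", "k", "K", "n", "N", "p", "q", "enriched"])
    return pd.concat(out_frames, ignore_index=True)


def pan_stratum_support(
    enrichments: dict[str, pd.DataFrame], min_strata: int = 2, fdr_max: float = 0.05
) -> pd.DataFrame:
    """Count strata where each (TF, direction) is enriched (q < fdr_max).

    A TF is ``reported`` when supported by at least ``min_strata`` strata.
    """
    rows = []
    for stratum, df in enrichments.items():
        sig = df[df["q"] < fdr_max]
        for row in sig.itertuples(index=False):
            rows.append((row.tf, row.direction, stratum))
    if not rows:
        return pd.DataFrame(columns=["tf", "direction", "support", "reported"])
    table = pd.DataFrame(rows, columns=["tf", "direction", "stratum"])
    support = table.groupby(["tf", "direction"])["stratum"].nunique().rename("support")
    out = support.reset_index()
    out["reported"] = out["support"] >= min_strata
    return out


def shared_tf_sets(enriched: dict[str, set]) -> tuple[pd.DataFrame, int]:
    """Exact-combination intersection counts over per-stratum enriched TF sets.

    For every nonempty combination of strata, counts the TFs enriched in
    exactly that combination (upset-plot style). Returns the count table and
    the shared-by-all count.
    """
    if not enriched:
        raise AnalysisError("no strata provided")
    strata = sorted(enriched)
    all_tfs = set().union(*enriched.values())
    membership = {tf: frozenset(s for s in strata if tf in enriched[s]) for tf in all_tfs}
    rows = []
    for r in range(1, len(strata) + 1):
        for combo in combinations(strata, r):
            combo_set = frozenset(combo)
            count = sum(1 for m in membership.values() if m == combo_set)
            rows.append(("&".join(combo), r, count))
    table = pd.DataFrame(rows, columns=["combination", "n_strata", "count"])
    shared_all = int(table.loc[table["n_strata"] == len(strata), "count"].iloc[-1])
    return table, shared_all


def locus_footprint_counts(
    calls: pd.DataFrame,
    gene: str,
    tss: pd.DataFrame,
    window: int = 100_000,
    group_cols: tuple[str, ...] = GROUP_COLS,
) -> pd.DataFrame:
    """Count footprints overlapping [TSS - window, TSS + window) per TF per group."""
    if gene not in tss.index:
        raise AnalysisError(f"gene {gene!r} not in the TSS table")
    chrom = tss.loc[gene, "chrom"]
    pos = int(tss.loc[gene, "pos"])
    lo, hi = pos - window, pos + window
    in_window = (
        (calls["chrom"] == chrom) & (calls["start"] < hi) & (calls["end"] > lo)
    )
    sub = calls[in_window]
    if len(sub) == 0:
        return pd.DataFrame(columns=[*group_cols, "tf", "count"])
    return sub.groupby([*group_cols, "tf"], sort=True).size().rename("count").reset_index()


# ---------------------------------------------------------------------------
# aggregate cut profiles


def aggregate_cut_profile(
    cut_signal: np.ndarray, footprint_centers, flank: int = 100
) -> tuple[np.ndarray, int, int]:
    """Library-normalized mean cut-count profile around footprint centers.

    profile[d] for offset d in [-flank, +flank] is the mean per-base cut count
    across usable centers, divided by the group's total cut count. Centers
    closer than ``flank`` to a chromosome edge are skipped (their number is
    returned). Returns (profile of length 2 * flank + 1, n_used, n_skipped).
    """
    cut_signal = np.asarray(cut_signal)
    centers = np.asarray(footprint_centers, dtype=int)
    usable = centers[(centers >= flank) & (centers < len(cut_signal) - flank)]
    n_skipped = len(centers) - len(usable)
    if len(usable) == 0:
        raise AnalysisError("no footprint centers far enough from chromosome edges")
    total = float(cut_signal.sum())
    if total <= 0:
        raise AnalysisError("cut signal is empty")
    windows = cut_signal[usable[:, None] + np.arange(-flank, flank + 1)[None, :]]
    profile = windows.mean(axis=0) / total
    return profile, len(usable), n_skipped
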