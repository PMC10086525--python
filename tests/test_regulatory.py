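"""Interval algebra, footprint statistics, and profile extraction."""

import numpy as np
import pandas as pd
import pytest

from agesig import regulatory
from agesig.errors import AnalysisError
from agesig.settests import hypergeom_upper_tail
from test_settests import exact_upper_tail


def peaks_df(intervals, chrom="chr1"):
    return pd.DataFrame(
        [(chrom, s, e, f"p{i}", 1) for i, (s, e) in enumerate(intervals)],
        columns=["chrom", "start", "end", "name", "support"],
    )


def footprints_df(rows):
    """rows: (chrom, start, end, tf) with default group metadata."""
    return pd.DataFrame(
        [(c, s, e, tf, 0.95, "B6", "PBL", 18.0) for c, s, e, tf in rows],
        columns=["chrom", "start", "end", "tf", "purity",
                 "strain", "tissue", "age_months"],
    )


# ---------------------------------------------------------------------------
# consensus peaks


class TestConsensus:
    def test_overlap_merge_and_support_filter(self):
        per_sample = {
            "A": peaks_df([(100, 200)]),
            "B": peaks_df([(150, 250)]),
            "C": peaks_df([(300, 400)]),
        }
        out = regulatory.build_consensus_peaks(per_sample, min_support=2)
        assert len(out) == 1
        assert (out.loc[0, ["start", "end", "support"]] == [100, 250, 2]).all()

    def test_identical_peak_in_three_samples(self):
        per_sample = {s: peaks_df([(10, 50)]) for s in "ABC"}
        out = regulatory.build_consensus_peaks(per_sample, min_support=2)
        assert len(out) == 1 and out.loc[0, "support"] == 3

    def test_book_ended_intervals_not_merged(self):
        per_sample = {"A": peaks_df([(100, 200)]), "B": peaks_df([(200, 300)])}
        out = regulatory.build_consensus_peaks(per_sample, min_support=1)
        assert len(out) == 2

    def test_empty_input_gives_empty_set(self):
        out = regulatory.build_consensus_peaks({}, min_support=2)
        assert len(out) == 0

    def test_order_invariant_and_idempotent(self):
        rng = np.random.default_rng(0)
        per_sample = {
            s: peaks_df(sorted(
                (int(a), int(a) + int(w))
                for a, w in zip(rng.integers(0, 5000, 40), rng.integers(10, 200, 40))
            ))
            for s in "ABCD"
        }
        out1 = regulatory.build_consensus_peaks(per_sample, min_support=2)
        reversed_input = dict(reversed(list(per_sample.items())))
        out2 = regulatory.build_consensus_peaks(reversed_input, min_support=2)
        pd.testing.assert_frame_equal(out1, out2)

    def test_matches_brute_force_on_random_intervals(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            per_sample = {
                f"s{j}": peaks_df(sorted(
                    (int(a), int(a + w))
                    for a, w in zip(rng.integers(0, 2000, 15), rng.integers(5, 150, 15))
                ))
                for j in range(3)
            }
            out = regulatory.build_consensus_peaks(per_sample, min_support=1)
            # brute force: pool intervals, grow clusters by all-pairs overlap
            pool = [
                (r.start, r.end, s)
                for s, df in per_sample.items()
                for r in df.itertuples(index=False)
            ]
            clusters = []
            for iv in sorted(pool):
                for cl in clusters:
                    if iv[0] < cl["end"] and iv[1] > cl["start"]:
                        cl["start"] = min(cl["start"], iv[0])
                        cl["end"] = max(cl["end"], iv[1])
                        cl["samples"].add(iv[2])
                        break
                else:
                    clusters.append({"start": iv[0], "end": iv[1], "samples": {iv[2]}})
            expected = sorted((c["start"], c["end"], len(c["samples"])) for c in clusters)
            got = sorted(zip(out["start"], out["end"], out["support"]))
            assert got == expected


# ---------------------------------------------------------------------------
# nearest TSS


class TestNearestTss:
    def tss(self):
        return pd.DataFrame(
            {"chrom": ["chr1", "chr1", "chr1"], "pos": [1000, 5000, 1000],
             "strand": ["+", "+", "-"]},
            index=pd.Index(["gene1", "gene2", "zgene"], name="gene"),
        ).iloc[:2]

    def test_peak_on_tss(self):
        ann = regulatory.annotate_nearest_tss(peaks_df([(900, 1100)]), self.tss())
        assert ann.loc[0, "gene"] == "gene1"
        assert ann.loc[0, "distance"] == 0
        assert ann.loc[0, "promoter"]

    def test_downstream_positive_on_plus_strand(self):
        ann = regulatory.annotate_nearest_tss(peaks_df([(1400, 1600)]), self.tss())
        assert ann.loc[0, "gene"] == "gene1"
        assert ann.loc[0, "distance"] == 500

    def test_minus_strand_flips_sign(self):
        tss = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [1000], "strand": ["-"]},
            index=pd.Index(["gene1"], name="gene"),
        )
        ann = regulatory.annotate_nearest_tss(peaks_df([(1400, 1600)]), tss)
        assert ann.loc[0, "distance"] == -500  # upstream of a - strand gene

    def test_unknown_chromosome_flagged(self):
        ann = regulatory.annotate_nearest_tss(peaks_df([(0, 10)], chrom="chrX"),
                                              self.tss())
        assert not ann.loc[0, "annotated"]

    def test_distance_tie_takes_smaller_gene_id(self):
        tss = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "pos": [900, 1100], "strand": ["+", "+"]},
            index=pd.Index(["b", "a"], name="gene"),
        )
        ann = regulatory.annotate_nearest_tss(peaks_df([(950, 1050)]), tss)
        assert ann.loc[0, "gene"] == "a"

    def test_matches_brute_force_on_random_geometry(self):
        rng = np.random.default_rng(7)
        tss = pd.DataFrame(
            {"chrom": "chr1", "pos": rng.choice(10_000, 50, replace=False),
             "strand": rng.choice(["+", "-"], 50)},
            index=pd.Index([f"g{i:02d}" for i in range(50)], name="gene"),
        )
        peaks = peaks_df([
            (int(s), int(s) + 100) for s in rng.integers(0, 9_800, 200)
        ])
        ann = regulatory.annotate_nearest_tss(peaks, tss)
        for row, out in zip(peaks.itertuples(index=False), ann.itertuples(index=False)):
            center = (row.start + row.end) / 2
            dists = (tss["pos"] - center).abs()
            best = dists[dists == dists.min()].index.min()
            assert out.gene == best


# ---------------------------------------------------------------------------
# footprint statistics


class TestFootprints:
    def test_purity_filter_strict(self):
        calls = footprints_df([("chr1", 0, 10, "A")] * 3)
        calls["purity"] = [0.95, 0.90, 0.85]
        assert len(regulatory.footprint_filter(calls, 0.9)) == 1

    def test_proportions_sum_to_one(self):
        calls = footprints_df(
            [("chr1", i, i + 10, "A") for i in range(30)]
            + [("chr1", i, i + 10, "B") for i in range(70)]
        )
        out = regulatory.footprint_proportions(calls)
        assert out.set_index("tf")["share"].to_dict() == pytest.approx(
            {"A": 0.3, "B": 0.7}
        )

    def test_enrichment_tf_everywhere_p_one(self):
        fg = peaks_df([(i * 100, i * 100 + 50) for i in range(5)])
        bg = peaks_df([(10_000 + i * 100, 10_000 + i * 100 + 50) for i in range(5)])
        bg["name"] = [f"b{i}" for i in range(5)]
        calls = footprints_df(
            [("chr1", r.start + 5, r.start + 15, "A")
             for r in pd.concat([fg, bg]).itertuples(index=False)]
        )
        res = regulatory.footprint_peak_enrichment(calls, fg, fg.iloc[:0], bg)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_enrichment_matches_exact_tail_oracle(self):
        rng = np.random.default_rng(1)
        fg = peaks_df([(i * 200, i * 200 + 100) for i in range(100)])
        bg = peaks_df([(100_000 + i * 200, 100_000 + i * 200 + 100)
                       for i in range(1000)])
        bg["name"] = [f"bg{i}" for i in range(1000)]
        fg_hit = rng.choice(100, 20, replace=False)
        bg_hit = rng.choice(1000, 50, replace=False)
        calls = footprints_df(
            [("chr1", int(fg.loc[i, "start"]) + 5, int(fg.loc[i, "start"]) + 15, "A")
             for i in fg_hit]
            + [("chr1", int(bg.loc[i, "start"]) + 5, int(bg.loc[i, "start"]) + 15, "A")
               for i in bg_hit]
        )
        res = regulatory.footprint_peak_enrichment(calls, fg, fg.iloc[:0], bg)
        row = res[res["direction"] == "opening"].iloc[0]
        assert row["k"] == 20 and row["K"] == 70
        assert row["p"] == pytest.approx(exact_upper_tail(20, 1100, 70, 100), rel=1e-9)

    def test_zero_background_rejected(self):
        fg = peaks_df([(0, 100)])
        with pytest.raises(AnalysisError):
            regulatory.footprint_peak_enrichment(
                footprints_df([("chr1", 5, 15, "A")]), fg, fg.iloc[:0], fg.iloc[:0]
            )

    def test_pan_stratum_support_rule(self):
        def enr(qs):
            return pd.DataFrame(
                {"tf": list("AB"), "direction": "opening", "q": qs}
            )

        support = regulatory.pan_stratum_support(
            {"s1": enr([0.01, 0.2]), "s2": enr([0.02, 0.01]), "s3": enr([0.9, 0.9])}
        )
        row_a = support[support["tf"] == "A"].iloc[0]
        row_b = support[support["tf"] == "B"].iloc[0]
        assert row_a["support"] == 2 and row_a["reported"]
        assert row_b["support"] == 1 and not row_b["reported"]


class TestSharedSets:
    def test_hand_enumeration(self):
        table, shared = regulatory.shared_tf_sets(
            {"A": {"x", "y", "z"}, "B": {"y", "z"}, "C": {"z"}}
        )
        counts = table.set_index("combination")["count"].to_dict()
        assert shared == 1
        assert counts["A"] == 1 and counts["A&B"] == 1 and counts["A&B&C"] == 1
        assert counts["B"] == 0 and counts["C"] == 0

    def test_identical_sets_all_mass_on_full_combination(self):
        table, shared = regulatory.shared_tf_sets({"A": {"x", "y"}, "B": {"x", "y"}})
        assert shared == 2
        assert table.set_index("combination")["count"]["A"] == 0

    def test_disjoint_sets_share_nothing(self):
        _, shared = regulatory.shared_tf_sets({"A": {"x"}, "B": {"y"}})
        assert shared == 0


class TestLocusCounts:
    def tss(self):
        return pd.DataFrame(
            {"chrom": ["chr1"], "pos": [500_000], "strand": ["+"]},
            index=pd.Index(["Il6"], name="gene"),
        )

    def test_window_overlap_rules(self):
        calls = footprints_df([
            ("chr1", 450_000, 450_020, "A"),   # inside
            ("chr1", 399_990, 400_010, "B"),   # straddles the lower edge
            ("chr1", 200_000, 200_020, "C"),   # outside
        ])
        out = regulatory.locus_footprint_counts(calls, "Il6", self.tss())
        assert set(out["tf"]) == {"A", "B"}

    def test_unknown_gene_rejected(self):
        with pytest.raises(AnalysisError):
            regulatory.locus_footprint_counts(
                footprints_df([("chr1", 0, 10, "A")]), "nope", self.tss()
            )


class TestCutProfile:
    def test_constant_signal_flat_profile(self):
        signal = np.full(10_000, 3, dtype=np.int64)
        profile, used, skipped = regulatory.aggregate_cut_profile(
            signal, [5000, 6000], flank=50
        )
        assert np.allclose(profile, 3 / signal.sum())
        assert used == 2 and skipped == 0

    def test_unit_impulse_at_centers(self):
        signal = np.zeros(1000, dtype=np.int64)
        centers = [200, 500, 800]
        signal[centers] = 1
        profile, _, _ = regulatory.aggregate_cut_profile(signal, centers, flank=10)
        assert profile[10] == pytest.approx(1 / 3)
        assert profile[[0, 5, 20]].sum() == 0

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        signal = rng.poisson(2.0, size=5000)
        p1, _, _ = regulatory.aggregate_cut_profile(signal, [2500], flank=20)
        p2, _, _ = regulatory.aggregate_cut_profile(signal * 2, [2500], flank=20)
        assert np.allclose(p1, p2)

    def test_edge_centers_skipped_and_all_skipped_raises(self):
        signal = np.ones(100, dtype=np.int64)
        _, used, skipped = regulatory.aggregate_cut_profile(signal, [5, 50], flank=10)
        assert used == 1 and skipped == 1
        with pytest.raises(AnalysisError):
            regulatory.aggregate_cut_profile(signal, [2], flank=10)
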