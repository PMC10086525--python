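"""MAG rank aggregation and preranked GSEA against enumeration oracles."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from agesig import conservation
from agesig.errors import AnalysisError, ValidationError


def results_frame(genes, ps, lfcs=None):
    lfcs = lfcs if lfcs is not None else np.ones(len(genes))
    return pd.DataFrame({"feature": genes, "p": ps, "log2fc_span": lfcs})


def random_rank_tables(rng, strains, tissues, n_genes):
    tables = {}
    genes = [f"g{i}" for i in range(n_genes)]
    for s in strains:
        for t in tissues:
            perm = rng.permutation(n_genes) + 1
            tables[f"{s}:{t}"] = pd.DataFrame(
                {"rank": perm, "log2fc_span": rng.normal(size=n_genes)},
                index=pd.Index(genes, name="feature"),
            )
    return tables


# ---------------------------------------------------------------------------
# ranking


class TestRankStratum:
    def test_orders_by_p(self):
        table = conservation.rank_stratum(
            results_frame(["a", "b", "c"], [0.001, 0.01, 0.0005])
        )
        assert table.loc[["a", "b", "c"], "rank"].tolist() == [2, 3, 1]

    def test_tie_broken_by_larger_fold_change(self):
        table = conservation.rank_stratum(
            results_frame(["a", "b"], [0.01, 0.01], [0.5, 2.0])
        )
        assert table.loc["b", "rank"] == 1

    def test_full_tie_lexicographic(self):
        table = conservation.rank_stratum(
            results_frame(["b", "a"], [0.01, 0.01], [1.0, 1.0])
        )
        assert table.loc["a", "rank"] == 1

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValidationError):
            conservation.rank_stratum(results_frame(["a", "a"], [0.1, 0.2]))


# ---------------------------------------------------------------------------
# MAG


class TestMag:
    def test_rank_one_everywhere_gives_total_equal_to_tissue_count(self):
        tables = {}
        for s in ("A", "B"):
            for t in ("t1", "t2", "t3", "t4"):
                tables[f"{s}:{t}"] = pd.DataFrame(
                    {"rank": [1, 2], "log2fc_span": [1.0, 1.0]},
                    index=pd.Index(["hit", "other"], name="feature"),
                )
        mag = conservation.mag_scores(tables, ["A", "B"], ["t1", "t2", "t3", "t4"])
        assert mag.loc["hit", "mag_total"] == pytest.approx(4.0)
        assert mag.loc["hit", "final_rank"] == 1

    def test_geometric_mean_of_inverse_ranks(self):
        tables = {
            "A:t": pd.DataFrame({"rank": [2, 1], "log2fc_span": [1, 1]},
                                index=pd.Index(["g", "h"], name="feature")),
            "B:t": pd.DataFrame({"rank": [8, 1], "log2fc_span": [1, 1]},
                                index=pd.Index(["g", "h"], name="feature")),
        }
        mag = conservation.mag_scores(tables, ["A", "B"], ["t"])
        assert mag.loc["g", "m_t"] == pytest.approx(0.25)  # sqrt(1/2 * 1/8)

    def test_total_is_sum_over_tissues(self):
        tables = {}
        per_tissue = {"t1": 1, "t2": 2, "t3": 4, "t4": 8}  # m = 1/rank
        for t, r in per_tissue.items():
            tables[f"A:{t}"] = pd.DataFrame(
                {"rank": [r] + list(range(1, 10)), "log2fc_span": 1.0},
                index=pd.Index(["g"] + [f"x{i}" for i in range(9)], name="feature"),
            )
        mag = conservation.mag_scores(tables, ["A"], list(per_tissue))
        assert mag.loc["g", "mag_total"] == pytest.approx(1.875)

    def test_missing_stratum_table_listed(self):
        tables = {"A:t1": pd.DataFrame({"rank": [1], "log2fc_span": [1]},
                                       index=pd.Index(["g"], name="feature"))}
        with pytest.raises(AnalysisError, match="B:t1"):
            conservation.mag_scores(tables, ["A", "B"], ["t1"])

    def test_absent_gene_gets_worst_plus_one_rank(self):
        tables = {
            "A:t": pd.DataFrame({"rank": [1, 2], "log2fc_span": [1, 1]},
                                index=pd.Index(["g", "h"], name="feature")),
            "B:t": pd.DataFrame({"rank": [1], "log2fc_span": [1]},
                                index=pd.Index(["g"], name="feature")),
        }
        mag = conservation.mag_scores(tables, ["A", "B"], ["t"])
        # h absent from B:t (1 tested) -> rank 2 there
        assert mag.loc["h", "m_t"] == pytest.approx(np.sqrt((1 / 2) * (1 / 2)))

    def test_matches_brute_force_and_is_order_invariant(self):
        rng = np.random.default_rng(11)
        strains, tissues = ["A", "B"], ["t1", "t2", "t3", "t4"]
        tables = random_rank_tables(rng, strains, tissues, 300)
        mag = conservation.mag_scores(tables, strains, tissues)
        brute = conservation.mag_brute_force(tables, strains, tissues)
        assert np.allclose(mag["mag_total"].loc[brute.index], brute, atol=1e-12)
        swapped = conservation.mag_scores(tables, strains[::-1], tissues[::-1])
        assert np.allclose(mag["mag_total"], swapped["mag_total"].loc[mag.index],
                           atol=1e-12)

    def test_improving_any_rank_never_decreases_total(self):
        rng = np.random.default_rng(5)
        strains, tissues = ["A", "B"], ["t1", "t2"]
        tables = random_rank_tables(rng, strains, tissues, 20)
        mag = conservation.mag_scores(tables, strains, tissues)
        label = "A:t2"
        gene = "g7"
        better = {k: v.copy() for k, v in tables.items()}
        old_rank = better[label].loc[gene, "rank"]
        swap_gene = better[label].index[better[label]["rank"] == 1][0]
        better[label].loc[gene, "rank"] = 1
        better[label].loc[swap_gene, "rank"] = old_rank
        mag2 = conservation.mag_scores(better, strains, tissues)
        assert mag2.loc[gene, "mag_total"] >= mag.loc[gene, "mag_total"] - 1e-12

    def test_direction_consensus(self):
        tables = {
            "A:t": pd.DataFrame({"rank": [1, 2], "log2fc_span": [1.0, -1.0]},
                                index=pd.Index(["up", "dn"], name="feature")),
            "B:t": pd.DataFrame({"rank": [1, 2], "log2fc_span": [2.0, 1.0]},
                                index=pd.Index(["up", "dn"], name="feature")),
        }
        mag = conservation.mag_scores(tables, ["A", "B"], ["t"])
        assert mag.loc["up", "direction"] == 1
        assert mag.loc["dn", "direction"] == 0


# ---------------------------------------------------------------------------
# GSEA


def exhaustive_es_reference(n_total, k, weights=None):
    """Independent enumeration of ES over all placements (unweighted)."""
    out = []
    for combo in itertools.combinations(range(n_total), k):
        run, best = 0.0, 0.0
        for pos in range(n_total):
            if pos in combo:
                run += 1.0 / k
            else:
                run -= 1.0 / (n_total - k)
            best = max(best, run)
        out.append(best)
    return np.array(out)


class TestGsea:
    def scores(self, n):
        return pd.Series(
            np.linspace(2.0, 0.5, n), index=[f"g{i}" for i in range(n)]
        )

    def test_top_gene_singleton_unweighted_es_one(self):
        res = conservation.preranked_gsea(
            self.scores(3), {"g0"}, weight_exponent=0.0, exhaustive=True
        )
        assert res.es == pytest.approx(1.0)

    def test_worked_exhaustive_example(self):
        """N=4, set at the top two positions, unweighted: ES 1, p 2/7, NES 1.6."""
        res = conservation.preranked_gsea(
            self.scores(4), {"g0", "g1"}, weight_exponent=0.0, exhaustive=True
        )
        assert res.es == pytest.approx(1.0)
        assert res.p == pytest.approx(2.0 / 7.0)
        assert res.nes == pytest.approx(1.6)
        assert sorted(res.leading_edge) == ["g0", "g1"]

    def test_bottom_placement_es_zero_p_large(self):
        res = conservation.preranked_gsea(
            self.scores(5), {"g3", "g4"}, weight_exponent=0.0, exhaustive=True
        )
        ref = exhaustive_es_reference(5, 2)
        assert res.es == pytest.approx(0.0)
        assert res.p >= 0.5
        assert res.p == pytest.approx(
            (1 + np.sum(ref >= res.es)) / (1 + len(ref))
        )

    def test_exhaustive_matches_reference_enumeration(self):
        for n, k in [(6, 2), (7, 3), (8, 3)]:
            scores = self.scores(n)
            members = set(list(scores.index)[1 : 1 + k])
            res = conservation.preranked_gsea(
                scores, members, weight_exponent=0.0, exhaustive=True
            )
            ref = exhaustive_es_reference(n, k)
            obs_idx = tuple(range(1, 1 + k))
            combos = list(itertools.combinations(range(n), k))
            assert res.es == pytest.approx(ref[combos.index(obs_idx)], abs=1e-12)
            # ties at the observed ES are equality cases; compare with a float margin
            expected_p = (1 + np.sum(ref >= res.es - 1e-9)) / (1 + len(ref))
            assert res.p == pytest.approx(expected_p, abs=1e-12)

    @staticmethod
    def mc_target_from_exhaustive(ex, n_perm):
        """Expected value of the add-one MC p given the enumeration tail
        frequency q = #{null ES >= observed} / #placements."""
        q = (ex.p * (1 + ex.n_perm) - 1) / ex.n_perm
        se = np.sqrt(q * (1 - q) / n_perm)
        return (1 + n_perm * q) / (1 + n_perm), se

    def test_monte_carlo_p_converges_to_exhaustive(self):
        scores = self.scores(8)
        members = {"g0", "g2", "g5"}
        ex = conservation.preranked_gsea(scores, members, weight_exponent=0.0,
                                         exhaustive=True)
        mc = conservation.preranked_gsea(scores, members, weight_exponent=0.0,
                                         n_perm=4000, seed=123)
        target, se = self.mc_target_from_exhaustive(ex, mc.n_perm)
        assert abs(mc.p - target) <= 3 * se + 2 / mc.n_perm

    def test_leading_edge_subset_of_set(self):
        rng = np.random.default_rng(0)
        scores = pd.Series(rng.normal(size=50) ** 2,
                           index=[f"g{i}" for i in range(50)])
        members = {f"g{i}" for i in range(0, 50, 7)}
        res = conservation.preranked_gsea(scores, members, n_perm=500, seed=1)
        assert set(res.leading_edge) <= members
        assert 0 < res.p <= 1
        assert res.es <= 1 + 1e-12

    def test_empty_intersection_rejected(self):
        with pytest.raises(AnalysisError):
            conservation.preranked_gsea(self.scores(5), {"absent"})

    def test_whole_list_set_rejected(self):
        scores = self.scores(4)
        with pytest.raises(AnalysisError):
            conservation.preranked_gsea(scores, set(scores.index))

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(min_value=5, max_value=9), st.integers(min_value=1, max_value=3),
           st.randoms(use_true_random=False))
    def test_monte_carlo_within_binomial_error_of_enumeration(self, n, k, rnd):
        positions = sorted(rnd.sample(range(n), k))
        scores = self.scores(n)
        members = {f"g{i}" for i in positions}
        ex = conservation.preranked_gsea(scores, members, weight_exponent=0.0,
                                         exhaustive=True)
        mc = conservation.preranked_gsea(scores, members, weight_exponent=0.0,
                                         n_perm=3000, seed=42)
        target, se = self.mc_target_from_exhaustive(ex, mc.n_perm)
        assert abs(mc.p - target) <= 3 * se + 2 / mc.n_perm
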