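from itertools import combinations
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mesrec import (
    ClinicalTable,
    ExpressionMatrix,
    MetageneScores,
    RankSumResult,
    exact_null_count,
    exact_null_pvalue,
    genome_wide_scan,
    permutation_pvalue,
    rank_samples,
    rank_sum_statistic,
    rank_sum_test,
    select_long_recurrence,
)
from tests.conftest import scores_with_ranks


def make_scores(ids, values) -> MetageneScores:
    return MetageneScores(
        sample_ids=tuple(ids),
        score=np.asarray(values, dtype=float),
        signature_name="t",
        n_genes_used=1,
        n_genes_missing=0,
    )


class TestRankSamples:
    def test_ascending_rank_assignment(self):
        ranks = rank_samples(make_scores(["A", "B", "C"], [0.1, 0.5, 0.3]))
        assert ranks == {"A": 1, "C": 2, "B": 3}

    def test_ties_break_by_sample_id(self):
        ranks = rank_samples(make_scores(["B", "A"], [1.0, 1.0]))
        assert ranks == {"A": 1, "B": 2}

    def test_ranks_are_a_permutation(self):
        rng = np.random.default_rng(0)
        ranks = rank_samples(make_scores([f"S{i}" for i in range(30)], rng.random(30)))
        assert sorted(ranks.values()) == list(range(1, 31))

    def test_non_finite_scores_rejected(self):
        scores = MetageneScores.__new__(MetageneScores)
        object.__setattr__(scores, "sample_ids", ("A", "B"))
        object.__setattr__(scores, "score", np.array([1.0, np.inf]))
        with pytest.raises(ValueError, match="non-finite"):
            rank_samples(scores)


class TestRankSumStatistic:
    def test_study_configuration_sums_to_seventy(self):
        """Eight subset members at ranks 1,2,6,7,9,11,16,18 of 99 give 70."""
        scores, subset = scores_with_ranks([1, 2, 6, 7, 9, 11, 16, 18], n=99)
        result = rank_sum_statistic(rank_samples(scores), subset)
        assert result.rank_sum == 70
        assert result.member_ranks == (1, 2, 6, 7, 9, 11, 16, 18)

    def test_bottom_block_attains_minimum(self):
        scores, subset = scores_with_ranks(list(range(1, 6)), n=20)
        result = rank_sum_statistic(rank_samples(scores), subset)
        assert result.rank_sum == 5 * 6 // 2

    def test_small_example(self):
        scores, subset = scores_with_ranks([2, 5], n=5)
        assert rank_sum_statistic(rank_samples(scores), subset).rank_sum == 7

    def test_unknown_sample_rejected(self):
        scores, _ = scores_with_ranks([1], n=5)
        with pytest.raises(ValueError, match="not in the ranking"):
            rank_sum_statistic(rank_samples(scores), {"GHOST"})

    def test_result_invariants_enforced(self):
        with pytest.raises(ValueError):
            RankSumResult(n=5, k=2, member_ranks=(1, 1), rank_sum=2)
        with pytest.raises(ValueError):
            RankSumResult(n=5, k=2, member_ranks=(1, 2), rank_sum=4)


class TestSelectLongRecurrence:
    def test_three_year_filter(self, toy_clinical):
        assert select_long_recurrence(toy_clinical) == {"B", "D"}

    def test_all_null_gives_empty_set(self):
        clin = ClinicalTable.from_records(["A", "B"], [np.nan, np.nan])
        assert select_long_recurrence(clin) == set()

    def test_zero_threshold_selects_all_responders(self, toy_clinical):
        assert select_long_recurrence(toy_clinical, 0) == {"A", "B", "D"}


class TestExactNull:
    @pytest.mark.parametrize(
        "n,k,s,expected",
        [
            (4, 2, 3, 1),  # only {1,2}
            (5, 2, 5, 4),  # {1,2},{1,3},{1,4},{2,3}
            (99, 8, 35, 0),  # below the minimum possible sum 36
            (99, 8, 36, 1),  # exactly the minimal subset
        ],
    )
    def test_counts_small_cases(self, n, k, s, expected):
        assert exact_null_count(n, k, s) == expected

    def test_pvalue_examples(self):
        assert exact_null_pvalue(4, 2, 3) == pytest.approx(1 / 6)
        assert exact_null_pvalue(99, 8, 36) == pytest.approx(1 / comb(99, 8))

    @given(st.integers(2, 12), st.data())
    @settings(max_examples=30, deadline=None)
    def test_count_matches_enumeration(self, n, data):
        k = data.draw(st.integers(1, n))
        s = data.draw(st.integers(0, n * k))
        brute = sum(
            1 for c in combinations(range(1, n + 1), k) if sum(c) <= s
        )
        assert exact_null_count(n, k, s) == brute

    def test_pvalue_nondecreasing_in_s_and_one_at_max(self):
        n, k = 12, 4
        s_max = k * (2 * n - k + 1) // 2
        previous = 0.0
        for s in range(0, s_max + 1):
            p = exact_null_pvalue(n, k, s)
            assert p >= previous
            previous = p
        assert exact_null_pvalue(n, k, s_max) == 1.0

    def test_symmetry_of_subset_sum_distribution(self):
        # sum of a uniform k-subset is symmetric about (S_min + S_max) / 2
        for n, k in [(9, 3), (11, 4), (14, 5)]:
            s_min = k * (k + 1) // 2
            s_max = k * (2 * n - k + 1) // 2
            for s in range(s_min, s_max + 1):
                lhs = exact_null_count(n, k, s)
                rhs = comb(n, k) - exact_null_count(n, k, s_max + s_min - s - 1)
                assert lhs == rhs

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            exact_null_count(5, 6, 10)
        with pytest.raises(ValueError):
            exact_null_count(5, 2, -1)


class TestPermutationNull:
    def test_matches_exact_minimum_probability(self):
        p_exact = 1 / comb(10, 3)
        p_mc, _ = permutation_pvalue(10, 3, 6, n_perm=1_000_000, seed=11)
        se = np.sqrt(p_exact * (1 - p_exact) / 1_000_000)
        assert abs(p_mc - p_exact) <= 3 * se

    def test_same_seed_reproduces_estimate(self):
        a = permutation_pvalue(30, 5, 40, n_perm=50_000, seed=5)
        b = permutation_pvalue(30, 5, 40, n_perm=50_000, seed=5)
        assert a == b

    def test_maximum_rank_sum_gives_one(self):
        n, k = 12, 4
        s_max = k * (2 * n - k + 1) // 2
        p_mc, se = permutation_pvalue(n, k, s_max, n_perm=10_000, seed=0)
        assert p_mc == 1.0 and se == 0.0

    @pytest.mark.parametrize("n,k,s", [(10, 3, 12), (20, 6, 50), (15, 12, 100)])
    def test_converges_to_exact_null(self, n, k, s):
        p_exact = exact_null_pvalue(n, k, s)
        p_mc, _ = permutation_pvalue(n, k, s, n_perm=200_000, seed=7)
        se = np.sqrt(p_exact * (1 - p_exact) / 200_000)
        assert abs(p_mc - p_exact) <= 3 * se


class TestRankSumTest:
    def test_attaches_exact_and_mc_pvalues(self):
        scores, subset = scores_with_ranks([1, 2, 3], n=10)
        result = rank_sum_test(scores, subset, n_perm=100_000, seed=3)
        assert result.p_exact == pytest.approx(1 / comb(10, 3))
        se = np.sqrt(result.p_exact * (1 - result.p_exact) / 100_000)
        assert abs(result.p_mc - result.p_exact) <= 3 * se


class TestGenomeWideScan:
    def test_inverted_days_gene_ranks_first(self):
        """A gene anti-tracking recurrence time puts the long-recurrence
        subset at the bottom ranks; construct so the subset holds the two
        lowest values and check R = 1 + 2 = 3."""
        days = np.array([2000.0, 1500.0, 100.0, 50.0, 10.0])
        rng = np.random.default_rng(1)
        values = np.vstack([rng.normal(size=5) for _ in range(3)] + [-days])
        matrix = ExpressionMatrix.from_arrays(
            ["B1", "B2", "B3", "ANTI"], [f"S{i}" for i in range(5)], values
        )
        scan = genome_wide_scan(matrix, {"S0", "S1"})
        anti = scan.table[scan.table.gene_id == "ANTI"]
        assert anti["rank_sum"].item() == 3
        assert scan.table.iloc[0]["gene_id"] == "ANTI"

    def test_constant_gene_rank_sum_set_by_id_tiebreak(self):
        matrix = ExpressionMatrix.from_arrays(
            ["FLAT"], ["C", "A", "B"], [[1.0, 1.0, 1.0]]
        )
        scan = genome_wide_scan(matrix, {"A", "B"})
        # tie-break ranks: A=1, B=2, C=3
        assert scan.table["rank_sum"].item() == 3

    def test_single_gene_scan(self, toy_matrix):
        one = ExpressionMatrix(toy_matrix.data.iloc[:1])
        scan = genome_wide_scan(one, {"A"})
        assert len(scan.table) == 1

    def test_sorted_ascending_with_stable_gene_id_ties(self):
        rng = np.random.default_rng(2)
        matrix = ExpressionMatrix.from_arrays(
            [f"G{i}" for i in range(20)],
            [f"S{i}" for i in range(10)],
            rng.normal(size=(20, 10)),
        )
        scan = genome_wide_scan(matrix, {"S0", "S3", "S7"})
        sums = scan.table["rank_sum"].to_numpy()
        assert (np.diff(sums) >= 0).all()
        for _, block in scan.table.groupby("rank_sum"):
            assert list(block["gene_id"]) == sorted(block["gene_id"])
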