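"""Rank-sum association of a phenotype-defined sample subset with a score.

Samples are ranked by a score (rank 1 = lowest); the statistic is the sum of
the ranks occupied by a designated subset (here, patients whose tumors
recurred more than three years after therapy).  A low rank sum means the
subset concentrates at the low-score end.  Under the null hypothesis the
subset's ranks are a uniformly random k-subset of {1..n}, so the one-sided
p-value P(R <= r_obs) has an exact combinatorial form: the number of
k-element subsets of {1..n} with sum <= r_obs, divided by C(n, k).  That
count is computed by exact integer dynamic programming; a seeded Monte-Carlo
permutation estimate is provided as a cross-check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from math import comb, sqrt
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .core_types import ClinicalTable, ExpressionMatrix
from .metagene import MetageneScores

logger = logging.getLogger(__name__)

#: Default long-recurrence cutoff: three years in days.
THREE_YEARS_DAYS = 1095


@dataclass(frozen=True)
class RankSumResult:
    """Observed rank sum of a k-subset among n ranked samples, with nulls."""

    n: int
    k: int
    member_ranks: tuple[int, ...]
    rank_sum: int
    p_exact: Optional[float] = None
    p_mc: Optional[float] = None
    mc_se: Optional[float] = None
    n_perm: Optional[int] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 1 <= self.k <= self.n:
            raise ValueError("require 1 <= k <= n")
        ranks = tuple(sorted(int(r) for r in self.member_ranks))
        if len(set(ranks)) != self.k or ranks[0] < 1 or ranks[-1] > self.n:
            raise ValueError("member ranks must be k distinct integers in [1, n]")
        if sum(ranks) != self.rank_sum:
            raise ValueError("rank_sum must equal the sum of member_ranks")
        object.__setattr__(self, "member_ranks", ranks)


@dataclass(frozen=True)
class ScanResult:
    """Per-gene rank sums, sorted ascending by rank sum then gene ID."""

    table: pd.DataFrame  # columns: gene_id, rank_sum

    def __post_init__(self) -> None:
        expected = ["gene_id", "rank_sum"]
        if list(self.table.columns) != expected:
            raise ValueError(f"scan table must have columns {expected}")

    def top(self, n: int = 30) -> pd.DataFrame:
        return self.table.head(n)


def rank_samples(scores: MetageneScores) -> dict[str, int]:
    """Assign ranks 1..n ascending in score; ties break by sample ID."""
    values = np.asarray(scores.score, dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("cannot rank non-finite scores")
    if len(values) < 2:
        raise ValueError("ranking requires at least two samples")
    ids = np.asarray(scores.sample_ids, dtype=object)
    order = np.lexsort((ids, values))
    return {str(ids[j]): rank for rank, j in enumerate(order, start=1)}


def rank_sum_statistic(
    ranks: Mapping[str, int], phenotype_set: Iterable[str]
) -> RankSumResult:
    """Sum the ranks of ``phenotype_set`` under a rank assignment."""
    subset = list(phenotype_set)
    if not subset:
        raise ValueError("phenotype set must be nonempty")
    unknown = [s for s in subset if s not in ranks]
    if unknown:
        raise ValueError(f"samples not in the ranking: {sorted(unknown)[:5]}")
    member_ranks = tuple(sorted(ranks[s] for s in subset))
    return RankSumResult(
        n=len(ranks), k=len(subset), member_ranks=member_ranks, rank_sum=sum(member_ranks)
    )


def select_long_recurrence(
    clinical: ClinicalTable, threshold_days: float = THREE_YEARS_DAYS
) -> set[str]:
    """Responders whose recurrence came strictly after ``threshold_days``."""
    if len(clinical.data) == 0:
        raise ValueError("clinical table is empty")
    days = clinical.data["days_to_recurrence"]
    chosen = set(clinical.data.index[days.notna() & (days > threshold_days)])
    if not chosen:
        logger.warning(
            "select_long_recurrence: no responder beyond %s days", threshold_days
        )
    return chosen


def exact_null_count(n: int, k: int, s: int) -> int:
    """Number of k-element subsets of {1..n} with element sum <= s.

    Exact integer dynamic programming over items 1..n; no floating point.
    """
    n, k, s = int(n), int(k), int(s)
    if not 1 <= k <= n:
        raise ValueError("require 1 <= k <= n")
    if s < 0:
        raise ValueError("require s >= 0")
    s_min = k * (k + 1) // 2
    s_max = k * (2 * n - k + 1) // 2
    if s < s_min:
        return 0
    if s >= s_max:
        return comb(n, k)
    s_cap = min(s, s_max)
    # dp[j][t]: number of j-subsets of the items seen so far with sum t
    dp = [[0] * (s_cap + 1) for _ in range(k + 1)]
    dp[0][0] = 1
    for item in range(1, n + 1):
        for j in range(min(item, k), 0, -1):
            row, prev = dp[j], dp[j - 1]
            for t in range(s_cap, item - 1, -1):
                row[t] += prev[t - item]
    return sum(dp[k])


def exact_null_pvalue(n: int, k: int, s: int) -> float:
    """P(sum of k distinct uniform draws from {1..n} <= s), exactly."""
    count = exact_null_count(n, k, s)
    return float(Fraction(count, comb(n, k)))


def permutation_pvalue(
    n: int,
    k: int,
    observed_rank_sum: int,
    n_perm: int = 10_000_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo estimate of P(R <= observed) with its standard error.

    Each replicate draws k distinct ranks uniformly from {1..n} (a phenotype
    permutation).  Distinct draws come from vectorized rejection sampling
    when acceptance is high, otherwise from per-row partial sorts; both paths
    are deterministic for a fixed seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not 1 <= k <= n:
        raise ValueError("require 1 <= k <= n")
    rng = np.random.default_rng(seed)

    # acceptance probability of k iid draws from {1..n} being distinct
    log_acc = sum(np.log1p(-i / n) for i in range(k))
    use_rejection = log_acc > np.log(0.2)

    hits = 0
    remaining = n_perm
    while remaining > 0:
        if use_rejection:
            batch = int(min(2_000_000, remaining / np.exp(log_acc) * 1.1 + 1000))
            draws = rng.integers(1, n + 1, size=(batch, k))
            draws.sort(axis=1)
            ok = (np.diff(draws, axis=1) > 0).all(axis=1) if k > 1 else np.ones(batch, bool)
            sums = draws.sum(axis=1)[ok]
        else:
            batch = int(min(max(1, 2_000_000 // n), remaining))
            keys = rng.random((batch, n))
            part = np.argpartition(keys, k - 1, axis=1)[:, :k] if k < n else (
                np.tile(np.arange(n), (batch, 1))
            )
            sums = (part + 1).sum(axis=1)
        take = sums[:remaining]
        hits += int((take <= observed_rank_sum).sum())
        remaining -= len(take)

    p_hat = hits / n_perm
    se = sqrt(p_hat * (1.0 - p_hat) / n_perm)
    return p_hat, se


def rank_sum_test(
    scores: MetageneScores,
    phenotype_set: Iterable[str],
    n_perm: int = 0,
    seed: int = 0,
) -> RankSumResult:
    """Full test: rank, sum the subset's ranks, attach exact (and MC) nulls."""
    ranks = rank_samples(scores)
    base = rank_sum_statistic(ranks, phenotype_set)
    p_exact = exact_null_pvalue(base.n, base.k, base.rank_sum)
    p_mc = mc_se = None
    if n_perm > 0:
        p_mc, mc_se = permutation_pvalue(base.n, base.k, base.rank_sum, n_perm, seed)
    return RankSumResult(
        n=base.n,
        k=base.k,
        member_ranks=base.member_ranks,
        rank_sum=base.rank_sum,
        p_exact=p_exact,
        p_mc=p_mc,
        mc_se=mc_se,
        n_perm=n_perm if n_perm > 0 else None,
        seed=seed if n_perm > 0 else None,
    )


def genome_wide_scan(
    matrix: ExpressionMatrix, phenotype_set: Iterable[str]
) -> ScanResult:
    """Rank sum of the phenotype subset for every gene, scanned exhaustively.

    For each gene, samples are ranked by that gene's expression with the same
    sample-ID tie rule as :func:`rank_samples`.
    """
    subset = set(phenotype_set)
    if not subset:
        raise ValueError("phenotype set must be nonempty")
    sample_ids = matrix.sample_ids
    unknown = subset - set(sample_ids)
    if unknown:
        raise ValueError(f"samples not in the matrix: {sorted(unknown)[:5]}")

    ids = np.asarray(sample_ids, dtype=object)
    id_order = np.argsort(ids, kind="stable")  # lexicographic tie-break key
    tie_key = np.empty(len(ids), dtype=np.int64)
    tie_key[id_order] = np.arange(len(ids))
    member = np.array([s in subset for s in sample_ids])

    values = matrix.values
    n = len(sample_ids)
    ranks = np.empty(n, dtype=np.int64)
    records = []
    for gi, gene in enumerate(matrix.gene_ids):
        order = np.lexsort((tie_key, values[gi]))
        ranks[order] = np.arange(1, n + 1)
        records.append((str(gene), int(ranks[member].sum())))

    table = pd.DataFrame(records, columns=["gene_id", "rank_sum"])
    table = table.sort_values(
        ["rank_sum", "gene_id"], kind="mergesort", ignore_index=True
    )
    return ScanResult(table=table)
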