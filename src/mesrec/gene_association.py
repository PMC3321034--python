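"""Gene-level association utilities.

Pearson correlation with a t-distribution p-value, mutual-information
ranking of all genes against a target gene, linear fold-change ranking
between two sample groups, and hypergeometric-tail enrichment of a gene
signature within a top-gene list.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from math import lgamma, log2
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_types import ExpressionMatrix, normalize_gene_id

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric upper-tail enrichment of K signature genes in a list."""

    universe_size: int
    signature_size: int
    list_size: int
    hits: int
    tail_p: float

    def __post_init__(self) -> None:
        if self.hits > min(self.signature_size, self.list_size):
            raise ValueError("hits cannot exceed min(signature size, list size)")
        if not 0.0 <= self.tail_p <= 1.0:
            raise ValueError("tail probability out of [0, 1]")


@dataclass(frozen=True)
class GeneRanking:
    """Genes sorted descending by a score; ties break by gene ID."""

    table: pd.DataFrame  # columns: gene_id, score
    score_kind: str  # "mutual_information_bits" | "linear_fold_change"

    def __post_init__(self) -> None:
        if list(self.table.columns) != ["gene_id", "score"]:
            raise ValueError("ranking table must have columns [gene_id, score]")

    def top(self, n: int) -> list[str]:
        return self.table["gene_id"].head(n).tolist()


def pearson_pvalue(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r with the two-sided t-distribution p-value.

    p comes from t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least three observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return r, min(1.0, p)


def _equal_frequency_bins(x: np.ndarray, bins: int) -> np.ndarray:
    """Assign bin indices by sorted position: floor(pos * B / n).

    Deterministic under ties (stable sort by value then original position)
    and yields bin counts as equal as n allows.
    """
    n = len(x)
    order = np.argsort(x, kind="stable")
    idx = np.empty(n, dtype=np.int64)
    idx[order] = (np.arange(n) * bins) // n
    return idx


def mutual_information(
    x: Sequence[float], y: Sequence[float], bins: int = 8
) -> float:
    """Plug-in mutual information in bits with Miller-Madow bias correction.

    Both variables are discretized into ``bins`` equal-frequency bins, which
    makes the estimate invariant to strictly monotone transforms.  A constant
    input yields 0 bits with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = len(x)
    if n < 4 * bins:
        raise ValueError(f"need at least {4 * bins} observations for {bins} bins")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: mutual information is 0", stacklevel=2)
        return 0.0

    bx = _equal_frequency_bins(x, bins)
    by = _equal_frequency_bins(y, bins)
    joint = np.zeros((bins, bins), dtype=np.int64)
    np.add.at(joint, (bx, by), 1)

    pxy = joint / n
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    nz = pxy > 0
    mi = float((pxy[nz] * np.log2(pxy[nz] / np.outer(px, py)[nz])).sum())

    # Miller-Madow: H_mm = H + (occupied-1)/(2n ln2); propagate through I = Hx+Hy-Hxy
    occ_x = int((px > 0).sum())
    occ_y = int((py > 0).sum())
    occ_xy = int(nz.sum())
    mi += ((occ_x - 1) + (occ_y - 1) - (occ_xy - 1)) / (2.0 * n * np.log(2.0))
    return max(0.0, mi)


def mi_rank_genes(
    matrix: ExpressionMatrix, target_gene: str, bins: int = 8
) -> GeneRanking:
    """Rank every other gene by mutual information with the target gene."""
    present, _ = matrix.find_genes([target_gene])
    if not present:
        raise ValueError(f"target gene {target_gene!r} not in the matrix")
    target_row = present[0]
    target = matrix.data.loc[target_row].to_numpy()
    records = []
    for gene in matrix.gene_ids:
        if gene == target_row:
            continue
        mi = mutual_information(matrix.data.loc[gene].to_numpy(), target, bins=bins)
        records.append((str(gene), mi))
    table = pd.DataFrame(records, columns=["gene_id", "score"])
    table = table.sort_values(
        ["score", "gene_id"], ascending=[False, True], kind="mergesort", ignore_index=True
    )
    return GeneRanking(table=table, score_kind="mutual_information_bits")


def log2_fold_change_ranking(
    matrix: ExpressionMatrix,
    group_a: Iterable[str],
    group_b: Iterable[str],
) -> GeneRanking:
    """Linear fold change 2^(mean_A - mean_B) per gene, sorted descending."""
    a = list(group_a)
    b = list(group_b)
    if not a or not b:
        raise ValueError("both groups must be nonempty")
    if set(a) & set(b):
        raise ValueError("groups overlap")
    missing = (set(a) | set(b)) - set(matrix.sample_ids)
    if missing:
        raise ValueError(f"samples not in the matrix: {sorted(missing)[:5]}")
    mean_a = matrix.data.loc[:, a].to_numpy().mean(axis=1)
    mean_b = matrix.data.loc[:, b].to_numpy().mean(axis=1)
    fc = np.exp2(mean_a - mean_b)
    table = pd.DataFrame({"gene_id": [str(g) for g in matrix.gene_ids], "score": fc})
    table = table.sort_values(
        ["score", "gene_id"], ascending=[False, True], kind="mergesort", ignore_index=True
    )
    return GeneRanking(table=table, score_kind="linear_fold_change")


def _log_comb(n: int, k: int) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def hypergeometric_enrichment(
    universe_size: int, signature_size: int, list_size: int, hits: int
) -> EnrichmentResult:
    """Upper-tail P(X >= hits) for X ~ Hypergeometric(N, K, n).

    Exact summation of the hypergeometric pmf with log-space binomial
    coefficients, stable down to ~1e-300.
    """
    N, K, n, k = universe_size, signature_size, list_size, hits
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("require 0 <= K <= N and 0 <= n <= N")
    if not 0 <= k <= min(K, n):
        raise ValueError("require 0 <= hits <= min(signature size, list size)")
    log_denominator = _log_comb(N, n)
    tail = 0.0
    for j in range(k, min(K, n) + 1):
        if n - j > N - K:
            continue
        tail += np.exp(_log_comb(K, j) + _log_comb(N - K, n - j) - log_denominator)
    return EnrichmentResult(
        universe_size=N,
        signature_size=K,
        list_size=n,
        hits=k,
        tail_p=min(1.0, tail),
    )


def signature_overlap_enrichment(
    universe_size: int,
    signature_genes: Iterable[str],
    top_list: Iterable[str],
) -> EnrichmentResult:
    """Convenience wrapper: count case-insensitive overlap, then the tail p."""
    sig = {normalize_gene_id(g) for g in signature_genes}
    top = [normalize_gene_id(g) for g in top_list]
    hits = sum(1 for g in top if g in sig)
    return hypergeometric_enrichment(universe_size, len(sig), len(top), hits)
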