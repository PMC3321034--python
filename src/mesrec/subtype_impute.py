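"""k-nearest-neighbor imputation of missing tumor-subtype labels.

Distances are Euclidean over the subtype signature genes after z-scoring
each gene across all samples (so high-variance genes do not dominate), and
each unlabeled sample takes the majority label of its k nearest labeled
neighbors.  Vote ties resolve to the label of the nearest neighbor carrying
one of the tied labels; neighbor order itself is made deterministic by
breaking distance ties on the labeled sample's ID.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
from scipy.spatial.distance import cdist

from .core_types import ExpressionMatrix, GeneSignature

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SubtypeAssignment:
    """One sample's label, its origin, and (if imputed) the neighbor votes."""

    sample_id: str
    label: str
    source: str  # "given" | "imputed"
    neighbor_vote_counts: Optional[dict[str, int]] = None

    def __post_init__(self) -> None:
        if self.source not in {"given", "imputed"}:
            raise ValueError("source must be 'given' or 'imputed'")
        if self.source == "imputed" and self.neighbor_vote_counts is None:
            raise ValueError("imputed assignments must carry vote counts")


def knn_impute_subtypes(
    matrix: ExpressionMatrix,
    labeled: Mapping[str, str],
    subtype_genes: GeneSignature,
    k: int = 10,
) -> list[SubtypeAssignment]:
    """Impute missing subtype labels by k-nearest neighbors.

    Samples present in ``labeled`` pass through unchanged; every other
    sample of the matrix is assigned the majority label among its ``k``
    nearest labeled samples.  Returns assignments in matrix sample order.
    """
    sample_ids = matrix.sample_ids
    unknown = set(labeled) - set(sample_ids)
    if unknown:
        raise ValueError(f"labeled samples not in the matrix: {sorted(unknown)[:5]}")
    labeled_ids = sorted(labeled)
    if len(labeled_ids) < k:
        raise ValueError(
            f"only {len(labeled_ids)} labeled samples but k={k}; use a smaller k"
        )

    present, missing = matrix.find_genes(subtype_genes.gene_ids)
    if not present:
        raise ValueError("no subtype signature genes present in the matrix")
    if missing:
        logger.warning(
            "knn_impute_subtypes: %d/%d subtype genes missing from matrix",
            len(missing),
            len(subtype_genes),
        )

    sub = matrix.data.loc[present]
    values = sub.to_numpy()
    sd = values.std(axis=1, ddof=0)
    keep = sd > 0
    if not keep.all():
        logger.warning("dropping %d constant subtype genes before z-scoring", int((~keep).sum()))
        if not keep.any():
            raise ValueError("all subtype genes are constant; cannot compute distances")
    z = (values[keep] - values[keep].mean(axis=1, keepdims=True)) / sd[keep, None]

    col_index = {s: i for i, s in enumerate(sample_ids)}
    labeled_cols = np.array([col_index[s] for s in labeled_ids])
    labels_arr = np.array([labeled[s] for s in labeled_ids], dtype=object)

    unlabeled_ids = [s for s in sample_ids if s not in labeled]
    assignments: dict[str, SubtypeAssignment] = {
        s: SubtypeAssignment(sample_id=s, label=str(labeled[s]), source="given")
        for s in labeled_ids
    }

    if unlabeled_ids:
        unlabeled_cols = np.array([col_index[s] for s in unlabeled_ids])
        dist = cdist(z[:, unlabeled_cols].T, z[:, labeled_cols].T)
        # stable neighbor order: distance, then labeled sample ID (already sorted)
        order = np.argsort(dist, axis=1, kind="stable")
        for row, sample in enumerate(unlabeled_ids):
            nearest = order[row, :k]
            votes: dict[str, int] = {}
            for j in nearest:
                lbl = str(labels_arr[j])
                votes[lbl] = votes.get(lbl, 0) + 1
            top = max(votes.values())
            tied = {lbl for lbl, c in votes.items() if c == top}
            if len(tied) == 1:
                winner = tied.pop()
            else:
                winner = next(str(labels_arr[j]) for j in nearest if str(labels_arr[j]) in tied)
            assignments[sample] = SubtypeAssignment(
                sample_id=sample, label=winner, source="imputed", neighbor_vote_counts=votes
            )

    return [assignments[s] for s in sample_ids]
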