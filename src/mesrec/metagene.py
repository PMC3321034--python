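"""Metagene scoring and centroid-difference signature construction.

A metagene score is the unweighted per-sample mean of log2 normalized
expression over a signature's genes: a single number summarizing how far a
sample has progressed through the coordinated transcriptional program.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_types import (
    ExpressionMatrix,
    GeneSignature,
    SubtypeCentroids,
    normalize_gene_id,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MetageneScores:
    """Per-sample metagene scores plus gene-coverage bookkeeping."""

    sample_ids: tuple[str, ...]
    score: np.ndarray
    signature_name: str
    n_genes_used: int
    n_genes_missing: int

    def __post_init__(self) -> None:
        score = np.asarray(self.score, dtype=float)
        if score.shape != (len(self.sample_ids),):
            raise ValueError("one score per sample required")
        if not np.isfinite(score).all():
            raise ValueError("metagene scores must be finite")
        object.__setattr__(self, "score", score)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.sample_ids, self.score.tolist()))


def compute_metagene(matrix: ExpressionMatrix, signature: GeneSignature) -> MetageneScores:
    """Average the signature genes' log2 expression per sample.

    Signature genes absent from the matrix are counted and logged; at least
    one must be present.
    """
    present, missing = matrix.find_genes(signature.gene_ids)
    if not present:
        raise ValueError(
            f"none of the {len(signature)} genes of signature "
            f"{signature.name!r} are present in the matrix"
        )
    if missing:
        logger.warning(
            "compute_metagene: %d/%d genes of %r missing from matrix",
            len(missing),
            len(signature),
            signature.name,
        )
    scores = matrix.data.loc[present].to_numpy().mean(axis=0)
    return MetageneScores(
        sample_ids=tuple(matrix.sample_ids),
        score=scores,
        signature_name=signature.name,
        n_genes_used=len(present),
        n_genes_missing=len(missing),
    )


def build_centroid_ranked_signature(
    centroids: SubtypeCentroids,
    target_subtype: str,
    candidate_genes: list[str] | tuple[str, ...] | None = None,
    top_k: int | None = None,
    contrast: str = "mean_of_others",
) -> GeneSignature:
    """Rank candidate genes by target-vs-rest centroid difference; keep top_k.

    The score for a gene is its centroid value in ``target_subtype`` minus
    the mean of the other three subtypes' centroid values
    (``contrast="mean_of_others"``), or minus the overall mean across all
    four (``contrast="overall_mean"``).  Ties break by gene symbol.
    """
    if target_subtype not in centroids.subtype_names:
        raise ValueError(
            f"unknown subtype {target_subtype!r}; centroids define {centroids.subtype_names}"
        )
    if contrast not in {"mean_of_others", "overall_mean"}:
        raise ValueError(f"unknown contrast {contrast!r}")

    frame = centroids.to_frame()
    if candidate_genes is None:
        candidates = list(centroids.gene_ids)
    else:
        lookup = {normalize_gene_id(g): g for g in centroids.gene_ids}
        candidates = []
        for g in candidate_genes:
            row = lookup.get(normalize_gene_id(g))
            if row is None:
                raise ValueError(f"candidate gene {g!r} not among centroid genes")
            candidates.append(row)
    if top_k is None:
        top_k = len(candidates)
    if not 1 <= top_k <= len(candidates):
        raise ValueError(f"top_k must be in [1, {len(candidates)}]")

    target = frame.loc[candidates, target_subtype].to_numpy()
    others = [s for s in centroids.subtype_names if s != target_subtype]
    if contrast == "mean_of_others":
        rest = frame.loc[candidates, others].to_numpy().mean(axis=1)
    else:
        rest = frame.loc[candidates].to_numpy().mean(axis=1)
    diff = target - rest

    order = sorted(range(len(candidates)), key=lambda i: (-diff[i], candidates[i]))
    chosen = tuple(candidates[i] for i in order[:top_k])
    return GeneSignature(
        name=f"{target_subtype.lower()}_centroid_top{top_k}",
        gene_ids=chosen,
        provenance=(
            f"top {top_k} genes by {target_subtype} centroid minus "
            f"{'mean of other subtypes' if contrast == 'mean_of_others' else 'overall mean'}"
        ),
    )
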