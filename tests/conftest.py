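import numpy as np
import pandas as pd
import pytest

from mesrec import ClinicalTable, ExpressionMatrix, GeneSignature


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples with distinct, hand-readable values."""
    return ExpressionMatrix.from_arrays(
        ["GENE1", "GENE2", "GENE3"],
        ["A", "B", "C", "D"],
        np.array(
            [
                [1.0, 2.0, 3.0, 4.0],
                [4.0, 3.0, 2.0, 1.0],
                [0.5, 0.5, 0.5, 0.5],
            ]
        ),
    )


@pytest.fixture
def toy_clinical() -> ClinicalTable:
    """Four samples: two responders, one long-recurrence, one non-responder."""
    return ClinicalTable.from_records(
        ["A", "B", "C", "D"],
        [100.0, 1100.0, np.nan, 2000.0],
    )


@pytest.fixture
def two_gene_signature() -> GeneSignature:
    return GeneSignature(name="toy", gene_ids=("GENE1", "GENE2"))


def scores_with_ranks(member_ranks: list[int], n: int):
    """Build MetageneScores whose rank assignment places samples P* at the
    given 1-based ranks; sample at rank r is named by its rank."""
    from mesrec import MetageneScores

    sample_ids = [f"S{r:03d}" for r in range(1, n + 1)]
    score = np.arange(1, n + 1, dtype=float)
    return (
        MetageneScores(
            sample_ids=tuple(sample_ids),
            score=score,
            signature_name="synthetic",
            n_genes_used=1,
            n_genes_missing=0,
        ),
        {f"S{r:03d}" for r in member_ranks},
    )
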