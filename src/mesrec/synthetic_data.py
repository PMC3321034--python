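"""Synthetic glioma cohorts with a latent mesenchymal-transition activity.

The generative model is a single-factor model: each sample carries a latent
activity m ~ Uniform[0, 1]; every signature gene tracks m with its own
loading plus Gaussian noise, background genes are pure noise around the same
baseline, and recurrence time follows a Weibull whose hazard increases with
m (log-hazard coefficient beta, so Cox regression on m is correctly
specified).  A fraction of patients never respond to therapy and get a null
recurrence time.  Optionally, samples are assigned one of four subtypes and
a block of subtype marker genes is generated from the subtype's centroid.

The ground truth (m, beta, loadings, subtype labels) is retained so that
recovery tests can compare estimates against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .core_types import (
    SUBTYPES,
    UNKNOWN_SUBTYPE,
    ClinicalTable,
    ExpressionMatrix,
    GeneSignature,
    SubtypeCentroids,
    emt_signature,
)

__all__ = [
    "SimulationParams",
    "SyntheticTruth",
    "simulate_cohort",
    "default_gbm_like_params",
    "make_subtype_centroids",
]


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the single-factor cohort generator.

    ``hazard_coef`` is the log-hazard increase per unit latent activity: the
    Weibull scale for sample i is ``weibull_scale * exp(-hazard_coef * m_i /
    weibull_shape)``, the accelerated parametrization under which the hazard
    is multiplied by ``exp(hazard_coef * m_i)``.
    """

    n_samples: int
    n_background_genes: int
    signature: GeneSignature
    loadings: np.ndarray = field(repr=False)
    noise_sd: float = 0.5
    baseline_log2: float = 6.0
    hazard_coef: float = 10.0
    weibull_shape: float = 1.2
    weibull_scale: float = 2600.0
    p_nonresponder: float = 0.0
    subtype_centroids: Optional[SubtypeCentroids] = None
    centroid_sd: float = 0.25
    censoring_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "loadings", np.asarray(self.loadings, dtype=float))
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.n_background_genes < 0:
            raise ValueError("n_background_genes must be >= 0")
        if self.loadings.shape != (len(self.signature),):
            raise ValueError(
                f"loadings length {self.loadings.shape} does not match "
                f"signature size {len(self.signature)}"
            )
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be > 0")
        if not 0 <= self.p_nonresponder < 1:
            raise ValueError("p_nonresponder must be in [0, 1)")
        if not (self.weibull_shape > 0 and self.weibull_scale > 0):
            raise ValueError("Weibull shape and scale must be > 0")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must be in [0, 1)")
        if self.centroid_sd <= 0:
            raise ValueError("centroid_sd must be > 0")

    def with_(self, **overrides) -> "SimulationParams":
        return replace(self, **overrides)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth retained from a simulated cohort."""

    latent_activity: np.ndarray
    hazard_coef: float
    loadings: np.ndarray
    sample_ids: tuple[str, ...]
    subtype: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if len(self.latent_activity) != len(self.sample_ids):
            raise ValueError("latent activity length must match sample count")
        if self.subtype is not None and len(self.subtype) != len(self.sample_ids):
            raise ValueError("subtype label length must match sample count")

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {"latent_activity": self.latent_activity},
            index=pd.Index(self.sample_ids, name="sample_id"),
        )
        if self.subtype is not None:
            frame["subtype"] = list(self.subtype)
        return frame


def simulate_cohort(
    params: SimulationParams,
) -> tuple[ExpressionMatrix, ClinicalTable, SyntheticTruth]:
    """Draw one cohort; a fixed seed gives bit-identical outputs.

    Draw order (fixed for reproducibility): latent activity, signature noise,
    background noise, recurrence times, non-responder mask, censoring mask,
    subtype labels, subtype-gene noise.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_samples
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    m = rng.random(n)

    sig_genes = list(params.signature.gene_ids)
    sig_expr = (
        params.baseline_log2
        + np.outer(params.loadings, m)
        + rng.normal(0.0, params.noise_sd, size=(len(sig_genes), n))
    )

    bg_genes = [f"BG{i + 1:05d}" for i in range(params.n_background_genes)]
    bg_expr = params.baseline_log2 + rng.normal(
        0.0, params.noise_sd, size=(params.n_background_genes, n)
    )

    scale_i = params.weibull_scale * np.exp(
        -params.hazard_coef * m / params.weibull_shape
    )
    times = scale_i * rng.weibull(params.weibull_shape, size=n)
    days = np.maximum(1, np.rint(times)).astype(float)

    nonresponder = rng.random(n) < params.p_nonresponder
    days[nonresponder] = np.nan

    event: Optional[np.ndarray] = None
    if params.censoring_rate > 0:
        censored = rng.random(n) < params.censoring_rate
        event = ~censored

    subtype_labels: Optional[list[str]] = None
    blocks = [sig_expr, bg_expr]
    gene_ids = sig_genes + bg_genes
    if params.subtype_centroids is not None:
        centroids = params.subtype_centroids
        label_idx = rng.integers(0, 4, size=n)
        subtype_labels = [centroids.subtype_names[j] for j in label_idx]
        sub_expr = centroids.centroid_values[:, label_idx] + rng.normal(
            0.0, params.centroid_sd, size=(len(centroids.gene_ids), n)
        )
        overlap = set(map(str, centroids.gene_ids)) & set(gene_ids)
        if overlap:
            raise ValueError(f"centroid genes collide with cohort genes: {sorted(overlap)[:5]}")
        blocks.append(sub_expr)
        gene_ids = gene_ids + list(centroids.gene_ids)

    matrix = ExpressionMatrix.from_arrays(gene_ids, sample_ids, np.vstack(blocks))

    clinical_frame = pd.DataFrame(
        {
            "days_to_recurrence": days,
            "responder": ~np.isnan(days),
            "subtype": subtype_labels if subtype_labels is not None else UNKNOWN_SUBTYPE,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    if event is not None:
        clinical_frame["event"] = event
    clinical = ClinicalTable(clinical_frame)

    truth = SyntheticTruth(
        latent_activity=m,
        hazard_coef=params.hazard_coef,
        loadings=params.loadings.copy(),
        sample_ids=tuple(sample_ids),
        subtype=tuple(subtype_labels) if subtype_labels is not None else None,
    )
    return matrix, clinical, truth


def default_gbm_like_params(seed: int = 0, **overrides) -> SimulationParams:
    """Defaults sized to the TCGA GBM study structure.

    545 samples with an expected 99 responders; 12,042 genes in total, of
    which the 64 signature genes load on the latent activity with loadings
    spread over [1, 3] log2 units (absence of expression through strong
    co-expression) and the rest are independent background.
    """
    signature = emt_signature()
    params = SimulationParams(
        n_samples=545,
        n_background_genes=12_042 - len(signature),
        signature=signature,
        loadings=np.linspace(1.0, 3.0, len(signature)),
        p_nonresponder=1.0 - 99.0 / 545.0,
        seed=seed,
    )
    return params.with_(**overrides) if overrides else params


def make_subtype_centroids(
    n_marker_genes: int = 10,
    baseline: float = 6.0,
    marker_delta: float = 2.0,
) -> SubtypeCentroids:
    """Block-structured centroids: each subtype elevates its own marker block.

    Produces ``4 * n_marker_genes`` subtype genes at ``baseline``, with the
    markers of each subtype raised by ``marker_delta`` in that subtype's
    centroid only.
    """
    n_genes = 4 * n_marker_genes
    values = np.full((n_genes, 4), baseline, dtype=float)
    gene_ids = []
    for j, name in enumerate(SUBTYPES):
        rows = slice(j * n_marker_genes, (j + 1) * n_marker_genes)
        values[rows, j] += marker_delta
        gene_ids.extend(f"{name.upper()[:4]}MK{i + 1:02d}" for i in range(n_marker_genes))
    return SubtypeCentroids(
        gene_ids=tuple(gene_ids),
        subtype_names=tuple(SUBTYPES),
        centroid_values=values,
    )
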