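"""Survival association: Kaplan-Meier by metagene split and Cox regression.

Recurrence times are the "days to tumor recurrence" of responders; every
non-null entry is treated as an observed event unless an explicit event
column says otherwise.  Cox models use the partial likelihood with Efron
handling of tied event times (lifelines' default).  The multivariate model
enters the metagene as a continuous covariate (optionally standardized to
unit variance) together with the four tumor subtypes in sum-to-zero
(deviation) coding, so each subtype coefficient is a contrast against the
overall mean log-hazard; all four contrasts are obtained by fitting twice
with different omitted levels and merging.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test

from .core_types import ClinicalTable
from .metagene import MetageneScores

logger = logging.getLogger(__name__)

Z_95 = 1.959963984540054  # normal 97.5% quantile for Wald CIs


@dataclass(frozen=True)
class SurvivalDataset:
    """Times, event flags, and covariates for the responder subcohort."""

    data: pd.DataFrame  # index sample_id; columns: time, event, covariates...

    def __post_init__(self) -> None:
        for col in ("time", "event"):
            if col not in self.data.columns:
                raise ValueError(f"survival dataset requires a {col!r} column")
        if (self.data["time"] <= 0).any():
            raise ValueError("times must be positive")

    @property
    def n_events(self) -> int:
        return int(self.data["event"].sum())


@dataclass(frozen=True)
class CoxFit:
    """Per-term Cox summary plus the model likelihood-ratio test.

    ``table`` columns: term, coef, se, hazard_ratio, ci_low, ci_high, p.
    """

    table: pd.DataFrame
    lrt_stat: float
    lrt_df: int
    lrt_p: float

    def term(self, name: str) -> pd.Series:
        rows = self.table[self.table["term"] == name]
        if len(rows) != 1:
            raise KeyError(f"term {name!r} not in fit")
        return rows.iloc[0]


@dataclass(frozen=True)
class KMResult:
    """Kaplan-Meier curves per group and the two-sample log-rank test."""

    curves: dict[str, pd.DataFrame]  # columns: time, survival
    chi2: float
    p_value: float


def survival_dataset(
    clinical: ClinicalTable,
    covariates: Optional[pd.DataFrame] = None,
) -> SurvivalDataset:
    """Build the responder-only survival dataset from a clinical table.

    Uses the optional ``event`` clinical column if present, else all
    responders are events.
    """
    responders = clinical.responders()
    frame = pd.DataFrame(
        {
            "time": responders["days_to_recurrence"].astype(float),
            "event": responders["event"].astype(bool)
            if "event" in responders.columns
            else True,
        },
        index=responders.index,
    )
    if covariates is not None:
        frame = frame.join(covariates.loc[frame.index])
    return SurvivalDataset(frame)


def median_split(scores: MetageneScores) -> dict[str, str]:
    """Split all samples into equal 'low'/'high' halves at the score median.

    With odd n the median sample goes to 'low'.  Ties (and the degenerate
    all-equal case) resolve by sample-ID order, so group sizes always differ
    by at most one.  The split is computed on the full cohort before any
    restriction to responders.
    """
    if len(scores.sample_ids) < 2:
        raise ValueError("median split requires at least two samples")
    ids = np.asarray(scores.sample_ids, dtype=object)
    order = np.lexsort((ids, scores.score))
    n_low = (len(ids) + 1) // 2
    labels = {}
    for pos, j in enumerate(order):
        labels[str(ids[j])] = "low" if pos < n_low else "high"
    return labels


def km_logrank(data: SurvivalDataset, groups: Mapping[str, str]) -> KMResult:
    """Product-limit curves and two-sample log-rank chi-squared (1 df)."""
    frame = data.data
    label = pd.Series({s: groups[s] for s in frame.index})
    levels = sorted(set(label))
    if len(levels) != 2:
        raise ValueError(f"exactly two groups required, got {levels}")
    curves = {}
    masks = {}
    for lv in levels:
        mask = label == lv
        if not mask.any():
            raise ValueError(f"group {lv!r} is empty")
        if frame.loc[mask, "event"].sum() == 0:
            warnings.warn(f"group {lv!r} has zero events", stacklevel=2)
        masks[lv] = mask
        fitter = KaplanMeierFitter()
        fitter.fit(frame.loc[mask, "time"], frame.loc[mask, "event"], label=lv)
        sf = fitter.survival_function_
        curves[lv] = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float), "survival": sf[lv].to_numpy()}
        )
    a, b = levels
    res = logrank_test(
        frame.loc[masks[a], "time"],
        frame.loc[masks[b], "time"],
        event_observed_A=frame.loc[masks[a], "event"],
        event_observed_B=frame.loc[masks[b], "event"],
    )
    return KMResult(curves=curves, chi2=float(res.test_statistic), p_value=float(res.p_value))


def _fit_cox(design: pd.DataFrame) -> CoxPHFitter:
    fitter = CoxPHFitter()
    try:
        fitter.fit(design, duration_col="time", event_col="event")
    except ConvergenceError as err:
        raise RuntimeError(
            f"Cox partial-likelihood fit failed to converge: {err}"
        ) from err
    return fitter


def _summary_rows(fitter: CoxPHFitter, terms: Sequence[str]) -> list[dict]:
    rows = []
    summary = fitter.summary
    for term in terms:
        coef = float(summary.loc[term, "coef"])
        se = float(summary.loc[term, "se(coef)"])
        rows.append(
            {
                "term": term,
                "coef": coef,
                "se": se,
                "hazard_ratio": float(np.exp(coef)),
                "ci_low": float(np.exp(coef - Z_95 * se)),
                "ci_high": float(np.exp(coef + Z_95 * se)),
                "p": float(summary.loc[term, "p"]),
            }
        )
    return rows


def cox_univariate(data: SurvivalDataset, covariate: str | pd.Series) -> CoxFit:
    """Single-covariate Cox proportional-hazards fit (Efron ties)."""
    frame = data.data
    if isinstance(covariate, str):
        x = frame[covariate].astype(float)
        name = covariate
    else:
        x = covariate.loc[frame.index].astype(float)
        name = str(covariate.name or "covariate")
    if not np.isfinite(x).all():
        raise ValueError("covariate must be finite")
    if float(np.ptp(x)) == 0.0:
        raise ValueError("degenerate design: covariate has zero variance")
    if data.n_events < 2:
        raise ValueError("at least two events are required")
    design = pd.DataFrame({"time": frame["time"], "event": frame["event"], name: x})
    fitter = _fit_cox(design)
    lrt = fitter.log_likelihood_ratio_test()
    return CoxFit(
        table=pd.DataFrame(_summary_rows(fitter, [name])),
        lrt_stat=float(lrt.test_statistic),
        lrt_df=int(lrt.degrees_freedom),
        lrt_p=float(lrt.p_value),
    )


def _deviation_design(subtype: pd.Series, omitted: str) -> pd.DataFrame:
    """Sum-to-zero coding: one column per non-omitted level, -1 on omitted."""
    levels = [lv for lv in sorted(subtype.unique()) if lv != omitted]
    cols = {}
    for lv in levels:
        col = np.where(subtype == lv, 1.0, np.where(subtype == omitted, -1.0, 0.0))
        cols[f"subtype[{lv}]"] = col
    return pd.DataFrame(cols, index=subtype.index)


def cox_multivariate_deviation(
    data: SurvivalDataset,
    metagene: pd.Series,
    subtype: pd.Series,
    standardize: bool = True,
) -> CoxFit:
    """Cox fit with metagene plus all four subtype-vs-overall-mean contrasts.

    Deviation (sum-to-zero) coding yields contrasts of each subtype's mean
    log hazard against the overall mean; a single fit identifies only three
    of the four, so the model is fit twice with different omitted levels and
    the rows are merged.  The reported LRT comes from the first fit (4 df:
    metagene + three independent subtype contrasts).
    """
    frame = data.data
    x = metagene.loc[frame.index].astype(float)
    if standardize:
        sd = float(x.std(ddof=1))
        if sd == 0:
            raise ValueError("metagene has zero variance")
        x = (x - x.mean()) / sd
    sub = subtype.loc[frame.index].astype(str)

    levels = sorted(sub.unique())
    declared = set(subtype.dropna().astype(str).unique())
    if declared - set(levels):
        logger.warning("dropping subtype levels with no samples: %s", sorted(declared - set(levels)))
    if len(levels) < 2:
        raise ValueError("need at least two populated subtype levels")
    if data.n_events < 2:
        raise ValueError("at least two events are required")

    base = pd.DataFrame({"time": frame["time"], "event": frame["event"], "metagene": x})

    fits = {}
    for omitted in (levels[-1], levels[0]):
        design = pd.concat([base, _deviation_design(sub, omitted)], axis=1)
        fits[omitted] = _fit_cox(design)

    first = fits[levels[-1]]
    rows = _summary_rows(first, ["metagene"])
    for lv in levels:
        source = first if lv != levels[-1] else fits[levels[0]]
        rows.extend(_summary_rows(source, [f"subtype[{lv}]"]))
    table = pd.DataFrame(rows)
    table["term"] = table["term"].str.replace(r"subtype\[(.+)\]", r"\1", regex=True)

    lrt = first.log_likelihood_ratio_test()
    return CoxFit(
        table=table,
        lrt_stat=float(lrt.test_statistic),
        lrt_df=int(lrt.degrees_freedom),
        lrt_p=float(lrt.p_value),
    )
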