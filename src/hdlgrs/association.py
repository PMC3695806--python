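"""Clustered association models for family-based cohorts.

Continuous and binary outcomes are analysed with marginal models solved by
generalized estimating equations (GEE) under an exchangeable working
correlation, with the sandwich variance estimator clustered on family —
exchangeable correlation coincides with the kinship structure of sibships
without parents, so this machinery also stands in for variance-components
single-SNP models.  Mortality is analysed with Cox proportional hazards
(Efron tie handling) and a cluster-robust sandwich variance.  Scores enter
either as continuous exposures, as an ordinal tertile trend (T1/T2/T3 coded
0/1/2), or as indicator contrasts against the lowest tertile.

Lipids are log-transformed and CAC is log(CAC+1)-transformed before
modelling, so continuous effect estimates are on the natural-log outcome
scale per score unit.  Confidence intervals are normal-theory (Wald),
estimate +/- 1.96 robust SE, exponentiated for hazard ratios.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter

__all__ = [
    "AssociationResult",
    "CovariateModel",
    "DEFAULT_MODELS",
    "AssociationError",
    "transform_outcome",
    "fit_marginal",
    "fit_cox_robust",
    "tertile_analysis",
    "run_model_battery",
    "results_table",
    "CONTINUOUS_OUTCOMES",
    "SURVIVAL_OUTCOMES",
    "BINARY_OUTCOMES",
]

logger = logging.getLogger(__name__)

Z_95 = 1.959963984540054  # standard normal 97.5% quantile

#: outcome -> transformation kind used before marginal modelling
CONTINUOUS_OUTCOMES = {
    "hdl": "log",
    "ldl": "log",
    "triglycerides": "log",
    "cac": "log1p",
}
SURVIVAL_OUTCOMES = {"death_all": "all-cause mortality", "death_cvd": "CVD mortality"}
BINARY_OUTCOMES = ("prior_cvd",)


class AssociationError(ValueError):
    """Raised for unusable model inputs (rank deficiency, no events, ...)."""


@dataclass(frozen=True)
class CovariateModel:
    """A labelled covariate adjustment set (phenotype column names)."""

    label: str
    covariates: tuple[str, ...]


# The covariate adjustment sets are config-overridable: Model 1 unadjusted,
# Model 2 age/sex/BMI, Model 3 adds the remaining CVD risk factors.
DEFAULT_MODELS: tuple[CovariateModel, ...] = (
    CovariateModel("M1", ()),
    CovariateModel("M2", ("age", "sex", "bmi")),
    CovariateModel(
        "M3",
        ("age", "sex", "bmi", "smoking", "hypertension", "cholesterol_med",
         "prior_cvd"),
    ),
)


@dataclass
class AssociationResult:
    """One fitted association: estimate, robust SE, Wald CI, p-value.

    ``estimate`` is a regression coefficient (log-outcome units per exposure
    unit) for marginal models and a log-hazard for Cox models; ``hr`` is
    exp(estimate) for survival models and None otherwise.
    """

    term: str
    estimate: float
    se_sandwich: float
    ci_low: float
    ci_high: float
    p_value: float
    model_label: str
    outcome: str
    n_used: int
    n_clusters: int
    hr: float | None = None
    score_label: str = ""
    note: str = ""

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise AssociationError("CI must bracket the estimate")

    def to_dict(self) -> dict:
        return {
            "score": self.score_label,
            "outcome": self.outcome,
            "model": self.model_label,
            "term": self.term,
            "estimate": self.estimate,
            "hr": self.hr,
            "se_sandwich": self.se_sandwich,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "n_used": self.n_used,
            "n_clusters": self.n_clusters,
            "note": self.note,
        }


def transform_outcome(values: np.ndarray, outcome_kind: str) -> np.ndarray:
    """Normality transformation: 'log' for lipids, 'log1p' for CAC,
    'identity' otherwise.  Non-positive values under 'log' are an error."""
    x = np.asarray(values, float)
    if not np.all(np.isfinite(x)):
        raise AssociationError("outcome contains non-finite values")
    if outcome_kind == "log":
        if (x <= 0).any():
            bad = int(np.argmax(x <= 0))
            raise AssociationError(
                f"non-positive value at record {bad} under log transform"
            )
        return np.log(x)
    if outcome_kind == "log1p":
        if (x < 0).any():
            raise AssociationError("negative value under log1p transform")
        return np.log1p(x)
    if outcome_kind == "identity":
        return x
    raise AssociationError(f"unknown transformation {outcome_kind!r}")


def _design(
    data: pd.DataFrame, exposure_cols: Sequence[str], covariates: Sequence[str]
) -> pd.DataFrame:
    X = pd.DataFrame(index=data.index)
    X["const"] = 1.0
    for c in exposure_cols:
        X[c] = pd.to_numeric(data[c])
    for c in covariates:
        if c == "sex":
            X["sex_male"] = (data["sex"] == "male").astype(float)
        else:
            X[c] = pd.to_numeric(data[c])
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise AssociationError(
            f"design matrix is rank deficient ({rank} < {X.shape[1]})"
        )
    return X


def fit_marginal(
    outcome: np.ndarray,
    exposure: pd.DataFrame | pd.Series | np.ndarray,
    covariates: Sequence[str],
    data: pd.DataFrame,
    family_ids: np.ndarray,
    binary: bool = False,
    model_label: str = "",
    outcome_label: str = "",
    score_label: str = "",
) -> list[AssociationResult]:
    """GEE marginal model with exchangeable working correlation and
    family-clustered sandwich standard errors.

    ``exposure`` may be one column (continuous score, ordinal trend) or
    several (tertile indicators); one result per exposure column is
    returned.  Identity link for continuous outcomes, logit for binary.
    With every family of size one the estimates reduce to ordinary
    (logistic) regression with heteroskedasticity-robust errors.
    """
    if isinstance(exposure, (pd.Series, np.ndarray)):
        exposure = pd.DataFrame({"score": np.asarray(exposure, float)})
    exposure = exposure.reset_index(drop=True)
    data = data.reset_index(drop=True)
    work = pd.concat([data, exposure], axis=1)
    X = _design(work, list(exposure.columns), covariates)
    groups = pd.Series(family_ids).reset_index(drop=True)
    if groups.nunique() < 2:
        raise AssociationError("need at least 2 clusters")
    fam = sm.families.Binomial() if binary else sm.families.Gaussian()
    model = sm.GEE(
        np.asarray(outcome, float),
        X,
        groups=groups,
        family=fam,
        cov_struct=sm.cov_struct.Exchangeable(),
    )
    try:
        res = model.fit(maxiter=100)
    except Exception as exc:
        raise AssociationError(f"GEE failed to converge: {exc}") from exc
    results = []
    for col in exposure.columns:
        est = float(res.params[col])
        se = float(res.bse[col])
        results.append(
            AssociationResult(
                term=col,
                estimate=est,
                se_sandwich=se,
                ci_low=est - Z_95 * se,
                ci_high=est + Z_95 * se,
                p_value=float(res.pvalues[col]),
                model_label=model_label,
                outcome=outcome_label,
                n_used=len(work),
                n_clusters=int(groups.nunique()),
                score_label=score_label,
            )
        )
    return results


def fit_cox_robust(
    time: np.ndarray,
    status: np.ndarray,
    exposure: pd.DataFrame | pd.Series | np.ndarray,
    covariates: Sequence[str],
    data: pd.DataFrame,
    family_ids: np.ndarray,
    model_label: str = "",
    outcome_label: str = "",
    score_label: str = "",
) -> list[AssociationResult]:
    """Cox proportional hazards with family-clustered sandwich variance.

    Partial-likelihood point estimates (Efron approximation for ties),
    robust standard errors clustered on family, hazard ratios with Wald
    95% CIs on the log scale.
    """
    time = np.asarray(time, float)
    status = np.asarray(status, int)
    if (time <= 0).any():
        raise AssociationError("event/censoring times must be positive")
    if status.sum() < 1:
        raise AssociationError("no events observed")
    if isinstance(exposure, (pd.Series, np.ndarray)):
        exposure = pd.DataFrame({"score": np.asarray(exposure, float)})
    exposure = exposure.reset_index(drop=True)
    data = data.reset_index(drop=True)
    work = pd.concat([data, exposure], axis=1)
    X = _design(work, list(exposure.columns), covariates).drop(columns="const")
    df = X.copy()
    df["_time"] = time
    df["_event"] = status
    df["_cluster"] = pd.Series(family_ids).reset_index(drop=True)
    cph = CoxPHFitter()
    try:
        cph.fit(
            df,
            duration_col="_time",
            event_col="_event",
            cluster_col="_cluster",
            show_progress=False,
            fit_options={"precision": 1e-14},  # tight Newton stop
        )
    except Exception as exc:
        raise AssociationError(f"Cox fit failed: {exc}") from exc
    results = []
    for col in exposure.columns:
        est = float(cph.params_[col])
        se = float(cph.standard_errors_[col])
        results.append(
            AssociationResult(
                term=col,
                estimate=est,
                se_sandwich=se,
                ci_low=est - Z_95 * se,
                ci_high=est + Z_95 * se,
                p_value=float(cph.summary.loc[col, "p"]),
                model_label=model_label,
                outcome=outcome_label,
                n_used=len(df),
                n_clusters=int(df["_cluster"].nunique()),
                hr=math.exp(est),
                score_label=score_label,
            )
        )
    return results


def _tertile_design(
    tertiles: np.ndarray, mode: Literal["ordinal_trend", "reference_contrast"]
) -> pd.DataFrame:
    t = np.asarray(tertiles, dtype=object)
    labels = {"T1", "T2", "T3"}
    if set(np.unique(t)) != labels:
        raise AssociationError("tertile analysis requires three non-empty tertiles")
    if mode == "ordinal_trend":
        code = np.select([t == "T1", t == "T2", t == "T3"], [0.0, 1.0, 2.0])
        return pd.DataFrame({"tertile_trend": code})
    if mode == "reference_contrast":
        return pd.DataFrame(
            {"T2_vs_T1": (t == "T2").astype(float), "T3_vs_T1": (t == "T3").astype(float)}
        )
    raise AssociationError(f"unknown tertile mode {mode!r}")


def tertile_analysis(
    tertiles: np.ndarray,
    data: pd.DataFrame,
    family_ids: np.ndarray,
    mode: Literal["ordinal_trend", "reference_contrast"],
    outcome: np.ndarray | None = None,
    time: np.ndarray | None = None,
    status: np.ndarray | None = None,
    covariates: Sequence[str] = (),
    model_label: str = "",
    outcome_label: str = "",
    score_label: str = "",
) -> list[AssociationResult]:
    """Tertile-based association: ordinal linear trend (T1/T2/T3 as 0/1/2)
    or indicator contrasts against the lowest tertile.

    Dispatches to the marginal model when ``outcome`` is given and to the
    robust Cox model when ``time``/``status`` are given.
    """
    design = _tertile_design(tertiles, mode)
    if outcome is not None:
        return fit_marginal(
            outcome, design, covariates, data, family_ids,
            model_label=model_label, outcome_label=outcome_label,
            score_label=score_label,
        )
    if time is not None and status is not None:
        return fit_cox_robust(
            time, status, design, covariates, data, family_ids,
            model_label=model_label, outcome_label=outcome_label,
            score_label=score_label,
        )
    raise AssociationError("supply either outcome or time+status")


def run_model_battery(
    phenotypes: pd.DataFrame,
    scores: pd.DataFrame,
    models: Sequence[CovariateModel] = DEFAULT_MODELS,
    continuous_outcomes: dict[str, str] | None = None,
    survival_outcomes: Sequence[str] = tuple(SURVIVAL_OUTCOMES),
    binary_outcomes: Sequence[str] = BINARY_OUTCOMES,
) -> pd.DataFrame:
    """Cross every score column with every outcome and covariate model.

    ``scores`` is a frame keyed like ``phenotypes`` rows (same order) with
    one column per score label.  Returns a long-format table with one row
    per (score, outcome, model); a failed fit contributes a row whose
    ``note`` records the reason instead of estimates.
    """
    if continuous_outcomes is None:
        continuous_outcomes = CONTINUOUS_OUTCOMES
    if len(scores) != len(phenotypes):
        raise AssociationError("scores and phenotypes must align row-wise")
    fam = phenotypes["family_id"].to_numpy()
    rows: list[dict] = []

    def record(fit_call, score_label, outcome_label, model_label):
        try:
            for r in fit_call():
                rows.append(r.to_dict())
        except AssociationError as exc:
            rows.append(
                {
                    "score": score_label, "outcome": outcome_label,
                    "model": model_label, "term": None, "estimate": np.nan,
                    "hr": np.nan, "se_sandwich": np.nan, "ci_low": np.nan,
                    "ci_high": np.nan, "p_value": np.nan,
                    "n_used": 0, "n_clusters": 0, "note": str(exc),
                }
            )

    for score_label in scores.columns:
        exposure = scores[score_label].to_numpy(float)
        for outcome_name, kind in continuous_outcomes.items():
            values = phenotypes[outcome_name].to_numpy(float)
            mask = np.isfinite(values)
            if kind == "log":
                mask &= values > 0
            y = transform_outcome(values[mask], kind)
            sub = phenotypes.loc[mask].reset_index(drop=True)
            for model in models:
                record(
                    lambda y=y, e=exposure[mask], m=model, s=sub: fit_marginal(
                        y, e, m.covariates, s, s["family_id"].to_numpy(),
                        model_label=m.label, outcome_label=outcome_name,
                        score_label=score_label,
                    ),
                    score_label, outcome_name, model.label,
                )
        for outcome_name in survival_outcomes:
            for model in models:
                record(
                    lambda o=outcome_name, m=model: fit_cox_robust(
                        phenotypes["followup_years"].to_numpy(),
                        phenotypes[o].to_numpy(int),
                        exposure, m.covariates,
                        phenotypes, fam,
                        model_label=m.label, outcome_label=o,
                        score_label=score_label,
                    ),
                    score_label, outcome_name, model.label,
                )
        for outcome_name in binary_outcomes:
            for model in models:
                covs = tuple(c for c in model.covariates if c != outcome_name)
                record(
                    lambda o=outcome_name, m=model, c=covs: fit_marginal(
                        phenotypes[o].to_numpy(float), exposure, c,
                        phenotypes, fam, binary=True,
                        model_label=m.label, outcome_label=o,
                        score_label=score_label,
                    ),
                    score_label, outcome_name, model.label,
                )
    return pd.DataFrame(rows)


def results_table(results: pd.DataFrame, survival: bool) -> pd.DataFrame:
    """Pretty wide summary mirroring the published table layout:
    one row per score x outcome, 'estimate (CI)' and p per model."""
    out_rows = []
    for (score, outcome), grp in results.groupby(["score", "outcome"], sort=False):
        row: dict = {"score": score, "outcome": outcome}
        for _, r in grp.iterrows():
            if pd.isna(r["estimate"]):
                cell, p = f"failed: {r['note']}", np.nan
            elif survival:
                cell = (
                    f"{math.exp(r['estimate']):.2f} "
                    f"({math.exp(r['ci_low']):.2f}-{math.exp(r['ci_high']):.2f})"
                )
                p = r["p_value"]
            else:
                cell = (
                    f"{r['estimate']:.3f} ({r['ci_low']:.3f}-{r['ci_high']:.3f})"
                )
                p = r["p_value"]
            row[f"{r['model']}_estimate"] = cell
            row[f"{r['model']}_p"] = p
        out_rows.append(row)
    return pd.DataFrame(out_rows)
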