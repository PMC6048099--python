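"""Imputation and confound adjustment of longitudinal cortical thickness.

Two steps precede network construction:

1. ``impute_month12``: subjects who missed only the month-12 visit get it
   imputed per region by extrapolating an ordinary least-squares line
   fitted to their months 0/3/6 trajectory. Subjects missing month 12
   plus any other visit are rejected.
2. ``adjust_thickness``: one pooled least-squares regression over ALL
   subjects, regions and timepoints removes variability related to age,
   sex, baseline lesion load and each subject's baseline mean cortical
   thickness (a global atrophy proxy); total intracranial volume is kept
   only if its coefficient is significant at the 5% level. The residuals
   are the "adjusted" thickness values used for all networks, so the
   relationships between groups are preserved by construction (one model
   for everyone, controls entering with lesion load 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "SubjectExclusionError",
    "AdjustmentReport",
    "impute_month12",
    "adjust_thickness",
]

_IMPUTE_MONTHS = (0, 3, 6)
_TARGET_MONTH = 12


class SubjectExclusionError(ValueError):
    """Raised when subjects miss month 12 plus at least one more visit."""

    def __init__(self, subject_ids: list[str]):
        self.subject_ids = list(subject_ids)
        super().__init__(
            "subjects missing month 12 and at least one other visit must be "
            f"excluded: {', '.join(self.subject_ids)}"
        )


def impute_month12(thickness: pd.DataFrame) -> pd.DataFrame:
    """Impute missing month-12 visits by per-region linear extrapolation.

    For each subject lacking month 12 but with complete months 0/3/6, an
    OLS line of thickness on month is fitted per region and evaluated at
    month 12. Returns the dataset with the imputed records appended and
    an ``imputed`` boolean column marking them.

    Raises
    ------
    SubjectExclusionError
        If any subject misses month 12 and one or more earlier visits.
    """
    df = thickness.copy()
    if "imputed" not in df.columns:
        df["imputed"] = False
    visits = df.groupby("subject_id")["month"].agg(lambda m: frozenset(m))
    need = visits[~visits.apply(lambda s: _TARGET_MONTH in s)]
    if need.empty:
        return df
    incomplete = [
        sid for sid, s in need.items() if not set(_IMPUTE_MONTHS).issubset(s)
    ]
    if incomplete:
        raise SubjectExclusionError(sorted(incomplete))

    months = np.array(_IMPUTE_MONTHS, dtype=float)
    xbar = months.mean()
    sxx = ((months - xbar) ** 2).sum()
    sub = df[df["subject_id"].isin(need.index) & df["month"].isin(_IMPUTE_MONTHS)]
    wide = sub.pivot_table(
        index=["subject_id", "group", "region"],
        columns="month",
        values="thickness_mm",
        observed=True,
    )
    y = wide[list(_IMPUTE_MONTHS)].to_numpy()
    ybar = y.mean(axis=1)
    slope = ((months - xbar) * (y - ybar[:, None])).sum(axis=1) / sxx
    predicted = ybar + slope * (_TARGET_MONTH - xbar)

    imputed = wide.index.to_frame(index=False)
    imputed["month"] = _TARGET_MONTH
    imputed["thickness_mm"] = predicted
    imputed["imputed"] = True
    out = pd.concat(
        [df, imputed[["subject_id", "group", "month", "region", "thickness_mm", "imputed"]]],
        ignore_index=True,
    )
    return out.sort_values(["subject_id", "month", "region"], ignore_index=True)


@dataclass
class AdjustmentReport:
    """Fit summary of the pooled confound regression."""

    coefficients: dict[str, float]
    std_errors: dict[str, float]
    tiv_considered: bool
    tiv_kept: bool
    tiv_p_value: float | None
    n_observations: int
    residual_skew: float
    residual_kurtosis: float
    covariate_columns: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients,
            "std_errors": self.std_errors,
            "tiv_considered": self.tiv_considered,
            "tiv_kept": self.tiv_kept,
            "tiv_p_value": self.tiv_p_value,
            "n_observations": self.n_observations,
            "residual_skew": self.residual_skew,
            "residual_kurtosis": self.residual_kurtosis,
            "covariate_columns": self.covariate_columns,
        }


def _baseline_mean_thickness(thickness: pd.DataFrame) -> pd.Series:
    base = thickness[thickness["month"] == thickness["month"].min()]
    return base.groupby("subject_id")["thickness_mm"].mean()


def adjust_thickness(
    thickness: pd.DataFrame,
    covariates: pd.DataFrame,
    *,
    include_lesion_load: bool = True,
    include_baseline_mean: bool = True,
    tiv_rule: bool = False,
    tiv_alpha: float = 0.05,
) -> tuple[pd.DataFrame, AdjustmentReport]:
    """Residualize thickness against confounders in ONE pooled regression.

    Outcome: every thickness value (all subjects, regions, timepoints).
    Covariates: age, sex (0/1), baseline lesion load (optional, the
    study's main analysis includes it), each subject's baseline mean
    cortical thickness, and — when ``tiv_rule`` — total intracranial
    volume retained only if its t-test is significant at ``tiv_alpha``.

    Returns the dataset with ``thickness_mm`` replaced by the residuals
    (mean zero, orthogonal to every retained covariate) plus the fit
    report. Disabling ``include_lesion_load`` reproduces the
    lesion-load-unadjusted sensitivity analysis.

    ``include_baseline_mean=False`` drops the baseline-mean covariate.
    Because that covariate is an aggregate of the outcome itself, it
    partially absorbs any subject-constant effect of the other
    covariates; slope-recovery checks against a known generative model
    should therefore disable it (the full model still residualizes
    correctly — orthogonality holds either way).
    """
    df = thickness.copy()
    if "imputed" not in df.columns:
        df["imputed"] = False

    missing = set(df["subject_id"]) - set(covariates["subject_id"])
    if missing:
        raise ValueError(f"covariates missing for subjects: {sorted(missing)}")
    cov = covariates.set_index("subject_id")
    if cov.index.has_duplicates:
        raise ValueError("covariate table must have one row per subject")

    # the baseline mean thickness covariate can be supplied in the
    # covariate table (one value per subject); otherwise it is derived
    # from the earliest visit of the data itself
    if "baseline_mean_thickness" in cov.columns:
        bmt = cov["baseline_mean_thickness"]
    else:
        bmt = _baseline_mean_thickness(df)
    design = pd.DataFrame(index=df.index)
    if not include_baseline_mean:
        bmt = None
    design["age_years"] = cov["age_years"].reindex(df["subject_id"]).to_numpy()
    sex = cov["sex"].reindex(df["subject_id"])
    if sex.dtype == object or pd.api.types.is_string_dtype(sex):
        design["sex"] = (sex.to_numpy() == "M").astype(float)
    else:
        design["sex"] = sex.to_numpy().astype(float)
    if include_lesion_load:
        design["lesion_load_ml"] = (
            cov["lesion_load_ml"].reindex(df["subject_id"]).to_numpy()
        )
    if bmt is not None:
        design["baseline_mean_thickness"] = bmt.reindex(df["subject_id"]).to_numpy()

    tiv_considered = tiv_rule and "tiv_ml" in cov.columns and cov["tiv_ml"].notna().all()
    if tiv_considered:
        design["tiv_ml"] = cov["tiv_ml"].reindex(df["subject_id"]).to_numpy()

    if design.isna().any().any():
        bad = design.columns[design.isna().any()].tolist()
        raise ValueError(f"missing covariate values in columns: {bad}")
    constant = [c for c in design.columns if np.ptp(design[c].to_numpy()) == 0]
    if constant:
        raise ValueError(
            f"design is rank-deficient: constant covariate column(s) {constant}"
        )

    y = df["thickness_mm"].to_numpy()
    x = sm.add_constant(design.to_numpy())
    names = ["const", *design.columns]
    # repeated measures per subject: cluster-robust SEs (coefficients and
    # residuals are plain least squares either way)
    clusters = pd.factorize(df["subject_id"])[0]
    fit = sm.OLS(y, x).fit(cov_type="cluster", cov_kwds={"groups": clusters})

    tiv_kept = False
    tiv_p = None
    if tiv_considered:
        tiv_p = float(fit.pvalues[names.index("tiv_ml")])
        tiv_kept = tiv_p < tiv_alpha
        if not tiv_kept:
            design = design.drop(columns="tiv_ml")
            x = sm.add_constant(design.to_numpy())
            names = ["const", *design.columns]
            fit = sm.OLS(y, x).fit(cov_type="cluster", cov_kwds={"groups": clusters})

    resid = fit.resid
    out = df.copy()
    out["thickness_mm"] = resid
    report = AdjustmentReport(
        coefficients=dict(zip(names, map(float, fit.params))),
        std_errors=dict(zip(names, map(float, fit.bse))),
        tiv_considered=bool(tiv_considered),
        tiv_kept=tiv_kept,
        tiv_p_value=tiv_p,
        n_observations=int(len(y)),
        residual_skew=float(stats.skew(resid)),
        residual_kurtosis=float(stats.kurtosis(resid)),
        covariate_columns=list(design.columns),
    )
    return out, report
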