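"""Cohort-level statistics: predictor regressions, VIF screening,
performance models, pain exclusions, precision (RMS-CV) and one-sample
z-score comparisons.

Ordinary least squares goes through statsmodels (formula interface with
treatment coding; reference levels male / White / non-Hispanic). Reported
p-values are the covariate-adjusted p-values of the multivariable model; no
multiplicity correction is applied. Missing data are handled complete-case
per model, and the base and MusD-augmented performance models are always
fitted on identical row sets so their R² values are comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

DEFAULT_BASE_PREDICTORS = ["age", "sex", "race", "ethnicity", "height_cm",
                           "bmi", "pct_fat", "alm_ht2"]

_CATEGORICAL_TERMS = {
    "sex": "C(sex, Treatment('M'))",
    "race": "C(race, Treatment('White'))",
    "ethnicity": "C(ethnicity, Treatment('Non-Hispanic'))",
}


@dataclass
class RegressionResult:
    """Multivariable OLS summary: per-predictor estimate, SE, adjusted p, R²,
    and per-predictor VIF (continuous design columns)."""

    estimates: pd.Series
    se: pd.Series
    pvalues: pd.Series
    r2: float
    vif: pd.Series
    n: int


@dataclass
class PerformanceFit:
    """Base model vs base + MusD model fitted on identical rows."""

    base: RegressionResult
    augmented: RegressionResult
    musd_term: str
    musd_estimate: float
    musd_se: float
    musd_p: float

    @property
    def delta_r2(self) -> float:
        return self.augmented.r2 - self.base.r2


@dataclass
class CohortComparison:
    """One-sample t-test of z-scores against a population mean of 0."""

    mean: float
    ci_low: float
    ci_high: float
    t: float
    df: int
    p: float
    n: int


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor of each column: 1 / (1 - R²_j) from
    regressing column j (with intercept) on all other columns.

    Perfect collinearity is reported as ``inf``.
    """
    design = design.astype(float)
    if design.shape[1] < 2:
        raise ValueError("VIF needs at least two predictors")
    if design.shape[0] <= design.shape[1]:
        raise ValueError("VIF needs more rows than predictors")
    out = {}
    for col in design.columns:
        y = design[col].to_numpy()
        X = np.column_stack([np.ones(len(design)),
                             design.drop(columns=col).to_numpy()])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        tss = np.sum((y - y.mean()) ** 2)
        if tss == 0:
            out[col] = np.inf
            continue
        r2 = 1.0 - np.sum(resid ** 2) / tss
        out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def _formula(outcome: str, predictors: list[str]) -> str:
    terms = [_CATEGORICAL_TERMS.get(p, p) for p in predictors]
    return f"{outcome} ~ " + " + ".join(terms)


def _fit_ols(df: pd.DataFrame, outcome: str, predictors: list[str]) -> RegressionResult:
    data = df.dropna(subset=[outcome] + predictors)
    model = smf.ols(_formula(outcome, predictors), data=data)
    exog = model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        bad = _deficient_columns(exog, model.exog_names)
        raise ValueError(f"rank-deficient design; offending columns: {bad}")
    res = model.fit()
    keep = [name for name in res.params.index if name != "Intercept"]
    design = pd.DataFrame(exog, columns=model.exog_names).drop(columns="Intercept")
    vifs = vif(design) if design.shape[1] >= 2 else pd.Series(dtype=float)
    return RegressionResult(estimates=res.params[keep], se=res.bse[keep],
                            pvalues=res.pvalues[keep], r2=float(res.rsquared),
                            vif=vifs, n=int(res.nobs))


def _deficient_columns(exog: np.ndarray, names: list[str]) -> list[str]:
    bad = []
    for j in range(1, exog.shape[1]):  # skip intercept
        others = np.delete(exog, j, axis=1)
        beta, *_ = np.linalg.lstsq(others, exog[:, j], rcond=None)
        resid = exog[:, j] - others @ beta
        if np.sum(resid ** 2) < 1e-10 * max(np.sum(exog[:, j] ** 2), 1.0):
            bad.append(names[j])
    return bad


def fit_predictors(df: pd.DataFrame, outcome: str,
                   predictors: list[str] | None = None) -> RegressionResult:
    """Multivariable OLS of an outcome on the standard predictor set.

    Categorical predictors expand against the reference levels male, White
    and non-Hispanic; complete cases only; deterministic.
    """
    predictors = predictors if predictors is not None else list(DEFAULT_BASE_PREDICTORS)
    return _fit_ols(df, outcome, predictors)


def fit_performance(df: pd.DataFrame, outcome: str, musd_column: str,
                    base_predictors: list[str] | None = None) -> PerformanceFit:
    """Base multivariable model and base + MusD model on identical rows."""
    base_predictors = base_predictors if base_predictors is not None \
        else list(DEFAULT_BASE_PREDICTORS)
    rows = df.dropna(subset=[outcome, musd_column] + base_predictors)
    base = _fit_ols(rows, outcome, base_predictors)
    augmented = _fit_ols(rows, outcome, base_predictors + [musd_column])
    return PerformanceFit(base=base, augmented=augmented, musd_term=musd_column,
                          musd_estimate=float(augmented.estimates[musd_column]),
                          musd_se=float(augmented.se[musd_column]),
                          musd_p=float(augmented.pvalues[musd_column]))


PAIN_TESTS = (("grip_kg", "grip_pain"), ("sts_30s", "sts_pain"))


def apply_pain_exclusion(df: pd.DataFrame, *, threshold: float = 3.0,
                         tests=PAIN_TESTS) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Null performance values where the matching pain rating exceeds 3/10.

    Strict inequality: pain 3 is retained, pain 4 excluded. Pain ratings
    outside 0-10 invalidate that row's test value with an ``invalid_pain``
    reason. Returns the filtered table and a per-test, per-sex exclusion
    log. Idempotent: excluded values carry no pain information forward.
    """
    df = df.copy()
    log_rows = []
    for value_col, pain_col in tests:
        if pain_col not in df.columns:
            warnings.warn(f"no pain column {pain_col!r}; test {value_col!r} untouched",
                          stacklevel=2)
            continue
        pain = df[pain_col]
        present = df[value_col].notna()  # only newly nulled values are logged
        invalid = present & pain.notna() & ((pain < 0) | (pain > 10))
        excluded = present & pain.notna() & (pain > threshold) & ~invalid
        df.loc[excluded | invalid, value_col] = np.nan
        for sex, sub_excl, sub_inv in ((s, excluded & (df["sex"] == s),
                                        invalid & (df["sex"] == s))
                                       for s in df.get("sex", pd.Series(dtype=object)).unique()):
            log_rows.append({"test": value_col, "sex": sex,
                             "excluded_pain": int(sub_excl.sum()),
                             "invalid_pain": int(sub_inv.sum())})
        if "sex" not in df.columns:
            log_rows.append({"test": value_col, "sex": "all",
                             "excluded_pain": int(excluded.sum()),
                             "invalid_pain": int(invalid.sum())})
    log = pd.DataFrame(log_rows, columns=["test", "sex", "excluded_pain", "invalid_pain"])
    return df, log


def rms_cv(repeats: pd.DataFrame) -> float:
    """Root-mean-square coefficient of variation (%) across subjects.

    ``repeats``: one row per subject, columns are repeat measurements.
    Per subject CV_i = 100 * sample SD / mean; RMS-CV = sqrt(mean CV_i²).
    """
    values = repeats.to_numpy(dtype=float)
    cvs = []
    for row in values:
        row = row[~np.isnan(row)]
        if row.size < 2:
            raise ValueError("each subject needs at least two repeat measurements")
        mean = row.mean()
        if mean <= 0:
            raise ValueError("subject mean must be positive for a CV")
        cvs.append(100.0 * row.std(ddof=1) / mean)
    return float(np.sqrt(np.mean(np.square(cvs))))


def compare_cohort(z_scores, confidence: float = 0.95) -> CohortComparison:
    """One-sample t-test of a cohort's z-scores against a population mean of 0.

    A mean whose confidence interval does not cross zero indicates a
    difference from the reference cohort. Zero variance with a nonzero mean
    is reported as an infinite t statistic.
    """
    z = np.asarray(z_scores, dtype=float)
    z = z[~np.isnan(z)]
    n = z.size
    if n < 2:
        raise ValueError("need at least two z-scores")
    mean = float(z.mean())
    sd = float(z.std(ddof=1))
    dof = n - 1
    if sd == 0:
        t = 0.0 if mean == 0 else float(np.inf) * np.sign(mean)
        p = 1.0 if mean == 0 else 0.0
        return CohortComparison(mean=mean, ci_low=mean, ci_high=mean, t=t,
                                df=dof, p=p, n=n)
    se = sd / np.sqrt(n)
    t = mean / se
    p = float(2.0 * stats.t.sf(abs(t), dof))
    tcrit = float(stats.t.ppf(0.5 + confidence / 2.0, dof))
    return CohortComparison(mean=mean, ci_low=mean - tcrit * se,
                            ci_high=mean + tcrit * se, t=float(t), df=dof,
                            p=p, n=n)
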