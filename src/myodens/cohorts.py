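"""Synthetic reference cohorts with the published statistical structure.

``generate_cohort`` draws demographics and body-composition covariates from
the per-sex reference distributions, builds forearm and leg MusD as the
published multivariable linear combination of those covariates plus
Gaussian residual, and builds physical-performance outcomes (grip, gait
speeds, 30-s sit-to-stand, PROMIS-PF) as base-covariate linear models plus
the published MusD term, with residual noise sized so the base model
explains the published fraction of variance.

``generate_decade_cohort`` instead draws an outcome around per-decade
central values (ages uniform within each decade), the design used to
exercise centile-curve fitting against decade-wise summaries.

All draws are seeded and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import reference_tables as ref

SEXES = ("F", "M")
RACES = ("White", "Asian", "Black", "Other")
ETHNICITIES = ("Non-Hispanic", "Hispanic")

#: columns of a generated cohort table
COHORT_COLUMNS = [
    "id", "sex", "age", "race", "ethnicity", "height_m", "height_cm",
    "weight_kg", "bmi", "pct_fat", "alm_ht2", "musd_forearm", "musd_leg",
    "grip_kg", "gait_usual", "gait_fast", "sts_30s", "promis_pf",
    "grip_pain", "sts_pain",
]

# Base-model coefficients for performance outcomes (package defaults; the
# source tables print only the base-model R^2 and the MusD term, so levels
# and covariate slopes are chosen to land near the observed per-sex medians).
DEFAULT_PERFORMANCE_BASE = {
    "grip_kg":   {"intercept": -13.75, "sex_female": -14.0, "age": -0.10,
                  "height_cm": 0.15, "bmi": 0.0, "pct_fat": -0.05, "alm_ht2": 2.2},
    "gait_usual": {"intercept": 1.12, "sex_female": -0.02, "age": -0.002,
                   "height_cm": 0.002, "bmi": -0.008, "pct_fat": -0.002, "alm_ht2": 0.02},
    "gait_fast": {"intercept": 1.41, "sex_female": -0.05, "age": -0.004,
                  "height_cm": 0.004, "bmi": -0.01, "pct_fat": -0.002, "alm_ht2": 0.03},
    "sts_30s":   {"intercept": 9.6, "sex_female": -1.0, "age": -0.06,
                  "height_cm": 0.03, "bmi": -0.15, "pct_fat": -0.05, "alm_ht2": 0.7},
    "promis_pf": {"intercept": 50.4, "sex_female": -1.0, "age": -0.15,
                  "height_cm": 0.05, "bmi": -0.3, "pct_fat": -0.1, "alm_ht2": 1.0},
}
# which MusD site feeds each performance outcome by default
DEFAULT_PERFORMANCE_SITE = {
    "grip_kg": "forearm", "gait_usual": "leg", "gait_fast": "leg",
    "sts_30s": "forearm", "promis_pf": "leg",
}

_COVARIATE_KEYS = ("height_m", "bmi", "pct_fat", "alm_ht2")


def _default_covariates() -> dict:
    return {sex: ref.pooled_covariate_medians(sex) for sex in SEXES}


def _default_race_probs() -> dict:
    return {sex: ref.race_probabilities(sex) for sex in SEXES}


@dataclass
class CohortSpec:
    """Generating parameters for a synthetic reference cohort."""

    n: int = 1662
    female_proportion: float = 1161 / 1662
    age_range: tuple[float, float] = (18.0, 80.0)
    covariates: dict = field(default_factory=_default_covariates)
    race_probs: dict = field(default_factory=_default_race_probs)
    hispanic_prob: dict = field(default_factory=lambda: dict(ref.ETHNICITY_HISPANIC))
    bmi_pctfat_corr: float = 0.0     # optional collinearity knob
    musd_coefs: dict = field(default_factory=lambda: {k: dict(v) for k, v in
                                                      ref.MUSD_PREDICTOR_COEFS.items()})
    musd_intercepts: dict | None = None   # None -> anchored to young-male medians
    musd_residual_sd: float = 1.3         # mgHA/cm^3
    performance_base: dict = field(default_factory=lambda: {k: dict(v) for k, v in
                                                            DEFAULT_PERFORMANCE_BASE.items()})
    performance_site: dict = field(default_factory=lambda: dict(DEFAULT_PERFORMANCE_SITE))
    performance_musd_coefs: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in ref.PERFORMANCE_MUSD_COEFS.items()})
    performance_base_r2: dict = field(default_factory=lambda: dict(ref.PERFORMANCE_BASE_R2))
    pain_gt3_prob: float = 0.05
    pain_low_prob: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError("cohort size must be non-negative")
        if not 0.0 <= self.female_proportion <= 1.0:
            raise ValueError("female proportion must lie in [0, 1]")
        if self.musd_residual_sd < 0:
            raise ValueError("residual SD must be non-negative")
        for sex, probs in self.race_probs.items():
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"race probabilities for sex {sex!r} must sum to 1")
        if not -1.0 < self.bmi_pctfat_corr < 1.0:
            raise ValueError("BMI-percent-fat correlation must lie in (-1, 1)")


def reference_male_covariates() -> dict[str, float]:
    """Covariates of the anchoring reference male: pooled male medians,
    age at the midpoint of the youngest decade, White, non-Hispanic."""
    pooled = ref.pooled_covariate_medians("M")
    return {"age": ref.decade_midpoint("18-29"),
            "sex_female": 0.0, "race_asian": 0.0, "race_black": 0.0,
            "race_other": 0.0, "ethnicity_hispanic": 0.0,
            "height_cm": 100.0 * pooled["height_m"], "bmi": pooled["bmi"],
            "pct_fat": pooled["pct_fat"], "alm_ht2": pooled["alm_ht2"]}


def default_musd_intercept(site: str, coefs: dict[str, float] | None = None) -> float:
    """Intercept anchoring the reference male's predicted MusD to the
    young-male (18-29) decade median."""
    coefs = coefs if coefs is not None else ref.MUSD_PREDICTOR_COEFS[site]
    anchor = ref.musd_decade_medians("M", site)["18-29"]
    x = reference_male_covariates()
    missing = set(coefs) - set(x)
    if missing:
        raise KeyError(f"no reference value for covariates {sorted(missing)}")
    return anchor - sum(beta * x[name] for name, beta in coefs.items())


def _design_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Indicator expansion used by the generating model (reference levels:
    male, White, non-Hispanic)."""
    out = pd.DataFrame(index=df.index)
    out["age"] = df["age"]
    out["sex_female"] = (df["sex"] == "F").astype(float)
    out["race_asian"] = (df["race"] == "Asian").astype(float)
    out["race_black"] = (df["race"] == "Black").astype(float)
    out["race_other"] = (df["race"] == "Other").astype(float)
    out["ethnicity_hispanic"] = (df["ethnicity"] == "Hispanic").astype(float)
    out["height_cm"] = df["height_cm"]
    out["bmi"] = df["bmi"]
    out["pct_fat"] = df["pct_fat"]
    out["alm_ht2"] = df["alm_ht2"]
    return out


def predict_musd(df: pd.DataFrame, site: str, *, coefs: dict | None = None,
                 intercept: float | None = None) -> pd.Series:
    """Deterministic part of the MusD generating model (no residual)."""
    coefs = coefs if coefs is not None else ref.MUSD_PREDICTOR_COEFS[site]
    design = _design_columns(df)
    missing = set(coefs) - set(design.columns)
    if missing:
        raise KeyError(f"missing coefficient covariates {sorted(missing)} in table")
    if intercept is None:
        intercept = default_musd_intercept(site, coefs)
    pred = pd.Series(intercept, index=df.index, dtype=float)
    for name, beta in coefs.items():
        pred += beta * design[name]
    return pred


def _empty_cohort() -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=float) for c in COHORT_COLUMNS})
    for c in ("id", "sex", "race", "ethnicity"):
        df[c] = df[c].astype(object)
    return df


def generate_cohort(spec: CohortSpec | None = None) -> pd.DataFrame:
    """Draw a seeded synthetic cohort table (one row per subject)."""
    spec = spec or CohortSpec()
    spec.validate()
    if spec.n == 0:
        return _empty_cohort()
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    sex = np.where(rng.random(n) < spec.female_proportion, "F", "M")
    age = rng.uniform(*spec.age_range, size=n)
    df = pd.DataFrame({"id": [f"S{i:05d}" for i in range(n)], "sex": sex, "age": age})

    race = np.empty(n, dtype=object)
    eth = np.empty(n, dtype=object)
    cov = {k: np.empty(n) for k in _COVARIATE_KEYS}
    for s in SEXES:
        idx = np.flatnonzero(sex == s)
        if idx.size == 0:
            continue
        probs = spec.race_probs[s]
        race[idx] = rng.choice(list(probs), size=idx.size, p=list(probs.values()))
        eth[idx] = np.where(rng.random(idx.size) < spec.hispanic_prob[s],
                            "Hispanic", "Non-Hispanic")
        loc = spec.covariates[s]
        cov["height_m"][idx] = rng.normal(loc["height_m"], loc["height_m_sd"], idx.size)
        rho = spec.bmi_pctfat_corr
        e1 = rng.standard_normal(idx.size)
        e2 = rho * e1 + np.sqrt(1 - rho ** 2) * rng.standard_normal(idx.size)
        cov["bmi"][idx] = loc["bmi"] + loc["bmi_sd"] * e1
        cov["pct_fat"][idx] = loc["pct_fat"] + loc["pct_fat_sd"] * e2
        cov["alm_ht2"][idx] = rng.normal(loc["alm_ht2"], loc["alm_ht2_sd"], idx.size)
    df["race"], df["ethnicity"] = race, eth
    df["height_m"] = np.clip(cov["height_m"], 1.30, 2.10)
    df["height_cm"] = 100.0 * df["height_m"]
    df["bmi"] = np.clip(cov["bmi"], 15.0, 55.0)
    df["pct_fat"] = np.clip(cov["pct_fat"], 5.0, 60.0)
    df["alm_ht2"] = np.clip(cov["alm_ht2"], 3.0, 14.0)
    df["weight_kg"] = df["bmi"] * df["height_m"] ** 2

    musd_eps = {}
    for site in ("forearm", "leg"):
        intercept = None if spec.musd_intercepts is None else spec.musd_intercepts[site]
        sysd = predict_musd(df, site, coefs=spec.musd_coefs[site], intercept=intercept)
        eps = rng.normal(0.0, spec.musd_residual_sd, n) if spec.musd_residual_sd > 0 \
            else np.zeros(n)
        musd_eps[site] = eps
        df[f"musd_{site}"] = sysd.to_numpy() + eps

    design = _design_columns(df)
    for outcome, base in spec.performance_base.items():
        lin = np.full(n, base.get("intercept", 0.0))
        for name, beta in base.items():
            if name == "intercept":
                continue
            if name not in design.columns:
                raise KeyError(f"missing coefficient covariate {name!r} for {outcome}")
            lin = lin + beta * design[name].to_numpy()
        site = spec.performance_site[outcome]
        musd_beta = spec.performance_musd_coefs[outcome][site]
        systematic = lin + musd_beta * df[f"musd_{site}"].to_numpy()
        r2 = spec.performance_base_r2[outcome]
        # residual sized so the base covariates explain ~r2 of total variance:
        # base-explainable part excludes only the MusD residual contribution
        var_base = float(np.var(lin + musd_beta * (df[f"musd_{site}"].to_numpy()
                                                   - musd_eps[site])))
        var_musd_eps = musd_beta ** 2 * spec.musd_residual_sd ** 2
        resid_var = max(var_base * (1.0 - r2) / r2 - var_musd_eps, 1e-12)
        df[outcome] = systematic + rng.normal(0.0, np.sqrt(resid_var), n)

    for col in ("grip_pain", "sts_pain"):
        u = rng.random(n)
        pain = np.zeros(n)
        low = u < spec.pain_low_prob
        pain[low] = rng.integers(1, 4, size=int(low.sum()))
        high = (u >= spec.pain_low_prob) & (u < spec.pain_low_prob + spec.pain_gt3_prob)
        pain[high] = rng.integers(4, 11, size=int(high.sum()))
        df[col] = pain
    return df[COHORT_COLUMNS]


def generate_decade_cohort(decade_summaries: pd.DataFrame, n_per_decade: int = 150,
                           dispersion: float = 0.5, seed: int = 0,
                           value_column: str = "value") -> pd.DataFrame:
    """Draw (sex, age, value) records around per-decade central values.

    ``decade_summaries`` needs columns ``sex``, ``decade`` and the value
    column; ages are uniform within each decade and values are
    Normal(central value, dispersion). A missing or NaN central value is an
    error. Fitted centile medians of the result track the supplied decade
    central values.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    required = {"sex", "decade", value_column}
    if not required.issubset(decade_summaries.columns):
        raise ValueError(f"decade summaries need columns {sorted(required)}")
    rng = np.random.default_rng(seed)
    rows = []
    for _, rec in decade_summaries.iterrows():
        centre = rec[value_column]
        if pd.isna(centre):
            raise ValueError(f"decade {rec['decade']!r} ({rec['sex']}) has no central value")
        lo, hi = ref.DECADES[rec["decade"]]
        ages = rng.uniform(lo, hi, n_per_decade)
        values = centre + (rng.normal(0.0, dispersion, n_per_decade)
                           if dispersion > 0 else np.zeros(n_per_decade))
        rows.append(pd.DataFrame({"sex": rec["sex"], "decade": rec["decade"],
                                  "age": ages, value_column: values}))
    return pd.concat(rows, ignore_index=True)


def musd_decade_summary_frame(sex: str, site: str) -> pd.DataFrame:
    """Published per-decade MusD medians as input for generate_decade_cohort."""
    med = ref.musd_decade_medians(sex, site)
    return pd.DataFrame({"sex": sex, "decade": list(med), "value": list(med.values())})
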