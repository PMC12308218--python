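"""Subject-facing reference calculator: percentiles, z-, t- and modified scores.

Given a fitted :class:`~myodens.lms.LMSModel` and a subject's sex, age (or
birth and scan dates) and a measured outcome, this module returns:

* **z-score** — SDs from the age- and sex-matched median, via the Box-Cox
  transform at the subject's age;
* **percentile** — ``100 * Phi(z)``;
* **t-score** — SDs from the best sex-specific median, i.e. the Box-Cox
  transform evaluated at the age a* where the fitted median curve peaks;
* **modified z-/t-scores** — for scores above +2, where the LMS transform
  compresses extremes, the deviation from the median re-expressed in units
  of half the distance between the median and the +2 centile (the growth-
  chart convention). The symmetric variant (also below -2) is available but
  off by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd
from scipy.stats import norm

from .lms import LMSModel, bccg_centile, bccg_z, best_median_anchor

DAYS_PER_YEAR = 365.25


def decimal_age(birth_date: date, scan_date: date) -> float:
    """Age in decimal years: (scan - birth) / 365.25."""
    return (scan_date - birth_date).days / DAYS_PER_YEAR


@dataclass
class StandardScores:
    """Standardised outcomes for one subject and one measurement."""

    z: float
    percentile: float      # 100 * Phi(z)
    t: float
    modified: bool         # True when the plain score exceeded the flag threshold
    modified_z: float | None = None   # half-distance units, present when flagged
    modified_t: float | None = None


def modified_score(y: float, age: float, model: LMSModel) -> float:
    """Deviation from the median in units of half the (median -> +2z) distance."""
    _, mu, _ = model.params_at(age)
    c2 = model.centile(100.0 * norm.cdf(2.0), age)
    half = (c2 - mu) / 2.0
    if half <= 0:
        raise RuntimeError("internal inconsistency: +2 centile at or below the median")
    return float((y - mu) / half)


def _modified_t(y: float, model: LMSModel) -> float:
    a_star, mu_star, lam_star, sig_star = best_median_anchor(model)
    c2 = bccg_centile(100.0 * norm.cdf(2.0), lam_star, mu_star, sig_star)
    half = (c2 - mu_star) / 2.0
    if half <= 0:
        raise RuntimeError("internal inconsistency: +2 centile at or below the median")
    return float((y - mu_star) / half)


def score_subject(y: float, age: float, model: LMSModel, *,
                  symmetric_modified: bool = False) -> StandardScores:
    """Score one measurement against a fitted reference model.

    Ages outside the fitted range are refused (no extrapolation). Modified
    scores are attached when the plain score exceeds +2 (or |score| > 2 with
    ``symmetric_modified``).
    """
    if y <= 0:
        raise ValueError("measurements must be positive")
    lam, mu, sigma = model.params_at(age)
    z = float(bccg_z(y, lam, mu, sigma))
    a_star, mu_star, lam_star, sig_star = best_median_anchor(model)
    t = float(bccg_z(y, lam_star, mu_star, sig_star))

    def _flag(score: float) -> bool:
        return score > 2.0 or (symmetric_modified and score < -2.0)

    flagged = _flag(z) or _flag(t)
    mod_z = modified_score(y, age, model) if flagged else None
    mod_t = _modified_t(y, model) if flagged else None
    return StandardScores(z=z, percentile=float(100.0 * norm.cdf(z)), t=t,
                          modified=flagged, modified_z=mod_z, modified_t=mod_t)


def batch_score(records: pd.DataFrame, models: dict[str, LMSModel], *,
                value_column: str, sex_column: str = "sex",
                age_column: str = "age",
                symmetric_modified: bool = False) -> pd.DataFrame:
    """Score a table of subjects row by row, never silently dropping rows.

    ``models`` maps sex codes to fitted models. The result has one row per
    input row in the input order; rows that cannot be scored (unknown sex,
    age out of range, non-positive value) carry an ``error`` code and NaN
    scores instead of disappearing.
    """
    out = []
    for _, row in records.iterrows():
        entry = {"z": np.nan, "percentile": np.nan, "t": np.nan,
                 "modified": False, "modified_z": np.nan, "modified_t": np.nan,
                 "error": ""}
        sex = row.get(sex_column)
        model = models.get(sex)
        if model is None:
            entry["error"] = f"unknown sex code {sex!r}"
        else:
            try:
                s = score_subject(float(row[value_column]), float(row[age_column]),
                                  model, symmetric_modified=symmetric_modified)
                entry.update(z=s.z, percentile=s.percentile, t=s.t,
                             modified=s.modified,
                             modified_z=np.nan if s.modified_z is None else s.modified_z,
                             modified_t=np.nan if s.modified_t is None else s.modified_t)
            except (ValueError, KeyError) as exc:
                entry["error"] = str(exc)
        out.append(entry)
    return pd.DataFrame(out, index=records.index)


DEFAULT_CENTILES = (3.0, 10.0, 25.0, 50.0, 75.0, 90.0, 97.0)


def centile_plot_data(model: LMSModel, ages=None,
                      centiles=DEFAULT_CENTILES) -> pd.DataFrame:
    """Per-age centile values (C3...C97) for plotting reference charts.

    The C50 column equals the fitted median curve exactly, and columns are
    strictly ordered at every age (non-crossing centiles).
    """
    ages = model.age_grid() if ages is None else np.asarray(ages, dtype=float)
    lam, mu, sigma = model.params_at(ages)
    table = {"age": ages}
    for alpha in centiles:
        table[f"C{alpha:g}"] = bccg_centile(alpha, lam, mu, sigma)
    return pd.DataFrame(table)
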