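"""Published normative tables for second-generation HR-pQCT muscle outcomes.

These constants reproduce the printed reference tables of the normative
HR-pQCT muscle-density study (1662 adults, 18-80 y): per-decade participant
characteristics, per-decade muscle outcomes (MusD, MV, TV, MV/TV),
multivariable predictor coefficients for forearm and leg MusD, and the
MusD terms of the physical-performance models. They are the generating
parameters for the synthetic cohorts and the comparators for the
parameter-recovery tests.

Units: MusD in mgHA/cm^3, MV/TV volumes in cm^3, height in m (``height_cm``
columns are derived), BMI in kg/m^2, whole-body percent fat in %,
ALM/height^2 in kg/m^2, grip in kg, gait speeds in m/s, PROMIS-PF as a
t-score (population mean 50, SD 10).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

# Decade bins of the reference cohort: label -> (low, high) in years
DECADES: dict[str, tuple[float, float]] = {
    "18-29": (18.0, 30.0),
    "30-39": (30.0, 40.0),
    "40-49": (40.0, 50.0),
    "50-59": (50.0, 60.0),
    "60-69": (60.0, 70.0),
    "70-80": (70.0, 80.0),
}

# participants per sex x decade
N_PER_DECADE = {
    "F": {"18-29": 206, "30-39": 125, "40-49": 129, "50-59": 263, "60-69": 322, "70-80": 116},
    "M": {"18-29": 145, "30-39": 61, "40-49": 48, "50-59": 64, "60-69": 110, "70-80": 73},
}

# race counts per sex (Asian, Black, White, Other) pooled over decades
RACE_COUNTS = {
    "F": {"Asian": 70, "Black": 98, "White": 985, "Other": 8},
    "M": {"Asian": 39, "Black": 33, "White": 428, "Other": 1},
}

# Hispanic / total per sex
ETHNICITY_HISPANIC = {"F": 34 / 1161, "M": 31 / 501}

# Covariate medians (IQR low, high) per sex x decade.
# columns: height_m, bmi, pct_fat, alm_ht2, plus physical function outcomes.
_COVARIATE_MEDIANS = {
    ("F", "18-29"): {"height_m": (1.64, 1.60, 1.69), "bmi": (24.6, 21.8, 28.0),
                     "pct_fat": (30.7, 25.2, 35.1), "alm_ht2": (7.05, 6.21, 7.91),
                     "gait_usual": (1.41, 1.26, 1.55), "gait_fast": (2.04, 1.84, 2.21),
                     "grip_kg": (27.0, 23.5, 31.2), "sts_30s": (16, 14, 19),
                     "promis_pf": (57.9, 52.4, 62.8)},
    ("F", "30-39"): {"height_m": (1.65, 1.60, 1.70), "bmi": (24.6, 22.0, 30.5),
                     "pct_fat": (31.2, 26.0, 36.9), "alm_ht2": (6.88, 6.22, 7.93),
                     "gait_usual": (1.39, 1.26, 1.55), "gait_fast": (1.96, 1.79, 2.19),
                     "grip_kg": (28.3, 25.0, 32.1), "sts_30s": (16, 13, 19),
                     "promis_pf": (55.8, 51.3, 61.9)},
    ("F", "40-49"): {"height_m": (1.65, 1.61, 1.68), "bmi": (26.0, 22.6, 31.9),
                     "pct_fat": (33.4, 26.9, 37.8), "alm_ht2": (6.86, 5.99, 7.67),
                     "gait_usual": (1.44, 1.32, 1.62), "gait_fast": (2.03, 1.83, 2.17),
                     "grip_kg": (27.2, 22.8, 31.3), "sts_30s": (16, 13, 18),
                     "promis_pf": (53.6, 48.7, 60.1)},
    ("F", "50-59"): {"height_m": (1.63, 1.59, 1.67), "bmi": (26.0, 22.9, 32.4),
                     "pct_fat": (36.0, 30.8, 40.4), "alm_ht2": (6.55, 5.83, 7.71),
                     "gait_usual": (1.43, 1.27, 1.59), "gait_fast": (1.91, 1.75, 2.11),
                     "grip_kg": (24.7, 21.2, 28.2), "sts_30s": (15, 13, 18),
                     "promis_pf": (51.7, 46.8, 57.3)},
    ("F", "60-69"): {"height_m": (1.63, 1.59, 1.67), "bmi": (26.3, 23.2, 31.4),
                     "pct_fat": (35.9, 32.1, 39.6), "alm_ht2": (6.39, 5.84, 7.34),
                     "gait_usual": (1.35, 1.20, 1.52), "gait_fast": (1.85, 1.70, 2.00),
                     "grip_kg": (23.9, 20.8, 27.0), "sts_30s": (14, 12, 16),
                     "promis_pf": (50.4, 45.9, 54.7)},
    ("F", "70-80"): {"height_m": (1.61, 1.58, 1.65), "bmi": (26.0, 22.4, 30.3),
                     "pct_fat": (35.7, 31.6, 40.3), "alm_ht2": (6.08, 5.61, 6.83),
                     "gait_usual": (1.30, 1.16, 1.43), "gait_fast": (1.74, 1.55, 1.94),
                     "grip_kg": (22.0, 17.9, 25.4), "sts_30s": (13, 11, 16),
                     "promis_pf": (48.8, 44.7, 53.9)},
    ("M", "18-29"): {"height_m": (1.78, 1.74, 1.78), "bmi": (25.3, 23.5, 28.6),
                     "pct_fat": (18.6, 14.8, 25.1), "alm_ht2": (8.98, 8.11, 9.72),
                     "gait_usual": (1.44, 1.33, 1.60), "gait_fast": (2.14, 1.97, 2.35),
                     "grip_kg": (48.0, 40.2, 55.3), "sts_30s": (17, 15, 21),
                     "promis_pf": (60.4, 55.8, 64.7)},
    ("M", "30-39"): {"height_m": (1.77, 1.73, 1.81), "bmi": (25.7, 24.5, 30.8),
                     "pct_fat": (20.9, 17.3, 24.7), "alm_ht2": (8.71, 8.03, 9.78),
                     "gait_usual": (1.42, 1.27, 1.65), "gait_fast": (2.26, 1.99, 2.41),
                     "grip_kg": (46.7, 39.2, 56.9), "sts_30s": (18, 15, 22),
                     "promis_pf": (60.1, 53.6, 66.6)},
    ("M", "40-49"): {"height_m": (1.78, 1.73, 1.84), "bmi": (27.6, 24.5, 31.5),
                     "pct_fat": (22.9, 17.4, 26.5), "alm_ht2": (8.92, 8.19, 10.48),
                     "gait_usual": (1.44, 1.28, 1.58), "gait_fast": (2.14, 1.81, 2.39),
                     "grip_kg": (50.3, 41.2, 55.4), "sts_30s": (17, 14, 20),
                     "promis_pf": (54.3, 49.8, 62.7)},
    ("M", "50-59"): {"height_m": (1.76, 1.71, 1.84), "bmi": (27.2, 24.7, 32.3),
                     "pct_fat": (23.8, 19.9, 28.3), "alm_ht2": (8.71, 8.12, 10.27),
                     "gait_usual": (1.42, 1.27, 1.52), "gait_fast": (2.04, 1.86, 2.33),
                     "grip_kg": (45.1, 37.6, 48.6), "sts_30s": (16, 14, 19),
                     "promis_pf": (53.5, 48.6, 60.5)},
    ("M", "60-69"): {"height_m": (1.77, 1.73, 1.81), "bmi": (27.6, 24.3, 30.3),
                     "pct_fat": (24.7, 20.7, 28.8), "alm_ht2": (8.06, 7.57, 8.82),
                     "gait_usual": (1.39, 1.27, 1.54), "gait_fast": (2.03, 1.85, 2.24),
                     "grip_kg": (40.8, 31.9, 48.2), "sts_30s": (10.3, 8.6, 11.5),
                     "promis_pf": (50.5, 47.1, 54.7)},
    ("M", "70-80"): {"height_m": (1.75, 1.70, 1.79), "bmi": (28.3, 25.2, 32.6),
                     "pct_fat": (28.2, 24.1, 31.3), "alm_ht2": (7.93, 7.18, 8.80),
                     "gait_usual": (1.29, 1.13, 1.46), "gait_fast": (1.87, 1.61, 2.12),
                     "grip_kg": (31.8, 27.0, 40.5), "sts_30s": (13, 11, 16),
                     "promis_pf": (48.6, 45.7, 51.7)},
}

# Muscle outcomes per sex x site x decade: median (IQR low, high).
_MUSCLE_MEDIANS = {
    ("F", "forearm"): {
        "MV":   {"18-29": (14.2, 12.7, 16.3), "30-39": (14.8, 13.2, 17.1), "40-49": (14.8, 13.1, 16.5),
                 "50-59": (14.2, 12.8, 16.1), "60-69": (13.9, 12.6, 15.3), "70-80": (13.3, 12.1, 14.7)},
        "TV":   {"18-29": (19.9, 17.4, 22.8), "30-39": (20.0, 17.7, 22.7), "40-49": (20.1, 18.0, 23.0),
                 "50-59": (19.7, 17.7, 23.0), "60-69": (19.4, 17.4, 21.7), "70-80": (18.9, 16.9, 21.0)},
        "MVTV": {"18-29": (72.6, 68.7, 76.2), "30-39": (74.5, 69.6, 77.3), "40-49": (72.8, 68.2, 77.0),
                 "50-59": (71.3, 67.9, 75.5), "60-69": (71.4, 67.3, 75.8), "70-80": (72.4, 67.4, 75.8)},
        "MusD": {"18-29": (23.91, 23.72, 24.10), "30-39": (23.65, 23.42, 23.87), "40-49": (23.74, 23.50, 23.98),
                 "50-59": (23.13, 22.94, 23.33), "60-69": (22.65, 22.48, 22.82), "70-80": (22.10, 21.82, 22.38)},
    },
    ("F", "leg"): {
        "MV":   {"18-29": (27.1, 23.2, 30.9), "30-39": (26.8, 23.1, 29.9), "40-49": (28.0, 24.2, 32.9),
                 "50-59": (26.7, 23.6, 30.6), "60-69": (26.4, 23.7, 29.9), "70-80": (24.6, 22.8, 27.3)},
        "TV":   {"18-29": (39.7, 34.6, 46.3), "30-39": (39.3, 34.5, 45.4), "40-49": (39.7, 35.8, 47.5),
                 "50-59": (40.3, 35.4, 45.6), "60-69": (38.9, 35.0, 44.5), "70-80": (37.0, 32.9, 41.6)},
        "MVTV": {"18-29": (67.0, 64.5, 70.2), "30-39": (68.2, 65.1, 70.9), "40-49": (68.4, 63.7, 71.5),
                 "50-59": (67.7, 62.9, 71.3), "60-69": (67.8, 63.8, 71.6), "70-80": (67.7, 63.1, 72.8)},
        "MusD": {"18-29": (24.08, 23.85, 24.30), "30-39": (23.56, 23.22, 23.89), "40-49": (22.86, 22.54, 23.17),
                 "50-59": (21.56, 21.30, 21.82), "60-69": (20.51, 20.27, 20.75), "70-80": (20.07, 19.65, 20.49)},
    },
    ("M", "forearm"): {
        "MV":   {"18-29": (22.3, 19.8, 25.2), "30-39": (21.7, 19.0, 25.4), "40-49": (24.5, 20.6, 28.2),
                 "50-59": (22.7, 20.5, 26.6), "60-69": (20.8, 19.0, 23.0), "70-80": (20.1, 17.4, 22.7)},
        "TV":   {"18-29": (27.7, 24.7, 30.9), "30-39": (27.3, 23.6, 32.5), "40-49": (30.2, 26.1, 35.2),
                 "50-59": (28.7, 26.1, 33.5), "60-69": (26.8, 23.8, 30.4), "70-80": (26.5, 22.5, 30.3)},
        "MVTV": {"18-29": (81.9, 76.9, 86.7), "30-39": (80.2, 76.1, 84.7), "40-49": (80.0, 74.5, 85.4),
                 "50-59": (80.4, 76.0, 83.4), "60-69": (78.0, 74.6, 82.9), "70-80": (76.4, 72.9, 81.2)},
        "MusD": {"18-29": (24.75, 24.53, 24.97), "30-39": (24.70, 24.42, 24.97), "40-49": (24.55, 24.09, 25.01),
                 "50-59": (24.39, 23.99, 24.79), "60-69": (24.28, 23.99, 24.57), "70-80": (23.48, 23.05, 23.91)},
    },
    ("M", "leg"): {
        "MV":   {"18-29": (31.9, 28.4, 36.5), "30-39": (33.2, 30.0, 38.0), "40-49": (33.3, 29.0, 36.0),
                 "50-59": (33.2, 31.6, 38.3), "60-69": (31.9, 28.7, 35.4), "70-80": (30.3, 27.1, 35.0)},
        "TV":   {"18-29": (43.0, 39.3, 49.5), "30-39": (44.0, 37.1, 50.5), "40-49": (42.7, 38.9, 47.0),
                 "50-59": (42.4, 40.3, 50.7), "60-69": (42.7, 37.6, 46.9), "70-80": (43.5, 36.5, 47.9)},
        "MVTV": {"18-29": (75.0, 70.1, 78.6), "30-39": (76.3, 72.5, 80.0), "40-49": (77.3, 71.8, 81.5),
                 "50-59": (78.5, 74.0, 81.8), "60-69": (76.0, 71.7, 79.5), "70-80": (75.6, 67.0, 78.9)},
        "MusD": {"18-29": (25.64, 25.39, 25.89), "30-39": (24.61, 24.15, 25.07), "40-49": (24.19, 23.53, 24.85),
                 "50-59": (23.54, 22.91, 24.17), "60-69": (22.29, 21.86, 22.72), "70-80": (21.50, 20.88, 22.12)},
    },
}

# Multivariable predictor coefficients for MusD (outcome units per predictor
# unit); reference levels: male, White, non-Hispanic. Height enters in cm.
MUSD_PREDICTOR_COEFS: dict[str, dict[str, float]] = {
    "forearm": {
        "age": -0.028, "sex_female": -0.458,
        "race_asian": -0.242, "race_black": 0.047, "race_other": 0.088,
        "ethnicity_hispanic": -0.238,
        "height_cm": 0.024, "bmi": 0.038, "pct_fat": -0.022, "alm_ht2": 0.052,
    },
    "leg": {
        "age": -0.075, "sex_female": -0.595,
        "race_asian": -0.181, "race_black": -0.227, "race_other": 0.780,
        "ethnicity_hispanic": -0.206,
        "height_cm": 0.012, "bmi": -0.046, "pct_fat": -0.051, "alm_ht2": 0.161,
    },
}
MUSD_MODEL_R2 = {"forearm": 0.275, "leg": 0.485}

# Performance-model MusD terms (outcome units per mgHA/cm^3) and the
# variance fraction explained by the base covariate model.
PERFORMANCE_MUSD_COEFS = {
    "gait_usual": {"forearm": -0.001, "leg": 0.005},
    "gait_fast": {"forearm": 0.009, "leg": 0.009},
    "grip_kg": {"forearm": 0.756, "leg": 0.211},
    "sts_30s": {"forearm": 0.134, "leg": 0.096},
    "promis_pf": {"forearm": 0.200, "leg": 0.212},
}
PERFORMANCE_BASE_R2 = {
    "gait_usual": 0.128, "gait_fast": 0.228, "grip_kg": 0.648,
    "sts_30s": 0.259, "promis_pf": 0.374,
}

IQR_TO_SD = 1.349  # width of the central 50% of a normal in SD units


def decade_midpoint(label: str) -> float:
    lo, hi = DECADES[label]
    return 0.5 * (lo + hi)


def covariate_table() -> pd.DataFrame:
    """Per sex x decade covariate medians and IQR-derived normal SDs."""
    rows = []
    for (sex, decade), d in _COVARIATE_MEDIANS.items():
        row = {"sex": sex, "decade": decade, "n": N_PER_DECADE[sex][decade],
               "age_mid": decade_midpoint(decade)}
        for var, (med, lo, hi) in d.items():
            row[var] = med
            row[f"{var}_sd"] = (hi - lo) / IQR_TO_SD
        rows.append(row)
    return pd.DataFrame(rows)


def muscle_outcome_table() -> pd.DataFrame:
    """Per sex x site x decade muscle-outcome medians and IQRs (long form)."""
    rows = []
    for (sex, site), outcomes in _MUSCLE_MEDIANS.items():
        for outcome, per_decade in outcomes.items():
            for decade, (med, lo, hi) in per_decade.items():
                rows.append({"sex": sex, "site": site, "outcome": outcome,
                             "decade": decade, "age_mid": decade_midpoint(decade),
                             "median": med, "iqr_low": lo, "iqr_high": hi,
                             "sd": (hi - lo) / IQR_TO_SD})
    return pd.DataFrame(rows)


def musd_decade_medians(sex: str, site: str) -> dict[str, float]:
    """Decade-label -> median MusD (mgHA/cm^3) for one sex and site."""
    return {dec: v[0] for dec, v in _MUSCLE_MEDIANS[(sex, site)]["MusD"].items()}


def pooled_covariate_medians(sex: str) -> dict[str, float]:
    """Participant-weighted medians of the per-decade covariate medians."""
    tab = covariate_table()
    sub = tab[tab.sex == sex]
    w = sub.n.to_numpy(dtype=float)
    out = {}
    for var in ("height_m", "bmi", "pct_fat", "alm_ht2"):
        out[var] = float(np.average(sub[var], weights=w))
        out[f"{var}_sd"] = float(np.average(sub[f"{var}_sd"], weights=w))
    return out


def race_probabilities(sex: str) -> dict[str, float]:
    counts = RACE_COUNTS[sex]
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}
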