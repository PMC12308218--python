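"""Sex-specific LMS (Box-Cox Cole-Green) reference centile curves over age.

The LMS method models a positive outcome y at age t with three smooth
curves: the Box-Cox power lambda(t) (L), the median mu(t) (M) and the
coefficient of variation sigma(t) (S). Conditional on age,

    z = ((y / mu)**lambda - 1) / (lambda * sigma)        (lambda != 0)
    z = log(y / mu) / sigma                              (lambda == 0)

is standard normal (the BCCG distribution), so centiles, percentiles and
z-/t-scores follow directly from the three curves.

Fitting maximises the penalised BCCG log-likelihood: each curve is a cubic
P-spline (B-spline basis with a second-order difference penalty on the
coefficients, the discrete analogue of an integrated-squared-second-
derivative penalty). Penalty weights are calibrated so each curve uses a
target number of effective degrees of freedom, then all three coefficient
vectors are optimised jointly with L-BFGS-B from fixed deterministic starts
(lambda = 1, mu = smoothed running median, sigma = IQR/1.349/median), so
refitting identical data reproduces identical curves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import optimize
from scipy.interpolate import BSpline

_LAMBDA_TOL = 1e-8
_SCHEMA_VERSION = 1


def bccg_z(y, lam, mu, sigma):
    """Box-Cox z-score of outcome ``y`` given BCCG parameters.

    Continuous in lambda at 0 (log-transform branch below ``1e-8``).
    """
    y = np.asarray(y, dtype=float)
    lam = np.asarray(lam, dtype=float)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(y <= 0):
        raise ValueError("BCCG outcomes must be positive")
    if np.any(mu <= 0) or np.any(sigma <= 0):
        raise ValueError("mu and sigma must be positive")
    r = np.log(y / mu)
    with np.errstate(over="ignore", invalid="ignore"):
        z_power = (np.exp(lam * r) - 1.0) / (lam * sigma)
    z_log = r / sigma
    z = np.where(np.abs(lam) > _LAMBDA_TOL, z_power, z_log)
    return z if z.ndim else float(z)


def bccg_centile(alpha, lam, mu, sigma):
    """Outcome value at percentile ``alpha`` (0-100) of the BCCG distribution.

    Exact inverse of :func:`bccg_z`: ``bccg_z(bccg_centile(alpha)) == z_alpha``.
    """
    from scipy.stats import norm

    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0) or np.any(alpha >= 100):
        raise ValueError("percentile must lie strictly between 0 and 100")
    lam = np.asarray(lam, dtype=float)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    z = norm.ppf(alpha / 100.0)
    base = 1.0 + lam * sigma * z
    if np.any((np.abs(lam) > _LAMBDA_TOL) & (base <= 0)):
        raise ValueError("requested centile lies outside the BCCG support")
    with np.errstate(invalid="ignore", divide="ignore"):
        c_power = mu * np.power(base, 1.0 / np.where(np.abs(lam) > _LAMBDA_TOL, lam, 1.0))
    c_log = mu * np.exp(sigma * z)
    c = np.where(np.abs(lam) > _LAMBDA_TOL, c_power, c_log)
    return c if c.ndim else float(c)


@dataclass
class FitConfig:
    """Smoothing and convergence controls for the penalised LMS fit."""

    n_basis: int = 8                  # cubic B-spline basis size per curve
    edf_mu: float = 4.0               # target effective df of the median curve
    edf_sigma: float = 2.0            # CV curve (2 = penalty null space: linear)
    edf_lambda: float = 2.0           # skewness curve
    grid_step: float = 0.1            # years, resolution of the stored curves
    gtol: float = 1e-8
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if self.grid_step <= 0 or self.gtol <= 0:
            raise ValueError("tolerances must be positive")
        if self.n_basis < 4:
            raise ValueError("need at least 4 basis functions for cubic splines")


@dataclass
class LMSModel:
    """Fitted lambda/mu/sigma curves plus the best-median anchor for t-scores."""

    sex: str
    outcome: str
    age_min: float
    age_max: float
    knots: np.ndarray
    coef_lambda: np.ndarray
    coef_log_mu: np.ndarray
    coef_log_sigma: np.ndarray
    edf: dict = field(default_factory=dict)
    tau: dict = field(default_factory=dict)
    converged: bool = True
    grid_step: float = 0.1

    _DEGREE = 3

    def _spline(self, coef: np.ndarray) -> BSpline:
        return BSpline(self.knots, coef, self._DEGREE, extrapolate=False)

    def age_grid(self) -> np.ndarray:
        grid = np.arange(self.age_min, self.age_max, self.grid_step)
        return np.append(grid, self.age_max)

    def params_at(self, age):
        """(lambda, mu, sigma) at one or more ages inside the fitted range."""
        age = np.asarray(age, dtype=float)
        if np.any(age < self.age_min - 1e-9) or np.any(age > self.age_max + 1e-9):
            raise ValueError(
                f"age outside the fitted range [{self.age_min:.1f}, {self.age_max:.1f}]"
                " years; reference scores are not extrapolated")
        age = np.clip(age, self.age_min, self.age_max)
        lam = self._spline(self.coef_lambda)(age)
        mu = np.exp(self._spline(self.coef_log_mu)(age))
        sigma = np.exp(self._spline(self.coef_log_sigma)(age))
        return lam, mu, sigma

    def z_score(self, y, age):
        lam, mu, sigma = self.params_at(age)
        return bccg_z(y, lam, mu, sigma)

    def centile(self, alpha, age):
        lam, mu, sigma = self.params_at(age)
        return bccg_centile(alpha, lam, mu, sigma)

    # -- persistence ------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "schema_version": _SCHEMA_VERSION,
            "sex": self.sex,
            "outcome": self.outcome,
            "age_min": self.age_min,
            "age_max": self.age_max,
            "knots": self.knots.tolist(),
            "coef_lambda": self.coef_lambda.tolist(),
            "coef_log_mu": self.coef_log_mu.tolist(),
            "coef_log_sigma": self.coef_log_sigma.tolist(),
            "edf": self.edf,
            "tau": self.tau,
            "converged": self.converged,
            "grid_step": self.grid_step,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "LMSModel":
        d = json.loads(Path(path).read_text())
        if d.get("schema_version") != _SCHEMA_VERSION:
            raise ValueError("unsupported reference-model schema version")
        return cls(sex=d["sex"], outcome=d["outcome"], age_min=d["age_min"],
                   age_max=d["age_max"], knots=np.array(d["knots"]),
                   coef_lambda=np.array(d["coef_lambda"]),
                   coef_log_mu=np.array(d["coef_log_mu"]),
                   coef_log_sigma=np.array(d["coef_log_sigma"]),
                   edf=d.get("edf", {}), tau=d.get("tau", {}),
                   converged=d.get("converged", True),
                   grid_step=d.get("grid_step", 0.1))


def best_median_anchor(model: LMSModel) -> tuple[float, float, float, float]:
    """(a*, mu(a*), lambda(a*), sigma(a*)): grid argmax of the median curve.

    Ties across a flat top resolve to the smallest age.
    """
    ages = model.age_grid()
    lam, mu, sigma = model.params_at(ages)
    # first grid age within floating tolerance of the maximum median
    top = mu.max()
    i = int(np.argmax(mu >= top * (1.0 - 1e-12)))
    return float(ages[i]), float(mu[i]), float(lam[i]), float(sigma[i])


# ---------------------------------------------------------------------------
# fitting

def _basis(ages: np.ndarray, age_min: float, age_max: float, n_basis: int):
    k = 3
    n_interior = n_basis - k - 1
    interior = np.linspace(age_min, age_max, n_interior + 2)[1:-1]
    knots = np.concatenate([[age_min] * (k + 1), interior, [age_max] * (k + 1)])
    x = np.clip(ages, age_min, age_max)
    B = BSpline.design_matrix(x, knots, k).toarray()
    return B, knots


def _penalty(p: int) -> np.ndarray:
    D2 = np.diff(np.eye(p), n=2, axis=0)
    return D2.T @ D2


def _edf(B: np.ndarray, w: np.ndarray, P: np.ndarray, tau: float) -> float:
    BtWB = B.T @ (w[:, None] * B)
    return float(np.trace(np.linalg.solve(BtWB + tau * P, BtWB)))


def _calibrate_tau(B: np.ndarray, w: np.ndarray, P: np.ndarray, target: float,
                   lo: float = 1e-6, hi: float = 1e10) -> float:
    """Bisection on log(tau) for trace edf ~= target (edf decreases in tau)."""
    p = B.shape[1]
    target = float(np.clip(target, 2.05, p - 1e-6))
    if _edf(B, w, P, lo) < target:
        return lo
    if _edf(B, w, P, hi) > target:
        return hi
    llo, lhi = np.log(lo), np.log(hi)
    for _ in range(60):
        mid = 0.5 * (llo + lhi)
        if _edf(B, w, P, np.exp(mid)) > target:
            llo = mid
        else:
            lhi = mid
    return float(np.exp(0.5 * (llo + lhi)))


def _nll_and_grad(theta, B, P, logy, taus):
    p = B.shape[1]
    a, b, c = theta[:p], theta[p:2 * p], theta[2 * p:]
    tau_l, tau_m, tau_s = taus
    lam = B @ a
    logmu = B @ b
    logsig = B @ c
    sig = np.exp(logsig)
    r = logy - logmu
    lr = np.clip(lam * r, -60.0, 60.0)
    u = np.exp(lr)
    small = np.abs(lam) <= _LAMBDA_TOL
    lam_safe = np.where(small, 1.0, lam)
    z = np.where(small, r / sig, (u - 1.0) / (lam_safe * sig))

    ll = lam * r - logsig - 0.5 * z * z
    pen = 0.5 * (tau_l * a @ P @ a + tau_m * b @ P @ b + tau_s * c @ P @ c)
    nll = -np.sum(ll) + pen

    dz_dlam = np.where(small, 0.5 * r * r / sig,
                       (u * r) / (lam_safe * sig) - z / lam_safe)
    dl_dlam = r - z * dz_dlam
    dl_dlogmu = -lam + z * u / sig
    dl_dlogsig = z * z - 1.0

    ga = -(B.T @ dl_dlam) + tau_l * (P @ a)
    gb = -(B.T @ dl_dlogmu) + tau_m * (P @ b)
    gc = -(B.T @ dl_dlogsig) + tau_s * (P @ c)
    return nll, np.concatenate([ga, gb, gc])


def _weights(theta, B, logy):
    """Gauss-Newton working weights for the edf calibration of each curve."""
    p = B.shape[1]
    a, b, c = theta[:p], theta[p:2 * p], theta[2 * p:]
    lam = B @ a
    sig = np.exp(B @ c)
    r = logy - B @ b
    u = np.exp(np.clip(lam * r, -60.0, 60.0))
    small = np.abs(lam) <= _LAMBDA_TOL
    lam_safe = np.where(small, 1.0, lam)
    z = np.where(small, r / sig, (u - 1.0) / (lam_safe * sig))
    dz_dlam = np.where(small, 0.5 * r * r / sig,
                       (u * r) / (lam_safe * sig) - z / lam_safe)
    w_lam = np.maximum(dz_dlam ** 2, 1e-8)
    w_mu = (u / sig) ** 2
    w_sig = np.full_like(sig, 2.0)
    return w_lam, w_mu, w_sig


def fit_lms(ages, values, config: FitConfig | None = None, *,
            sex: str = "", outcome: str = "") -> LMSModel:
    """Fit sex-specific LMS curves to (age, value) pairs by penalised likelihood.

    Requires at least 50 records spanning at least ten years of age, all
    values positive. Raises on degenerate data (all values identical) and on
    optimiser failure; there is no silent fallback.
    """
    config = config or FitConfig()
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    if ages.shape != values.shape or ages.ndim != 1:
        raise ValueError("ages and values must be 1-D arrays of equal length")
    if ages.size < 50:
        raise ValueError("need at least 50 records to fit reference curves")
    if ages.max() - ages.min() < 10.0:
        raise ValueError("records must span at least ten years of age")
    if np.any(values <= 0):
        raise ValueError("BCCG outcomes must be positive")
    if np.ptp(values) == 0:
        raise ValueError("degenerate data: all outcome values identical (sigma -> 0)")

    age_min, age_max = float(ages.min()), float(ages.max())
    B, knots = _basis(ages, age_min, age_max, config.n_basis)
    p = B.shape[1]
    P = _penalty(p)
    logy = np.log(values)

    # fixed deterministic starts
    med = float(np.median(values))
    iqr = float(np.subtract(*np.percentile(values, [75, 25])))
    sigma0 = max(iqr / 1.349 / med, 1e-4)
    a0 = np.ones(p)                                   # lambda = 1
    ridge = B.T @ B + 1e-4 * P + 1e-8 * np.eye(p)
    b0 = np.linalg.solve(ridge, B.T @ logy)           # smoothed log-median start
    c0 = np.full(p, np.log(sigma0))
    theta = np.concatenate([a0, b0, c0])

    bounds = ([(-4.0, 4.0)] * p
              + [(np.log(med) - 2.0, np.log(med) + 2.0)] * p
              + [(np.log(sigma0) - 3.0, np.log(sigma0) + 3.0)] * p)

    taus = None
    res = None
    for _round in range(2):  # calibrate tau, fit, recalibrate at optimum, refit
        w_lam, w_mu, w_sig = _weights(theta, B, logy)
        taus = (_calibrate_tau(B, w_lam, P, config.edf_lambda),
                _calibrate_tau(B, w_mu, P, config.edf_mu),
                _calibrate_tau(B, w_sig, P, config.edf_sigma))
        res = optimize.minimize(
            _nll_and_grad, theta, args=(B, P, logy, taus), jac=True,
            method="L-BFGS-B", bounds=bounds,
            options={"maxiter": config.max_iter, "gtol": config.gtol,
                     "ftol": 1e-12})
        theta = res.x
    if res is None or not (res.success or res.status == 1):
        raise RuntimeError(f"LMS fit did not converge: {res.message if res else 'no fit'}")

    w_lam, w_mu, w_sig = _weights(theta, B, logy)
    edf = {"lambda": _edf(B, w_lam, P, taus[0]),
           "mu": _edf(B, w_mu, P, taus[1]),
           "sigma": _edf(B, w_sig, P, taus[2])}
    return LMSModel(sex=sex, outcome=outcome, age_min=age_min, age_max=age_max,
                    knots=knots, coef_lambda=theta[:p],
                    coef_log_mu=theta[p:2 * p], coef_log_sigma=theta[2 * p:],
                    edf=edf, tau={"lambda": taus[0], "mu": taus[1], "sigma": taus[2]},
                    converged=bool(res.success or res.status == 1),
                    grid_step=config.grid_step)
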