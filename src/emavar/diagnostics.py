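"""Residual diagnostics: the four-test validity gate and the trend check.

A candidate model is *valid* only when it passes all four checks:

1. stability — every eigenvalue of the companion matrix lies strictly
   inside the unit circle;
2. white noise — a Ljung-Box portmanteau test on each equation's residuals
   finds no serial autocorrelation;
3. homoscedasticity — the same portmanteau statistic on the *squared*
   residuals finds no persistence in variance;
4. normality — a skewness/kurtosis (Jarque-Bera) omnibus test does not
   reject Gaussian residuals.

All per-variable tests must be nonsignificant, at the shared alpha, for the
model to count as valid. The trend decision uses a Phillips-Perron unit-root
test per endogenous variable: a significant result (stationarity around a
deterministic trend) adds one linear day-index regressor system-wide.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.tsa.adfvalues import mackinnonp

from .data_io import RunConfig
from .var_engine import VarFit

__all__ = [
    "ValidityReport",
    "stability_check",
    "portmanteau",
    "normality_check",
    "assess_validity",
    "validity_report",
    "trend_needed",
    "companion_matrix",
    "portmanteau_maxlag",
]


@dataclass(frozen=True)
class ValidityReport:
    stability: dict
    white_noise: dict
    homoscedasticity: dict
    normality: dict
    overall_valid: bool
    alpha: float

    def failures(self) -> list[str]:
        out = []
        if not self.stability["pass"]:
            out.append("stability")
        for name, res in self.white_noise.items():
            if not res["pass"]:
                out.append(f"white_noise[{name}]")
        for name, res in self.homoscedasticity.items():
            if not res["pass"]:
                out.append(f"homoscedasticity[{name}]")
        for name, res in self.normality.items():
            if not res["pass"]:
                out.append(f"normality[{name}]")
        return out

    def to_dict(self) -> dict:
        return {
            "stability": self.stability,
            "white_noise": self.white_noise,
            "homoscedasticity": self.homoscedasticity,
            "normality": self.normality,
            "overall_valid": self.overall_valid,
            "alpha": self.alpha,
        }


def companion_matrix(lag_matrices: list[np.ndarray]) -> np.ndarray:
    """pV x pV companion form of the lag matrices A_1..A_p."""
    p = len(lag_matrices)
    V = lag_matrices[0].shape[0]
    comp = np.zeros((p * V, p * V))
    comp[:V] = np.hstack(lag_matrices)
    if p > 1:
        comp[V:, : (p - 1) * V] = np.eye((p - 1) * V)
    return comp


def stability_check(fit: VarFit) -> dict:
    """Eigenvalue stability condition on the companion matrix."""
    comp = companion_matrix(fit.lag_coefficients)
    modulus = float(np.max(np.abs(np.linalg.eigvals(comp)))) if comp.size else 0.0
    return {"max_eigenvalue_modulus": modulus, "pass": bool(modulus < 1.0)}


def portmanteau_maxlag(n: int) -> int:
    """Default portmanteau lag horizon: min(12, floor(n/4)), at least 1."""
    return max(1, min(12, n // 4))


def portmanteau(residual_series: np.ndarray, h: int) -> dict:
    """Ljung-Box Q over lags 1..h with a chi-square(h) reference.

    Q = n(n+2) * sum_{j<=h} r_j^2 / (n-j). No degrees-of-freedom reduction
    for fitted lag order is applied (the same form serves both the
    white-noise check and, on squared residuals, the homoscedasticity
    check).
    """
    e = np.asarray(residual_series, dtype=float)
    n = len(e)
    if not n > h >= 1:
        raise ValueError(f"need n > h >= 1, got n={n}, h={h}")
    d = e - e.mean()
    denom = float(d @ d)
    if denom == 0:
        raise ValueError("zero variance: portmanteau undefined on a constant series")
    q = 0.0
    for j in range(1, h + 1):
        r_j = float(d[j:] @ d[:-j]) / denom
        q += r_j * r_j / (n - j)
    q *= n * (n + 2.0)
    return {"Q": float(q), "df": h, "p": float(stats.chi2.sf(q, df=h))}


def normality_check(residual_series: np.ndarray) -> dict:
    """Skewness-kurtosis omnibus (Jarque-Bera) test, chi-square(2) reference."""
    e = np.asarray(residual_series, dtype=float)
    if np.std(e) == 0:
        raise ValueError("zero variance: normality test undefined on a constant series")
    if len(e) < 8:
        warnings.warn(
            f"normality test on only n={len(e)} residuals is unreliable",
            UserWarning,
            stacklevel=2,
        )
    n = len(e)
    d = e - e.mean()
    m2 = float(np.mean(d**2))
    s = float(np.mean(d**3)) / m2**1.5  # sample skewness (biased moments)
    kurt = float(np.mean(d**4)) / m2**2  # sample kurtosis, normal reference 3
    jb = n / 6.0 * (s**2 + (kurt - 3.0) ** 2 / 4.0)
    p = float(stats.chi2.sf(jb, df=2))
    return {"statistic": jb, "p": p}


def validity_report(fit: VarFit, alpha: float) -> ValidityReport:
    """Run all four checks on a fit and combine the verdict."""
    stab = stability_check(fit)
    h = portmanteau_maxlag(fit.T_eff)
    white, hetero, normal = {}, {}, {}
    valid = stab["pass"]
    for name in fit.variable_names:
        e = fit.residuals[name].to_numpy()
        wn = portmanteau(e, h)
        wn["pass"] = bool(wn["p"] >= alpha)
        hc = portmanteau((e - e.mean()) ** 2, h)
        hc["pass"] = bool(hc["p"] >= alpha)
        nm = normality_check(e)
        nm["pass"] = bool(nm["p"] >= alpha)
        white[name], hetero[name], normal[name] = wn, hc, nm
        valid = valid and wn["pass"] and hc["pass"] and nm["pass"]
    return ValidityReport(
        stability=stab,
        white_noise=white,
        homoscedasticity=hetero,
        normality=normal,
        overall_valid=bool(valid),
        alpha=alpha,
    )


def assess_validity(fit: VarFit, config: RunConfig) -> ValidityReport:
    """Four-test validity gate at the run's shared significance level."""
    return validity_report(fit, config.alpha)


def trend_needed(series: np.ndarray, alpha: float = 0.05) -> dict:
    """Phillips-Perron check for stationarity around a deterministic trend.

    Fits y_t = c + b t + rho y_{t-1} + u_t and corrects the t-statistic of
    rho = 1 with a Bartlett-kernel long-run variance at bandwidth
    floor(4 (T/100)^(1/4)) (the Z_tau statistic). A significant result
    rejects the unit root in favour of trend stationarity, in which case a
    linear trend regressor is added to the model.
    """
    y = np.asarray(series, dtype=float)
    T = len(y)
    if T < 20:
        raise ValueError(f"trend check needs T >= 20, got {T}")
    if np.std(y) == 0:
        warnings.warn("constant series: no trend decision possible", UserWarning, stacklevel=2)
        return {"statistic": float("nan"), "p": 1.0, "include_trend": False}
    ylag = y[:-1]
    dep = y[1:]
    n = len(dep)
    X = np.column_stack([np.ones(n), np.arange(1, n + 1, dtype=float), ylag])
    beta, *_ = np.linalg.lstsq(X, dep, rcond=None)
    u = dep - X @ beta
    dof = n - X.shape[1]
    s2 = float(u @ u) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se_rho = math.sqrt(s2 * xtx_inv[2, 2])
    t_rho = (beta[2] - 1.0) / se_rho
    # Bartlett-weighted long-run variance of the regression errors
    q = int(4 * (T / 100.0) ** 0.25)
    gamma0 = float(u @ u) / n
    lam2 = gamma0
    for j in range(1, q + 1):
        gamma_j = float(u[j:] @ u[:-j]) / n
        lam2 += 2.0 * (1.0 - j / (q + 1.0)) * gamma_j
    if lam2 <= 0:  # guard: kernel estimate can go nonpositive on tiny samples
        lam2 = gamma0
    z_tau = math.sqrt(gamma0 / lam2) * t_rho - (lam2 - gamma0) / (
        2.0 * math.sqrt(lam2)
    ) * (n * se_rho / math.sqrt(s2))
    p = float(mackinnonp(z_tau, regression="ct", N=1))
    return {"statistic": float(z_tau), "p": p, "include_trend": bool(p < alpha)}
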