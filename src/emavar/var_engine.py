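"""Equation-wise VAR estimation, information criteria and constraint pruning.

A VAR(p) treats every diary variable as endogenous: each variable is
regressed on a constant, p lags of *all* endogenous variables and the
spec's exogenous columns. Estimation is ordinary least squares per
equation; constrained coefficients are simply removed from that equation's
regressor set. The system Gaussian log-likelihood (with additive
constants, MLE residual covariance with divisor T_eff) feeds

    AIC = -2 logL + 2 k        BIC = -2 logL + k ln T

with T the nominal series length and k the number of freely estimated
regression coefficients across all equations (intercepts included,
constrained positions and covariance entries excluded). By construction
BIC - AIC = k (ln T - 2).

Pruning repeatedly zeroes the single least significant lag/exogenous
coefficient (highest p-value above alpha, system-wide) and keeps the step
only while the chosen criterion strictly decreases; the four validity
checks are re-run after every accepted constraint.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data_io import EmaDataset
from .spec_builder import ModelSpec

__all__ = [
    "VarFit",
    "DegenerateFitError",
    "CollinearityError",
    "build_design",
    "fit_var",
    "information_criteria",
    "prune_parameters",
]


class DegenerateFitError(RuntimeError):
    """Zero residual variance: coefficient inference is undefined."""

    def __init__(self, message: str, coefficients: Optional[pd.DataFrame] = None):
        super().__init__(message)
        self.coefficients = coefficients


class CollinearityError(ValueError):
    """Rank-deficient regressor matrix; names the offending columns."""


@dataclass(frozen=True)
class VarFit:
    """A fitted (possibly constrained) VAR model.

    ``coefficients``/``se``/``pvalues`` are V x K frames indexed by equation
    variable, columns in the fixed regressor order. Constrained positions
    hold coefficient 0 with SE and p-value NaN.
    """

    spec: ModelSpec
    variable_names: tuple[str, ...]
    regressor_labels: tuple[str, ...]
    coefficients: pd.DataFrame
    se: pd.DataFrame
    pvalues: pd.DataFrame
    residuals: pd.DataFrame
    residual_covariance: np.ndarray
    k: int
    logL: float
    aic: float
    bic: float
    T: int
    T_eff: int
    constraints: frozenset[tuple[str, str]]
    cov_params: dict = field(repr=False)
    design: tuple = field(repr=False)  # (Y, X) ndarrays, kept for refits
    validity_history: tuple = ()

    @property
    def intercepts(self) -> np.ndarray:
        return self.coefficients["const"].to_numpy()

    @property
    def lag_coefficients(self) -> list[np.ndarray]:
        """p matrices A_1..A_p with A[l][i, j] = effect of var j at lag l+1 on var i."""
        out = []
        for lag in range(1, self.spec.lag + 1):
            cols = [f"L{lag}.{v}" for v in self.variable_names]
            out.append(self.coefficients[cols].to_numpy())
        return out

    @property
    def exogenous_coefficients(self) -> pd.DataFrame:
        lag_cols = {f"L{l}.{v}" for l in range(1, self.spec.lag + 1) for v in self.variable_names}
        cols = [c for c in self.regressor_labels if c != "const" and c not in lag_cols]
        return self.coefficients[cols]

    def to_json(self) -> str:
        """Structured-text export of the fitted model."""
        table = []
        for eq in self.variable_names:
            for label in self.regressor_labels:
                constrained = (eq, label) in self.constraints
                table.append(
                    {
                        "equation": eq,
                        "regressor": label,
                        "estimate": float(self.coefficients.loc[eq, label]),
                        "se": None if constrained else float(self.se.loc[eq, label]),
                        "p": None if constrained else float(self.pvalues.loc[eq, label]),
                        "constrained": constrained,
                    }
                )
        payload = {
            "spec": self.spec.describe(),
            "coefficients": table,
            "k": self.k,
            "logL": self.logL,
            "AIC": self.aic,
            "BIC": self.bic,
        }
        return json.dumps(payload, indent=2)


def build_design(
    dataset: EmaDataset, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Stack the response block and the shared regressor matrix.

    Regressor order: intercept, lagged endogenous (lag 1..p, variables in
    dataset order within each lag), then the materialized exogenous columns
    (trend, weekday dummies, outlier dummies, user exogenous). Every
    equation shares the same regressor matrix.
    """
    p = spec.lag
    values = dataset.values.to_numpy(dtype=float)
    T, V = values.shape
    if T <= p:
        raise ValueError(f"need more than lag={p} rows, got T={T}")
    Y = values[p:]
    cols = [np.ones(T - p)]
    labels = ["const"]
    for lag in range(1, p + 1):
        block = values[p - lag : T - lag]
        cols.append(block)
        labels.extend(f"L{lag}.{v}" for v in dataset.variable_names)
    if dataset.exogenous is not None:
        exog = dataset.exogenous.to_numpy(dtype=float)[p:]
        cols.append(exog)
        labels.extend(dataset.exogenous.columns)
    X = np.column_stack(cols)
    if Y.shape[0] < X.shape[1]:
        raise ValueError(
            f"insufficient observations: T_eff={Y.shape[0]} < K={X.shape[1]} regressors"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X)
        bad = [labels[i] for i in range(X.shape[1]) if abs(R[i, i]) < 1e-10]
        raise CollinearityError(f"collinear regressor column(s): {bad or labels}")
    return Y, X, labels


def fit_var(dataset: EmaDataset, spec: ModelSpec) -> VarFit:
    """Estimate the spec by equation-wise OLS on the materialized dataset.

    Raises :class:`DegenerateFitError` (carrying the point estimates) when
    any equation has zero residual variance.
    """
    Y, X, labels = build_design(dataset, spec)
    return _fit_from_design(Y, X, labels, dataset, spec)


def _fit_from_design(Y, X, labels, dataset: EmaDataset, spec: ModelSpec) -> VarFit:
    T_eff, V = Y.shape
    names = tuple(dataset.variable_names)
    K = len(labels)
    coef_arr = np.zeros((V, K))
    se_arr = np.full((V, K), np.nan)
    p_arr = np.full((V, K), np.nan)
    resid = np.empty((T_eff, V))
    cov_params: dict[str, tuple[list[str], np.ndarray]] = {}
    k = 0
    degenerate = False
    for i, eq in enumerate(names):
        free = [j for j, lab in enumerate(labels) if (eq, lab) not in spec.constraints]
        res = sm.OLS(Y[:, i], X[:, free]).fit()
        coef_arr[i, free] = res.params
        resid[:, i] = res.resid
        k += len(free)
        if res.ssr <= 1e-12 * max(1.0, float(np.sum(Y[:, i] ** 2))):
            degenerate = True
            continue
        se_arr[i, free] = res.bse
        p_arr[i, free] = res.pvalues
        cov_params[eq] = ([labels[j] for j in free], np.asarray(res.cov_params()))
    coef = pd.DataFrame(coef_arr, index=list(names), columns=labels)
    se = pd.DataFrame(se_arr, index=list(names), columns=labels)
    pval = pd.DataFrame(p_arr, index=list(names), columns=labels)
    if degenerate:
        raise DegenerateFitError(
            "degenerate fit: zero residual variance, inference undefined",
            coefficients=coef,
        )
    sigma = resid.T @ resid / T_eff
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        raise DegenerateFitError("degenerate fit: singular residual covariance", coef)
    logL = -0.5 * T_eff * (V * math.log(2 * math.pi) + logdet + V)
    T = dataset.T
    aic = -2.0 * logL + 2.0 * k
    bic = -2.0 * logL + k * math.log(T)
    return VarFit(
        spec=spec,
        variable_names=names,
        regressor_labels=tuple(labels),
        coefficients=coef,
        se=se,
        pvalues=pval,
        residuals=pd.DataFrame(resid, columns=names),
        residual_covariance=sigma,
        k=k,
        logL=float(logL),
        aic=float(aic),
        bic=float(bic),
        T=T,
        T_eff=T_eff,
        constraints=spec.constraints,
        cov_params=cov_params,
        design=(Y, X),
    )


def information_criteria(fit: VarFit) -> tuple[float, float]:
    """(AIC, BIC) of a fit; identical to the values stored on it."""
    return fit.aic, fit.bic


def _criterion(fit: VarFit, criterion: str) -> float:
    return fit.aic if criterion.upper() == "AIC" else fit.bic


def prune_parameters(
    dataset: EmaDataset,
    fit: VarFit,
    criterion: str = "AIC",
    alpha: float = 0.05,
) -> VarFit:
    """Iteratively constrain nonsignificant coefficients to zero.

    At each step the single lag/exogenous coefficient with the highest
    p-value above ``alpha`` (intercepts are never pruned) is fixed to zero
    and the system refitted; the step stands only if the chosen criterion
    strictly decreased, otherwise it is reverted and pruning stops. After
    every accepted constraint the four validity checks are re-run and
    appended to ``validity_history``.
    """
    from .diagnostics import validity_report  # local import to avoid a cycle

    Y, X = fit.design
    labels = list(fit.regressor_labels)
    current = fit
    history = list(fit.validity_history)
    while True:
        pmat = current.pvalues.to_numpy()
        candidates = []
        for i, eq in enumerate(current.variable_names):
            for j, label in enumerate(labels):
                if label == "const" or (eq, label) in current.constraints:
                    continue
                p = pmat[i, j]
                if np.isfinite(p) and p > alpha:
                    # order index makes the highest-p tie-break deterministic
                    candidates.append((float(p), -(i * len(labels) + j), eq, label))
        if not candidates:
            return current
        _, _, eq, label = max(candidates)
        new_spec = replace(
            current.spec, constraints=current.spec.constraints | {(eq, label)}
        )
        trial = _fit_from_design(Y, X, labels, dataset, new_spec)
        if _criterion(trial, criterion) < _criterion(current, criterion):
            history.append(validity_report(trial, alpha))
            current = replace(trial, validity_history=tuple(history))
        else:
            return current
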