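"""Two-stage least-squares (regression-imputation) expression-trait analysis.

Stage 1 regresses measured expression on genotype in the TWAS dataset
(optionally with inverse-probability weights); stage 2 predicts expression
from genotype in the independent GWAS dataset and regresses the trait on the
prediction.  The stage-2 slope estimates the population expression-trait
association; because the regressor is a prediction rather than the true
expression, its nominal confidence interval ignores first-stage estimation
error and covers below the nominal level even under random sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "OLSFit",
    "StageOneFit",
    "StageTwoFit",
    "weighted_ols",
    "stage_one",
    "predict_expression",
    "stage_two",
    "relative_bias",
    "ci_covers",
    "mean_predicted_expression",
]


@dataclass(frozen=True)
class OLSFit:
    """Coefficients, classical standard errors, residual sd and residual
    degrees of freedom of a (weighted) least-squares fit."""

    coef: np.ndarray
    se: np.ndarray
    resid_sd: float
    df: int


def weighted_ols(
    X: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None
) -> OLSFit:
    """Least squares minimizing sum_i w_i (y_i - X_i b)^2.

    Unweighted when ``weights`` is None (all weights 1).  Standard errors are
    the classical homoskedastic ones, sigma^2 (X'WX)^{-1}, with
    sigma^2 = weighted RSS / (n - p).  Raises on rank-deficient designs.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < p:
        raise ValueError("fewer rows than columns")
    if weights is None:
        Xw, yw = X, y
    else:
        weights = np.asarray(weights, dtype=float)
        if np.any(weights < 0):
            raise ValueError("weights must be nonnegative")
        sw = np.sqrt(weights)
        Xw, yw = X * sw[:, None], y * sw
    xtx = Xw.T @ Xw
    if np.linalg.matrix_rank(xtx) < p:
        raise ValueError("rank-deficient design matrix")
    xtx_inv = np.linalg.inv(xtx)
    coef = xtx_inv @ (Xw.T @ yw)
    resid = yw - Xw @ coef
    df = n - p
    sigma2 = float(resid @ resid) / df if df > 0 else 0.0
    se = np.sqrt(np.clip(sigma2 * np.diag(xtx_inv), 0.0, None))
    return OLSFit(coef=coef, se=se, resid_sd=float(np.sqrt(sigma2)), df=df)


@dataclass(frozen=True)
class StageOneFit:
    """Estimated eQTL model: intercept, two SNP coefficients, residual sd."""

    alpha0_hat: float
    alpha1_hat: float
    alpha2_hat: float
    residual_sd: float
    weights_used: str  # "none" | "known" | "estimated"
    n1: int

    @property
    def coef(self) -> np.ndarray:
        return np.array([self.alpha0_hat, self.alpha1_hat, self.alpha2_hat])


def stage_one(
    z: np.ndarray, x: np.ndarray, weights: np.ndarray | None = None,
    weights_used: str = "none",
) -> StageOneFit:
    """Fit expression on genotype, x ~ 1 + z1 + z2, optionally IPW-weighted."""
    z = np.asarray(z)
    x = np.asarray(x, dtype=float)
    n1 = x.size
    if n1 < 4:
        raise ValueError("stage 1 needs at least 4 observations")
    X = np.column_stack([np.ones(n1), z])
    fit = weighted_ols(X, x, weights)
    if weights is not None and weights_used == "none":
        weights_used = "known"
    return StageOneFit(
        alpha0_hat=float(fit.coef[0]),
        alpha1_hat=float(fit.coef[1]),
        alpha2_hat=float(fit.coef[2]),
        residual_sd=fit.resid_sd,
        weights_used=weights_used,
        n1=n1,
    )


def predict_expression(fit: StageOneFit, z: np.ndarray) -> np.ndarray:
    """Genotype-predicted expression: alpha0_hat + z @ (alpha1_hat,
    alpha2_hat).  No residual noise is added."""
    z = np.asarray(z, dtype=float)
    return fit.alpha0_hat + z @ np.array([fit.alpha1_hat, fit.alpha2_hat])


@dataclass(frozen=True)
class StageTwoFit:
    """Trait on predicted expression: slope, classical SE and t-based 95% CI."""

    gamma0_hat: float
    gamma1_hat: float
    se_gamma1: float
    ci_low: float
    ci_high: float
    ci_length: float
    n2: int
    xhat_mean: float


def stage_two(xhat: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> StageTwoFit:
    """Unweighted OLS of the trait on predicted expression, with a
    t(n2-2)-based confidence interval on the slope."""
    xhat = np.asarray(xhat, dtype=float)
    y = np.asarray(y, dtype=float)
    n2 = y.size
    if n2 < 3:
        raise ValueError("stage 2 needs at least 3 observations")
    if np.ptp(xhat) == 0:
        raise ValueError("predicted expression is constant: degenerate regressor")
    X = np.column_stack([np.ones(n2), xhat])
    fit = weighted_ols(X, y)
    tcrit = float(stats.t.ppf(1 - alpha / 2, n2 - 2))
    lo = float(fit.coef[1] - tcrit * fit.se[1])
    hi = float(fit.coef[1] + tcrit * fit.se[1])
    return StageTwoFit(
        gamma0_hat=float(fit.coef[0]),
        gamma1_hat=float(fit.coef[1]),
        se_gamma1=float(fit.se[1]),
        ci_low=lo,
        ci_high=hi,
        ci_length=hi - lo,
        n2=n2,
        xhat_mean=float(xhat.mean()),
    )


def relative_bias(estimate: float, truth: float) -> float:
    """Percent relative bias, 100 * (estimate - truth) / truth."""
    if truth == 0:
        raise ValueError("relative bias undefined for a zero true value")
    return 100.0 * (estimate - truth) / truth


def ci_covers(ci_low: float, ci_high: float, truth: float) -> bool:
    """Closed-interval coverage indicator: ci_low <= truth <= ci_high."""
    if ci_low > ci_high:
        raise ValueError("ci_low exceeds ci_high")
    return bool(ci_low <= truth <= ci_high)


def mean_predicted_expression(xhat: np.ndarray) -> tuple[float, float]:
    """Mean predicted expression on the log2 scale and its base-2 anti-log.

    The anti-log ``2**mean`` is a reporting convention (geometric-mean scale),
    not the arithmetic mean of raw-scale expression.
    """
    xhat = np.asarray(xhat, dtype=float)
    if xhat.size == 0:
        raise ValueError("empty prediction vector")
    m = float(xhat.mean())
    return m, float(2.0**m)
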