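"""Analysis-model fitting and average-treatment-effect estimators.

The propensity score π(Z) = P(X=1 | Z) is fit by maximum-likelihood
logistic regression (IRLS); per-arm outcome means μ₁(Z), μ₀(Z) by least
squares among the exposed and unexposed (which is equivalent to a full
exposure interaction).  Two ATE estimators are provided:

IPW:   Δ̂ = n⁻¹ Σᵢ [ XᵢYᵢ/πᵢ − (1−Xᵢ)Yᵢ/(1−πᵢ) ]

AIPW:  Δ̂ = n⁻¹ Σᵢ [ μ₁ᵢ − μ₀ᵢ + Xᵢ(Yᵢ−μ₁ᵢ)/πᵢ − (1−Xᵢ)(Yᵢ−μ₀ᵢ)/(1−πᵢ) ]

AIPW is doubly robust: consistent when either the propensity model or the
outcome models are correctly specified.  The within-dataset variance U is
the empirical variance of the unit-level influence contribution φᵢ divided
by n, treating π and μ as known.

A weighted-outcome-regression alternative (`weighted_outcome_ate`) fits an
ATE-weighted outcome model with an exposure-confounder interaction and
averages the fitted exposed/unexposed contrast, with a fixed-weights HC0
sandwich variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .design import DesignMatrix, Term, build_design_matrix
from .dgp import CompleteData, ObservedData
from .errors import (
    DegenerateFitError,
    EstimationError,
    SeparationError,
)

logger = logging.getLogger(__name__)

#: fitted propensity probabilities are clipped into [CLIP, 1−CLIP] before
#: weight formation; no weight truncation is applied.
PROB_CLIP = 1e-9

IRLS_TOL = 1e-8
IRLS_MAXITER = 25


@dataclass
class FitResult:
    coefficients: np.ndarray
    fitted_values: np.ndarray
    residual_variance: float
    design_info: dict = field(default_factory=dict)
    converged: bool = True


@dataclass
class ATEEstimate:
    """Point estimate Δ̂ with its within-dataset variance U."""

    delta_hat: float
    variance: float
    estimator_id: str
    n_used: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.delta_hat):
            raise EstimationError("non-finite ATE estimate")
        if self.variance < 0:
            raise EstimationError("negative variance")


# ---------------------------------------------------------------------------
# model fits
# ---------------------------------------------------------------------------


def _solve_sym(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.solve(a, b)
    except np.linalg.LinAlgError:
        ridge = 1e-5 * np.mean(np.diag(a))
        a = a + ridge * np.eye(a.shape[0])
        try:
            return np.linalg.solve(a, b)
        except np.linalg.LinAlgError as exc:
            raise DegenerateFitError("singular system beyond ridge tolerance") from exc


def fit_logistic(design: DesignMatrix, outcome: np.ndarray) -> FitResult:
    """Maximum-likelihood logistic regression via IRLS.

    Converges when the largest absolute coefficient change drops below
    ``IRLS_TOL`` within ``IRLS_MAXITER`` iterations; otherwise the result is
    flagged ``converged=False`` for the caller to log.
    """
    X = design.values
    y = np.asarray(outcome, dtype=float)
    if y.min() == y.max():
        raise SeparationError("logistic outcome contains a single class")
    beta = np.zeros(X.shape[1])
    converged = False
    for _ in range(IRLS_MAXITER):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        xw = X * w[:, None]
        beta_new = _solve_sym(xw.T @ X, xw.T @ z)
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if step < IRLS_TOL:
            converged = True
            break
    fitted = expit(X @ beta)
    return FitResult(beta, fitted, 0.0, {"knot_store": design.knot_store}, converged)


def fit_ols(design: DesignMatrix, outcome: np.ndarray) -> FitResult:
    """Least squares with residual variance RSS/(n−p)."""
    X = design.values
    y = np.asarray(outcome, dtype=float)
    n, p = X.shape
    if n <= p:
        raise DegenerateFitError(f"need n > p for OLS (n={n}, p={p})")
    beta = _solve_sym(X.T @ X, X.T @ y)
    fitted = X @ beta
    resid = y - fitted
    return FitResult(
        beta,
        fitted,
        float(resid @ resid) / (n - p),
        {"knot_store": design.knot_store},
    )


# ---------------------------------------------------------------------------
# ATE estimators
# ---------------------------------------------------------------------------


def _frame(data) -> pd.DataFrame:
    return data.df if isinstance(data, CompleteData) else data


def _influence_estimate(phi: np.ndarray, estimator_id: str) -> ATEEstimate:
    n = len(phi)
    return ATEEstimate(
        float(phi.mean()),
        float(phi.var(ddof=1)) / n if n > 1 else 0.0,
        estimator_id,
        n,
    )


def aipw_from_components(
    x: np.ndarray,
    y: np.ndarray,
    pi: np.ndarray,
    mu1: np.ndarray,
    mu0: np.ndarray,
    estimator_id: str = "aipw",
) -> ATEEstimate:
    """AIPW estimate from already-computed π, μ₁, μ₀ (the estimating kernel)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    phi = mu1 - mu0 + x * (y - mu1) / pi - (1.0 - x) * (y - mu0) / (1.0 - pi)
    return _influence_estimate(phi, estimator_id)


def _fit_propensity(df: pd.DataFrame, ps_terms: list[Term]) -> np.ndarray:
    dm = build_design_matrix(df, ps_terms)
    fit = fit_logistic(dm, df["x"].to_numpy())
    if not fit.converged:
        logger.info("propensity IRLS did not converge in %d iterations", IRLS_MAXITER)
    pi = np.clip(fit.fitted_values, PROB_CLIP, 1.0 - PROB_CLIP)
    n_clip = int(np.sum((fit.fitted_values <= PROB_CLIP) | (fit.fitted_values >= 1 - PROB_CLIP)))
    if n_clip:
        logger.info("near-positivity violation: %d probabilities at clip boundary", n_clip)
    return pi


def _fit_arm_means(
    df: pd.DataFrame, outcome_terms: list[Term]
) -> tuple[np.ndarray, np.ndarray]:
    """μ₁ and μ₀ predictions for every row, each fit on its own arm.

    Spline knots are fitted within the arm and frozen for out-of-arm
    prediction.
    """
    x = df["x"].to_numpy()
    y = df["y"].to_numpy()
    mus = {}
    for arm in (1.0, 0.0):
        rows = x == arm
        if not rows.any():
            raise EstimationError(f"empty exposure arm x={int(arm)}")
        dm_fit = build_design_matrix(df.loc[rows], outcome_terms)
        fit = fit_ols(dm_fit, y[rows])
        dm_all = build_design_matrix(df, outcome_terms, knot_store=dm_fit.knot_store)
        mus[arm] = dm_all.values @ fit.coefficients
    return mus[1.0], mus[0.0]


def aipw_ate(data, ps_terms: list[Term], outcome_terms: list[Term]) -> ATEEstimate:
    """Doubly robust AIPW estimate of the ATE on one complete dataset."""
    df = _frame(data)
    pi = _fit_propensity(df, ps_terms)
    mu1, mu0 = _fit_arm_means(df, outcome_terms)
    return aipw_from_components(df["x"].to_numpy(), df["y"].to_numpy(), pi, mu1, mu0)


def ipw_ate(data, ps_terms: list[Term]) -> ATEEstimate:
    """Inverse-probability-weighted estimate (AIPW with μ ≡ 0)."""
    df = _frame(data)
    pi = _fit_propensity(df, ps_terms)
    zero = np.zeros(len(df))
    return aipw_from_components(
        df["x"].to_numpy(), df["y"].to_numpy(), pi, zero, zero, estimator_id="ipw"
    )


def complete_case_ate(
    obs: ObservedData, ps_terms: list[Term], outcome_terms: list[Term]
) -> ATEEstimate:
    """Drop rows with a masked entry, then apply AIPW to the remainder."""
    df = obs.base.df.loc[~obs.mask]
    est = aipw_ate(df, ps_terms, outcome_terms)
    est.estimator_id = "complete_case_aipw"
    return est


def weighted_outcome_ate(
    data, ps_terms: list[Term], outcome_terms: list[Term]
) -> ATEEstimate:
    """ATE via an IPW-weighted outcome regression with an X-confounder
    interaction, averaged over the sample; fixed-weights HC0 variance."""
    import statsmodels.api as sm

    df = _frame(data)
    x = df["x"].to_numpy()
    y = df["y"].to_numpy()
    if not (x == 1).any() or not (x == 0).any():
        raise EstimationError("empty exposure arm")
    pi = _fit_propensity(df, ps_terms)
    w = x / pi + (1.0 - x) / (1.0 - pi)

    conf = "zc1" if "zc1" in df.columns else "zc"
    dm = build_design_matrix(df, outcome_terms)

    def assemble(xv: np.ndarray) -> np.ndarray:
        return np.column_stack([dm.values, xv, xv * df[conf].to_numpy()])

    res = sm.WLS(y, assemble(x), weights=w).fit(cov_type="HC0")
    contrast = assemble(np.ones(len(df))) - assemble(np.zeros(len(df)))
    a = contrast.mean(axis=0)
    delta = float(a @ res.params)
    var = float(a @ res.cov_params() @ a)
    return ATEEstimate(delta, var, "weighted_outcome", len(df))


ESTIMATORS = ("aipw", "ipw", "weighted_outcome")


def estimate_ate(
    data, estimator_id: str, ps_terms: list[Term], outcome_terms: list[Term]
) -> ATEEstimate:
    """Dispatch on estimator label (used by the simulation harness and CLI)."""
    if estimator_id == "aipw":
        return aipw_ate(data, ps_terms, outcome_terms)
    if estimator_id == "ipw":
        return ipw_ate(data, ps_terms)
    if estimator_id == "weighted_outcome":
        return weighted_outcome_ate(data, ps_terms, outcome_terms)
    raise EstimationError(f"unknown estimator {estimator_id!r}")
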