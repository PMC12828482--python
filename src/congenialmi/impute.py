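"""Multiple imputation of a single missing variable by Bayesian normal
linear regression (posterior-predictive draws), optionally stratified by
exposure, plus a catalog of named imputation-model variants.

Because exactly one variable is incomplete per missingness pattern and all
its predictors are fully observed, a single regression-and-draw per
imputation is exactly equivalent to a chained-equations pass; no iteration
is needed.

The draw is the standard "norm" method: with least-squares fit
(β̂, RSS, ν = n−p) on the observed-response rows,

    g  ~ χ²(ν),          σ*² = RSS / g,
    β* ~ N(β̂, σ*²·(XᵀX)⁻¹),
    imputations = X_pred β* + N(0, σ*²·I),

so parameter uncertainty propagates into the between-imputation variance.

When fits are stratified by exposure the strata are processed in the order
X=0 then X=1, one draw stream across strata and imputations, which fixes the
random-number consumption order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .design import Term, build_design_matrix
from .dgp import CompleteData, ObservedData
from .errors import (
    DegenerateFitError,
    InvalidArgumentError,
    SmallStratumError,
)

#: relative ridge added to XᵀX when its Cholesky factorization fails
#: (near-collinear spline bases at small n); multiplies the mean diagonal.
RIDGE_REL = 1e-5

COMPLETE_CASE = "complete_case"


@dataclass(frozen=True)
class ImputationSpec:
    """Declarative description of one imputation strategy."""

    response: str | None
    predictor_terms: tuple[Term, ...] = ()
    stratify_by_exposure: bool = False
    m: int = 20
    variant_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "predictor_terms", tuple(self.predictor_terms))
        if self.variant_id == COMPLETE_CASE:
            return
        if self.m < 2:
            raise InvalidArgumentError("m must be >= 2")
        if self.stratify_by_exposure and any(
            t.variable == "x" for t in self.predictor_terms
        ):
            raise InvalidArgumentError(
                "x cannot be a predictor when stratifying by exposure"
            )

    @property
    def is_complete_case(self) -> bool:
        return self.variant_id == COMPLETE_CASE

    @classmethod
    def complete_case(cls) -> "ImputationSpec":
        """Sentinel spec: drop incomplete rows instead of imputing."""
        return cls(response=None, variant_id=COMPLETE_CASE)

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "predictor_terms": [t.to_dict() for t in self.predictor_terms],
            "stratify_by_exposure": self.stratify_by_exposure,
            "m": self.m,
            "variant_id": self.variant_id,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ImputationSpec":
        return cls(
            response=d.get("response"),
            predictor_terms=tuple(
                Term.from_dict(t) for t in d.get("predictor_terms", [])
            ),
            stratify_by_exposure=d.get("stratify_by_exposure", False),
            m=d.get("m", 20),
            variant_id=d.get("variant_id", ""),
        )


@dataclass
class ImputedStack:
    """m completed datasets drawn for one observed dataset."""

    datasets: list[CompleteData]
    spec: ImputationSpec
    source: ObservedData

    def __len__(self) -> int:
        return len(self.datasets)

    def __iter__(self):
        return iter(self.datasets)


# ---------------------------------------------------------------------------
# Bayesian normal-linear draw
# ---------------------------------------------------------------------------


class _BayesLinearFit:
    """Precomputed least-squares state shared by the m posterior draws."""

    def __init__(self, X: np.ndarray, y: np.ndarray):
        n, p = X.shape
        if n <= p:
            raise SmallStratumError(
                f"need more rows than parameters to draw (n={n}, p={p})"
            )
        xtx = X.T @ X
        xty = X.T @ y
        try:
            chol = cho_factor(xtx, lower=True)
        except np.linalg.LinAlgError:
            xtx = xtx + RIDGE_REL * np.mean(np.diag(xtx)) * np.eye(p)
            try:
                chol = cho_factor(xtx, lower=True)
            except np.linalg.LinAlgError as exc:
                raise DegenerateFitError(
                    "design matrix singular beyond ridge tolerance"
                ) from exc
        self.beta_hat = cho_solve(chol, xty)
        resid = y - X @ self.beta_hat
        self.rss = float(resid @ resid)
        self.dof = n - p
        self._chol_lower = chol[0]  # R with R Rᵀ = XᵀX

    def draw(self, rng: np.random.Generator, X_pred: np.ndarray) -> np.ndarray:
        if X_pred.shape[0] == 0:
            return np.empty(0)
        g = rng.chisquare(self.dof)
        sigma2 = self.rss / g
        sigma = np.sqrt(sigma2)
        z = rng.standard_normal(len(self.beta_hat))
        # R⁻ᵀ z has covariance (R Rᵀ)⁻¹ = (XᵀX)⁻¹
        beta_star = self.beta_hat + sigma * solve_triangular(
            self._chol_lower, z, lower=True, trans="T"
        )
        noise = rng.standard_normal(X_pred.shape[0])
        return X_pred @ beta_star + sigma * noise


def bayes_norm_draw(
    X_fit: np.ndarray, y_fit: np.ndarray, X_pred: np.ndarray, rng
) -> np.ndarray:
    """One posterior-predictive imputation vector for the rows of ``X_pred``."""
    X_fit = np.asarray(X_fit, dtype=float)
    X_pred = np.asarray(X_pred, dtype=float)
    y_fit = np.asarray(y_fit, dtype=float)
    fit = _BayesLinearFit(X_fit, y_fit)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return fit.draw(rng, X_pred)


# ---------------------------------------------------------------------------
# multiple imputation
# ---------------------------------------------------------------------------


def multiply_impute(obs: ObservedData, spec: ImputationSpec, seed) -> ImputedStack:
    """Draw ``spec.m`` completed datasets for ``obs``.

    Fits are restricted to observed-response rows (within each exposure
    stratum when ``spec.stratify_by_exposure``); spline knots are fitted on
    those rows and frozen for the prediction rows.  Observed entries pass
    through untouched in every completed dataset.
    """
    if spec.is_complete_case:
        raise InvalidArgumentError("complete_case spec does not impute; drop rows instead")
    target = obs.target_variable
    if spec.response != target:
        raise InvalidArgumentError(
            f"spec imputes {spec.response!r} but pattern masks {target!r}"
        )
    df = obs.base.df
    mask = obs.mask
    if spec.stratify_by_exposure:
        x = df["x"].to_numpy()
        groups = [x == 0.0, x == 1.0]
    else:
        groups = [np.ones(len(df), dtype=bool)]

    plans: list[tuple[np.ndarray, _BayesLinearFit, np.ndarray]] = []
    for g in groups:
        fit_rows = g & ~mask
        pred_rows = g & mask
        dm_fit = build_design_matrix(df.loc[fit_rows], list(spec.predictor_terms))
        if dm_fit.n <= dm_fit.p:
            raise SmallStratumError(
                f"stratum has {dm_fit.n} observed rows for {dm_fit.p} parameters"
            )
        fit = _BayesLinearFit(dm_fit.values, df.loc[fit_rows, target].to_numpy())
        dm_pred = build_design_matrix(
            df.loc[pred_rows], list(spec.predictor_terms), knot_store=dm_fit.knot_store
        )
        plans.append((pred_rows, fit, dm_pred.values))

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    datasets = []
    for _ in range(spec.m):
        completed = df.copy()
        for pred_rows, fit, X_pred in plans:
            completed.loc[pred_rows, target] = fit.draw(rng, X_pred)
        datasets.append(CompleteData(completed, obs.base.scenario_id))
    return ImputedStack(datasets, spec, obs)


# ---------------------------------------------------------------------------
# variant catalog
# ---------------------------------------------------------------------------


def _t(variable: str, transform: str = "identity", df: int | None = None) -> Term:
    return Term(variable, transform, df)


def _single_confounder_catalog(scenario: str, pattern: str) -> dict[str, ImputationSpec]:
    # the precision variable enters the analysis models quadratically in the
    # nonlinear scenario; "correct" imputation matches that functional form
    zp_true = _t("zp", "square") if scenario == "nonlinear_prec" else _t("zp")
    if pattern == "confounder":
        resp = "zc"
        specs = {
            "correct": ((_t("y"), zp_true), True),
            "oversaturated": ((_t("y", "nspline", 3), _t("zp", "nspline", 3)), True),
            "omits_precision": ((_t("y"),), True),
            "omits_exposure": ((_t("y"), zp_true), False),
            "omits_outcome": ((zp_true,), True),
            "missing_interaction": ((_t("x"), _t("y"), zp_true), False),
            "misspecified_precision": ((_t("y"), _t("zp")), True),
            "misspecified_precision_missing_interaction": (
                (_t("x"), _t("y"), _t("zp")),
                False,
            ),
            # zp linear in imputation AND analysis outcome models (the
            # analysis override is applied by the harness)
            "linear_both": ((_t("y"), _t("zp")), True),
        }
    else:
        resp = "y"
        specs = {
            "correct": ((_t("zc"), zp_true), True),
            "oversaturated": ((_t("zc", "nspline", 3), _t("zp", "nspline", 3)), True),
            "omits_precision": ((_t("zc"),), True),
            "omits_confounder": ((zp_true,), True),
            "omits_exposure": ((_t("zc"), zp_true), False),
            "missing_interaction": ((_t("x"), _t("zc"), zp_true), False),
            "misspecified_precision": ((_t("zc"), _t("zp")), True),
            "misspecified_precision_missing_interaction": (
                (_t("x"), _t("zc"), _t("zp")),
                False,
            ),
        }
    return {
        vid: ImputationSpec(resp, terms, stratified, variant_id=vid)
        for vid, (terms, stratified) in specs.items()
    }


def _two_confounder_catalog(scenario: str, pattern: str) -> dict[str, ImputationSpec]:
    # zc2 is quadratic in the outcome equation of s2/s3, linear in s1
    zc2_true = _t("zc2", "square") if scenario in ("s2_nl_y", "s3_nl_both") else _t("zc2")
    if pattern == "confounder":
        resp, other = "zc1", _t("y")
    else:
        resp, other = "y", _t("zc1")
    specs = {
        "correct": ((other, zc2_true), True),
        "oversaturated": (
            (
                _t(other.variable, "nspline", 3),
                _t("zc2", "nspline", 3),
            ),
            True,
        ),
        "misspecified_zc2": ((other, _t("zc2")), True),
    }
    return {
        vid: ImputationSpec(resp, terms, stratified, variant_id=vid)
        for vid, (terms, stratified) in specs.items()
    }


def imputation_spec_catalog(scenario: str, pattern: str, variant: str) -> ImputationSpec:
    """Look up a named imputation variant for (scenario, pattern)."""
    if pattern not in ("confounder", "outcome"):
        raise InvalidArgumentError(f"unknown pattern {pattern!r}")
    if variant == COMPLETE_CASE:
        return ImputationSpec.complete_case()
    from .dgp import SINGLE_CONFOUNDER_SCENARIOS, TWO_CONFOUNDER_SCENARIOS

    if scenario in SINGLE_CONFOUNDER_SCENARIOS:
        catalog = _single_confounder_catalog(scenario, pattern)
    elif scenario in TWO_CONFOUNDER_SCENARIOS:
        catalog = _two_confounder_catalog(scenario, pattern)
    else:
        raise InvalidArgumentError(f"unknown scenario {scenario!r}")
    try:
        return catalog[variant]
    except KeyError:
        raise InvalidArgumentError(
            f"unknown variant {variant!r} for ({scenario}, {pattern}); "
            f"known: {sorted(catalog)}"
        ) from None


def catalog_variants(scenario: str, pattern: str) -> list[str]:
    """Names of the variants available for (scenario, pattern)."""
    from .dgp import SINGLE_CONFOUNDER_SCENARIOS

    if scenario in SINGLE_CONFOUNDER_SCENARIOS:
        cat = _single_confounder_catalog(scenario, pattern)
    else:
        cat = _two_confounder_catalog(scenario, pattern)
    return sorted(cat) + [COMPLETE_CASE]


def with_m(spec: ImputationSpec, m: int) -> ImputationSpec:
    """Copy of ``spec`` with a different number of imputations."""
    if spec.is_complete_case:
        return spec
    return replace(spec, m=m)
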