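"""Model fits and ATE estimators, cross-checked against statsmodels."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from congenialmi import dgp
from congenialmi.design import Term, build_design_matrix
from congenialmi.errors import EstimationError, SeparationError
from congenialmi.estimate import (
    aipw_ate,
    aipw_from_components,
    complete_case_ate,
    fit_logistic,
    fit_ols,
    ipw_ate,
    weighted_outcome_ate,
)

PS = [Term("zc")]
OUT = [Term("zc"), Term("zp")]


def test_logistic_intercept_only_is_sample_mean():
    y = np.array([1, 1, 0, 0, 0], dtype=float)
    dm = build_design_matrix(pd.DataFrame(index=range(5)), [], intercept=True)
    fit = fit_logistic(dm, y)
    assert np.allclose(fit.fitted_values, 0.4, atol=1e-8)


def test_logistic_matches_statsmodels(cohort_linear_het):
    df = cohort_linear_het.df
    dm = build_design_matrix(df, PS)
    mine = fit_logistic(dm, df["x"].to_numpy())
    ref = sm.Logit(df["x"].to_numpy(), dm.values).fit(disp=0)
    assert np.allclose(mine.coefficients, ref.params, atol=1e-6)
    assert mine.converged


def test_logistic_coefficient_recovery():
    """n=10⁵ draws from logit(p) = 1 − zc recover (1, −1) within 3 SE."""
    rng = np.random.default_rng(17)
    zc = rng.normal(1, 1, 100_000)
    p = 1.0 / (1.0 + np.exp(-(1.0 - zc)))
    x = (rng.uniform(size=zc.size) < p).astype(float)
    df = pd.DataFrame({"zc": zc})
    fit = fit_logistic(build_design_matrix(df, PS), x)
    ref = sm.Logit(x, sm.add_constant(zc)).fit(disp=0)
    assert np.all(np.abs(fit.coefficients - [1.0, -1.0]) < 3 * ref.bse)


def test_logistic_single_class_raises():
    dm = build_design_matrix(pd.DataFrame(index=range(4)), [])
    with pytest.raises(SeparationError):
        fit_logistic(dm, np.ones(4))


def test_ols_exact_and_intercept_only():
    rng = np.random.default_rng(3)
    df = pd.DataFrame({"zc": rng.normal(size=30)})
    y = 2.0 + 3.0 * df["zc"].to_numpy()
    fit = fit_ols(build_design_matrix(df, PS), y)
    assert np.allclose(fit.fitted_values, y, atol=1e-10)
    assert fit.residual_variance == pytest.approx(0.0, abs=1e-18)
    only = fit_ols(build_design_matrix(df, []), y)
    assert only.coefficients[0] == pytest.approx(y.mean())


def test_ols_matches_statsmodels(cohort_linear_het):
    df = cohort_linear_het.df
    dm = build_design_matrix(df, OUT)
    mine = fit_ols(dm, df["y"].to_numpy())
    ref = sm.OLS(df["y"].to_numpy(), dm.values).fit()
    assert np.allclose(mine.coefficients, ref.params, atol=1e-9)
    assert mine.residual_variance == pytest.approx(ref.mse_resid)


def test_aipw_two_unit_hand_example():
    """With π ≡ 0.5 and μ ≡ 0: Δ̂ = ½(2/0.5 − 1/0.5) = 1."""
    x = np.array([1.0, 0.0])
    y = np.array([2.0, 1.0])
    pi = np.array([0.5, 0.5])
    zero = np.zeros(2)
    est = aipw_from_components(x, y, pi, zero, zero)
    assert est.delta_hat == pytest.approx(1.0)


def test_aipw_with_zero_mu_equals_ipw(cohort_linear_het):
    """Exact algebraic identity, bit-for-bit."""
    from congenialmi.estimate import _fit_propensity

    df = cohort_linear_het.df
    pi = _fit_propensity(df, PS)
    zero = np.zeros(len(df))
    a = aipw_from_components(df["x"].to_numpy(), df["y"].to_numpy(), pi, zero, zero)
    b = ipw_ate(cohort_linear_het, PS)
    assert a.delta_hat == b.delta_hat
    assert a.variance == b.variance


def test_saturated_outcome_model_nullifies_augmentation():
    """When residuals vanish within arms, Δ̂ equals mean(μ1 − μ0) exactly."""
    rng = np.random.default_rng(5)
    zc = rng.normal(1, 1, 400)
    x = (rng.uniform(size=400) < 0.5).astype(float)
    y = np.where(x == 1, 2.0 + zc, 1.0 - zc)  # exactly linear per arm
    df = pd.DataFrame({"zc": zc, "zp": rng.normal(size=400), "x": x, "y": y})
    est = aipw_ate(df, PS, [Term("zc")])
    mu_diff = (2.0 + zc) - (1.0 - zc)
    assert est.delta_hat == pytest.approx(mu_diff.mean(), abs=1e-9)


@pytest.mark.parametrize(
    "ps_terms,outcome_terms",
    [
        (PS, [Term("zc")]),  # correct π, outcome model omits zp
        ([], OUT)  # intercept-only π, correct outcome model
    ],
)
def test_double_robustness_one_sided_misspecification(ps_terms, outcome_terms):
    data = dgp.make_data(100_000, "linear_het", seed=31)
    est = aipw_ate(data, ps_terms, outcome_terms)
    assert abs(est.delta_hat - 1.0) < 3 * np.sqrt(est.variance)


def test_estimator_consistency_complete_data():
    data = dgp.make_data(100_000, "linear_het", seed=41)
    for est in (aipw_ate(data, PS, OUT), ipw_ate(data, PS)):
        assert abs(est.delta_hat - 1.0) < 3 * np.sqrt(est.variance)
        assert est.variance > 0


def test_complete_case_without_missingness_matches_aipw(cohort_linear_het):
    obs = dgp.ObservedData(
        cohort_linear_het, "outcome", np.zeros(cohort_linear_het.n, bool)
    )
    cc = complete_case_ate(obs, PS, OUT)
    full = aipw_ate(cohort_linear_het, PS, OUT)
    assert cc.delta_hat == full.delta_hat
    assert cc.n_used == full.n_used


def test_weighted_outcome_agrees_with_aipw():
    """Both estimators are consistent on complete data; paired replications
    agree within joint standard error."""
    diffs, scale = [], []
    for seed in range(20):
        data = dgp.make_data(2000, "linear_het", seed=100 + seed)
        a = aipw_ate(data, PS, OUT)
        w = weighted_outcome_ate(data, PS, OUT)
        diffs.append(a.delta_hat - w.delta_hat)
        scale.append(max(np.sqrt(a.variance), np.sqrt(w.variance)))
    assert np.all(np.abs(diffs) < 2 * np.array(scale))


def test_empty_arm_raises():
    df = pd.DataFrame(
        {"zc": np.arange(10.0), "zp": np.zeros(10), "x": np.ones(10), "y": np.arange(10.0)}
    )
    with pytest.raises((EstimationError, SeparationError)):
        aipw_ate(df, PS, OUT)
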