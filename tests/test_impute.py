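"""Posterior-predictive imputation draws and the variant catalog."""

import numpy as np
import pytest

from congenialmi import dgp
from congenialmi.design import Term
from congenialmi.errors import InvalidArgumentError, SmallStratumError
from congenialmi.impute import (
    ImputationSpec,
    bayes_norm_draw,
    imputation_spec_catalog,
    multiply_impute,
    with_m,
)


def test_noiseless_limit_is_deterministic_prediction():
    rng = np.random.default_rng(0)
    X = np.column_stack([np.ones(50), np.linspace(0, 1, 50)])
    beta = np.array([1.0, -2.0])
    y = X @ beta  # exactly linear, RSS = 0
    Xp = np.column_stack([np.ones(5), np.linspace(2, 3, 5)])
    draw = bayes_norm_draw(X, y, Xp, rng)
    assert np.allclose(draw, Xp @ beta, atol=1e-6)


def test_empty_prediction_rows():
    rng = np.random.default_rng(0)
    X = np.column_stack([np.ones(10), np.arange(10.0)])
    y = np.arange(10.0)
    assert bayes_norm_draw(X, y, np.empty((0, 2)), rng).size == 0


def test_posterior_draws_center_on_truth():
    """Mean of 200 coefficient draws from a large known linear model matches
    the generating coefficients within Monte Carlo error."""
    rng = np.random.default_rng(7)
    n = 10_000
    X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
    beta = np.array([0.5, 1.5, -1.0])
    y = X @ beta + rng.normal(size=n)
    # predicting at unit vectors returns β*ⱼ plus predictive noise (mean 0)
    Xp = np.eye(3)
    draws = np.array([bayes_norm_draw(X, y, Xp, rng) for _ in range(200)])
    se = draws.std(axis=0, ddof=1) / np.sqrt(200)
    assert np.all(np.abs(draws.mean(axis=0) - beta) < 3 * se)


def test_observed_entries_pass_through(observed_confounder):
    spec = with_m(
        imputation_spec_catalog("linear_het", "confounder", "correct"), 5
    )
    stack = multiply_impute(observed_confounder, spec, seed=3)
    base = observed_confounder.base.df
    keep = ~observed_confounder.mask
    imputed_matrix = np.array(
        [d.df["zc"].to_numpy() for d in stack]
    )
    for row in imputed_matrix:
        assert np.array_equal(row[keep], base.loc[keep, "zc"].to_numpy())
    # imputed entries vary across imputations
    assert imputed_matrix[:, ~keep].std(axis=0).min() > 0
    for d in stack:
        d.validate_complete()


def test_no_missingness_returns_identical_datasets(cohort_linear_het):
    obs = dgp.ObservedData(
        cohort_linear_het, "confounder", np.zeros(cohort_linear_het.n, bool)
    )
    spec = with_m(imputation_spec_catalog("linear_het", "confounder", "correct"), 3)
    stack = multiply_impute(obs, spec, seed=1)
    for d in stack:
        assert d.df.equals(cohort_linear_het.df)


def test_imputed_values_track_held_out_truth():
    """With the congenial model, the pooled mean of imputed confounder values
    matches the mean of the (known) masked true values."""
    data = dgp.make_data(100_000, "linear_het", seed=21)
    obs = dgp.induce_missingness(data, "confounder", seed=22)
    spec = with_m(imputation_spec_catalog("linear_het", "confounder", "correct"), 5)
    stack = multiply_impute(obs, spec, seed=23)
    truth = data.df.loc[obs.mask, "zc"].to_numpy()
    imputed = np.array([d.df.loc[obs.mask, "zc"].to_numpy() for d in stack])
    diff = imputed.mean() - truth.mean()
    # per-imputation mean difference has sd ≈ sd(imp − truth)/√n_miss
    se = (imputed - truth).std() / np.sqrt(obs.n_missing)
    assert abs(diff) < 3 * se


def test_small_stratum_raises(cohort_linear_het):
    obs = dgp.induce_missingness(cohort_linear_het, "confounder", seed=5)
    tiny = dgp.ObservedData(
        dgp.CompleteData(cohort_linear_het.df.iloc[:6].copy(), "linear_het"),
        "confounder",
        obs.mask[:6],
    )
    rich = ImputationSpec(
        "zc", (Term("y", "nspline", 3), Term("zp", "nspline", 3)), True, 5, "v"
    )
    with pytest.raises(SmallStratumError):
        multiply_impute(tiny, rich, seed=1)


def test_catalog_variant_structure():
    omits_x = imputation_spec_catalog("linear_het", "confounder", "omits_exposure")
    assert not omits_x.stratify_by_exposure
    assert all(t.variable != "x" for t in omits_x.predictor_terms)

    over = imputation_spec_catalog("nonlinear_prec", "confounder", "oversaturated")
    assert over.stratify_by_exposure
    assert {t.transform for t in over.predictor_terms} == {"nspline"}

    correct_nl = imputation_spec_catalog("nonlinear_prec", "confounder", "correct")
    assert ("zp", "square") in [
        (t.variable, t.transform) for t in correct_nl.predictor_terms
    ]

    interaction = imputation_spec_catalog("linear_het", "outcome", "missing_interaction")
    assert not interaction.stratify_by_exposure
    assert "x" in [t.variable for t in interaction.predictor_terms]

    cc = imputation_spec_catalog("linear_het", "outcome", "complete_case")
    assert cc.is_complete_case

    s2 = imputation_spec_catalog("s2_nl_y", "confounder", "misspecified_zc2")
    assert ("zc2", "identity") in [
        (t.variable, t.transform) for t in s2.predictor_terms
    ]
    s2c = imputation_spec_catalog("s2_nl_y", "confounder", "correct")
    assert ("zc2", "square") in [
        (t.variable, t.transform) for t in s2c.predictor_terms
    ]

    with pytest.raises(InvalidArgumentError):
        imputation_spec_catalog("linear_het", "confounder", "nope")


def test_spec_invariants():
    with pytest.raises(InvalidArgumentError):
        ImputationSpec("zc", (Term("x"),), stratify_by_exposure=True, m=5)
    with pytest.raises(InvalidArgumentError):
        ImputationSpec("zc", (Term("y"),), m=1)
    spec = ImputationSpec("zc", (Term("y"),), True, 5, "v")
    assert ImputationSpec.from_dict(spec.to_dict()) == spec


def test_response_pattern_mismatch(observed_outcome):
    spec = imputation_spec_catalog("linear_het", "confounder", "correct")
    with pytest.raises(InvalidArgumentError):
        multiply_impute(observed_outcome, spec, seed=1)
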