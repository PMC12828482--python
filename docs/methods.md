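# Methods

## Model and estimands

The framework works in the standard potential-outcomes setting: binary
exposure X, continuous outcome Y, continuous pre-exposure covariates
partitioned by causal role into instruments ZI (affect X only), precision
variables ZP (affect Y only) and confounders ZC (affect both). Under
consistency, exchangeability given ZC, and positivity, the average
treatment effect Δ = E[Y(1) − Y(0)] is identified and estimated by
augmented inverse probability weighting (AIPW):

Δ̂ = n⁻¹ Σ [μ̂₁ − μ̂₀] + n⁻¹ Σ [X(Y − μ̂₁)/π̂ − (1−X)(Y − μ̂₀)/(1−π̂)],

with π̂ a logistic propensity score fit on the full sample and μ̂₁, μ̂₀
least-squares outcome models fit separately in each exposure arm
(equivalent to interacting every outcome-model term with X). A plain IPW
estimator (μ ≡ 0) and an IPW-weighted outcome-regression estimator (WLS
with an exposure–confounder interaction, contrast averaged over the sample,
HC0 sandwich variance) are provided as alternatives.

The within-dataset variance U of Δ̂ is the empirical variance of the
unit-level influence contribution

φᵢ = μ̂₁ᵢ − μ̂₀ᵢ + Xᵢ(Yᵢ−μ̂₁ᵢ)/π̂ᵢ − (1−Xᵢ)(Yᵢ−μ̂₀ᵢ)/(1−π̂ᵢ)

divided by n, treating π̂ and μ̂ as known. This is the usual sandwich-free
plug-in; it ignores the first-stage estimation effect, which is second-order
for AIPW when at least one nuisance model is correct. Consequence: point
estimates, bias and RMSE are exact reproductions in distribution, while
"average SE" and CI coverage are close but not estimator-theoretic
guarantees; coverage of badly biased variants (which is what the framework
is designed to expose) is insensitive to this choice.

## Missing data and multiple imputation

Exactly one variable is incomplete per experiment: the confounder (ZC or
ZC1) or the outcome Y, missing at random with logistic mechanisms

P(M_Y = 1)  = (1 + exp{0.65 + ZC})⁻¹,
P(M_ZC = 1) = (1 + exp{1.15 + 0.5·X})⁻¹,

each yielding ≈20% marginal missingness under the default cohorts.
Because the missingness is univariate and all predictors of the imputation
model are fully observed, one regression-and-draw per imputation is exactly
equivalent to a chained-equations pass; no iteration is performed.

Imputations are posterior-predictive draws from the Bayesian normal linear
model ("norm"-type): with least-squares fit (β̂, RSS, ν = n_fit − p) on
observed-response rows,

g ~ χ²(ν),  σ*² = RSS/g,  β* ~ N(β̂, σ*²(XᵀX)⁻¹),
imputed = X_pred β* + N(0, σ*² I).

Parameter uncertainty therefore propagates into the between-imputation
variance B. When the strategy is stratified by exposure, the fit/draw is
done independently within X=0 and X=1 (strata processed in that fixed
order on a single draw stream, so random-number consumption is
deterministic). Predictive-mean-matching and tree-based engines are out of
scope: the normal draw is the parametric reference case that makes
congeniality arguments exact.

Per-imputation estimates are pooled by Rubin's rules: Δ̄ = mean Δ̂⁽ʲ⁾,
T = Ū + (1 + 1/m)·B, CI = Δ̄ ± t_{ν,0.975}·√T with the classic degrees of
freedom ν = (m−1)(1 + Ū/((1+1/m)B))², and normal quantiles when B = 0.
The Barnard–Rubin small-sample adjustment is omitted; at m = 20 and
n ≥ 500 its effect is negligible relative to Monte Carlo error.
Complete-case analysis drops incomplete rows and reports a single AIPW
estimate with a normal CI.

## Synthetic cohorts

Six data-generating scenarios, all with true Δ = 1:

| scenario | exposure model P(X=1) | outcome model |
|---|---|---|
| `linear_het` | (1+exp{ZC − 2ZI})⁻¹ | 0.5X + ZC + 2ZP + 0.5X·ZC + ε |
| `linear_homog` | (1+exp{ZC − 2ZI})⁻¹ | X + ZC + 2ZP + ε |
| `nonlinear_prec` | (1+exp{ZC − 2ZI})⁻¹ | 0.5X + ZC + 2ZP² + 0.5X·ZC + ε |
| `s1_nl_x` | (1+exp{ZC1 + ZC2²})⁻¹ | 0.5X + ZC1 + ZC2 + 0.5X·ZC1 + ε |
| `s2_nl_y` | (1+exp{ZC1 + ZC2})⁻¹ | 0.5X + ZC1 + ZC2² + 0.5X·ZC1 + ε |
| `s3_nl_both` | (1+exp{ZC1 + ZC2²})⁻¹ | 0.5X + ZC1 + ZC2² + 0.5X·ZC1 + ε |

with ZI, ZP ~ N(0,1), ZC, ZC1, ZC2 ~ N(1,1), ε ~ N(0,1). In the
heterogeneous scenarios Δ = 0.5 + 0.5·E[ZC] = 1 in closed form. Draw order
within a generator stream is fixed (covariates in column order, exposure
uniforms, outcome noise) so cohorts are bit-reproducible given a seed.

What the generator emulates: the exact covariate, exposure, outcome and
missingness laws of the study conditions, including effect heterogeneity
and the nonlinearities that drive congeniality failures. What it does not
emulate: measurement error, non-Gaussian covariates, MNAR mechanisms,
multivariate missingness, or finite-population structure — so passing
results demonstrate the congeniality mechanics, not robustness of MI on
arbitrary real data.

The two-confounder scenarios with ZC2² in the exposure model are
deliberately heavy-tailed: E[exp{ZC2²}] diverges, so inverse-probability
weights have infinite moments, estimates converge slowly, and nominal
coverage is not attained even by correctly specified models. Summaries for
those scenarios carry large Monte Carlo error by construction.

## Analysis models per scenario

The propensity model conditions on the confounder(s) in the generating
functional form (e.g. `zc1 + zc2²` in `s1_nl_x`/`s3_nl_both`); per-arm
outcome models add the precision variable (`zp²` in `nonlinear_prec`).
The `linear_both` variant additionally replaces the outcome models' ZP²
with linear ZP so that a linear-ZP imputation model is congenial with the
(misspecified) outcome model and the correct propensity model restores
consistency through double robustness.

## Imputation variant catalog

For each (scenario, missingness pattern) the catalog names the strategies
under study. For a missing confounder: `correct` (stratified by exposure;
outcome + precision variable in the analysis functional form),
`oversaturated` (stratified; all predictors as natural cubic splines,
df = 3), `omits_precision`, `omits_outcome`, `omits_exposure` (pooled, X
excluded), `missing_interaction` (pooled, X additive),
`misspecified_precision` (ZP linear where the analysis uses ZP²), and
`complete_case` (sentinel: no imputation). Missing-outcome and
two-confounder analogues follow the same naming. The instrument ZI appears
in no analysis model and is excluded from the catalog's models; including
it additively changes nothing material (it is conditionally informative
within exposure strata but both choices are unbiased).

## Numerical choices

- **Natural cubic splines**: truncated-power natural basis of dimension
  df; boundary knots at the min/max of the fitting values, interior knots
  at evenly spaced quantiles (i/df). Knots fitted on the fitting rows
  (within an arm or stratum) are frozen and reused verbatim for prediction
  rows, preventing basis mismatch between fit and prediction. Only span
  properties matter; tests assert them rather than coordinates, and patsy's
  `cr` basis on the same knots serves as an independent span oracle.
- **Logistic IRLS**: convergence when the max absolute coefficient change
  < 1e−8, at most 25 iterations; non-convergence is flagged and logged,
  not fatal. Fitted probabilities are clipped to [1e−9, 1 − 1e−9] before
  weight formation; no weight truncation is applied, so heavy-tailed
  scenarios keep their heavy tails.
- **Ridge stabilization**: when XᵀX cannot be Cholesky-factorized
  (near-collinear spline bases at n = 100), λ = 1e−5 × mean(diag XᵀX) is
  added once; still-singular systems raise a degenerate-fit error.
- **Small strata**: a stratum with fewer observed rows than parameters
  raises an error; the harness logs it, drops the replication and counts it
  in `n_failed` (non-zero essentially only at n = 100 with spline models).
- **Seed protocol**: data and missingness streams derive from
  (base_seed, scenario, pattern, n, rep_index) via `SeedSequence`, so all
  imputation variants of a cell see identical cohorts (paired comparisons
  reduce between-variant Monte Carlo noise); the imputation stream is
  additionally keyed by the variant id so streams never collide.

## Problem sizes

Scenario summaries default to 500 replications with m = 20 imputations at
n ∈ {100, 500, 1000, 2000}; a single n = 2000 cell (≈30 000 small
regressions) runs in ~15–25 s on one CPU, and the full headline-results
script in a few minutes. Large-sample checks (double robustness,
missingness calibration) use single cohorts of n = 10⁵ and Monte Carlo
oracles of 10⁶ draws.

## Known limitations

- The within-imputation variance is the plug-in influence-function
  estimator; "Avg. SE" and coverage are therefore approximate for variants
  whose nuisance models are both misspecified.
- In the heavy-tailed scenarios (quadratic confounder terms inside the
  exposure model, or imputation errors that leak a quadratic into the
  estimated propensity index), summaries are dominated by extreme-weight
  units; bias and dispersion measured for *misspecified* imputation
  variants there are sensitive to implementation details of the whole
  stack (draw engine, basis parameterization, weight handling), and
  different software pipelines can legitimately report materially
  different magnitudes for the same nominal design.
- Only univariate missingness (one confounder or the outcome), Gaussian
  covariates, and binary exposure are supported; no MNAR, no TMLE, no
  survival outcomes.
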