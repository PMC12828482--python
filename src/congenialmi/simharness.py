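"""Monte Carlo harness: replications over scenario × pattern × variant × n.

One replication generates a cohort, induces missingness, runs either the
complete-case path (drop masked rows, single estimate) or the
multiple-imputation path (m imputations → m estimates → Rubin pooling), and
is fully determined by (config, rep_index).  A scenario summary aggregates
`reps` replications into the usual simulation-study metrics: mean estimate,
Monte Carlo SE, average model SE, bias, RMSE and 95% CI coverage against the
true ATE of 1.

Seed protocol: the per-replication data and missingness streams derive from
(base_seed, scenario, pattern, n, rep_index) only, so all imputation
variants of one scenario see identical datasets (paired comparisons); the
imputation stream is additionally keyed by the variant so draw streams never
collide.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from joblib import Parallel, delayed

from . import dgp
from .design import Term
from .errors import (
    CongenialMIError,
    EmptySummaryError,
    InvalidArgumentError,
)
from .estimate import ATEEstimate, estimate_ate
from .impute import COMPLETE_CASE, imputation_spec_catalog, multiply_impute, with_m
from .pool import PooledResult, covers, rubin_pool, single_estimate_result

logger = logging.getLogger(__name__)

SAMPLE_SIZES = (100, 500, 1000, 2000)

#: analysis models per scenario: propensity-score terms and per-arm outcome
#: terms.  The propensity model conditions on confounders only; outcome
#: models add the precision variable (quadratically where the truth is
#: quadratic).
ANALYSIS_MODELS: dict[str, tuple[tuple[Term, ...], tuple[Term, ...]]] = {
    "linear_het": ((Term("zc"),), (Term("zc"), Term("zp"))),
    "linear_homog": ((Term("zc"),), (Term("zc"), Term("zp"))),
    "nonlinear_prec": ((Term("zc"),), (Term("zc"), Term("zp", "square"))),
    "s1_nl_x": ((Term("zc1"), Term("zc2", "square")), (Term("zc1"), Term("zc2"))),
    "s2_nl_y": ((Term("zc1"), Term("zc2")), (Term("zc1"), Term("zc2", "square"))),
    "s3_nl_both": (
        (Term("zc1"), Term("zc2", "square")),
        (Term("zc1"), Term("zc2", "square")),
    ),
}

#: variants that also change the ANALYSIS outcome model (not only the
#: imputation model): "linear_both" uses the precision variable linearly in
#: both, so imputation and (misspecified) outcome model are congenial and
#: the correctly specified propensity model restores consistency.
_ANALYSIS_OVERRIDES: dict[str, tuple[Term, ...]] = {
    "linear_both": (Term("zc"), Term("zp")),
}


def analysis_models(scenario: str, variant: str = "") -> tuple[list[Term], list[Term]]:
    """(ps_terms, outcome_terms) for a scenario, honouring variant overrides."""
    try:
        ps_terms, outcome_terms = ANALYSIS_MODELS[scenario]
    except KeyError:
        raise InvalidArgumentError(f"unknown scenario {scenario!r}") from None
    if variant in _ANALYSIS_OVERRIDES:
        outcome_terms = _ANALYSIS_OVERRIDES[variant]
    return list(ps_terms), list(outcome_terms)


@dataclass(frozen=True)
class ScenarioConfig:
    scenario_id: str
    pattern: str
    variant: str
    n: int
    reps: int = 500
    m: int = 20
    base_seed: int = 1
    estimator_id: str = "aipw"

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InvalidArgumentError("n must be >= 2")
        if self.reps < 1:
            raise InvalidArgumentError("reps must be >= 1")


@dataclass
class ScenarioSummary:
    config: ScenarioConfig
    est_mean: float
    mc_se: float
    avg_se: float
    bias: float
    rmse: float
    coverage: float
    n_failed: int = 0


# ---------------------------------------------------------------------------
# seeds
# ---------------------------------------------------------------------------


def _tag(*parts) -> int:
    return zlib.crc32("|".join(str(p) for p in parts).encode()) & 0x7FFFFFFF


def _replication_streams(config: ScenarioConfig, rep_index: int):
    cell = _tag(config.scenario_id, config.pattern, config.n)
    data_ss = np.random.SeedSequence(
        [config.base_seed & 0x7FFFFFFF, cell, rep_index, 0]
    )
    rng_data, rng_miss = [np.random.default_rng(s) for s in data_ss.spawn(2)]
    imp_ss = np.random.SeedSequence(
        [config.base_seed & 0x7FFFFFFF, cell, rep_index, 1, _tag(config.variant)]
    )
    return rng_data, rng_miss, np.random.default_rng(imp_ss)


# ---------------------------------------------------------------------------
# replications
# ---------------------------------------------------------------------------


def run_replication(config: ScenarioConfig, rep_index: int):
    """One deterministic replication.

    Returns an :class:`ATEEstimate` on the complete-case path, otherwise a
    Rubin-pooled :class:`PooledResult` over ``config.m`` imputations.
    """
    rng_data, rng_miss, rng_imp = _replication_streams(config, rep_index)
    data = dgp.make_data(config.n, config.scenario_id, rng_data)
    obs = dgp.induce_missingness(data, config.pattern, rng_miss)
    ps_terms, outcome_terms = analysis_models(config.scenario_id, config.variant)
    if config.variant == COMPLETE_CASE:
        kept = obs.base.df.loc[~obs.mask]
        return estimate_ate(kept, config.estimator_id, ps_terms, outcome_terms)
    spec = with_m(
        imputation_spec_catalog(config.scenario_id, config.pattern, config.variant),
        config.m,
    )
    stack = multiply_impute(obs, spec, rng_imp)
    estimates = [
        estimate_ate(d, config.estimator_id, ps_terms, outcome_terms) for d in stack
    ]
    return rubin_pool(estimates)


def _as_pooled(result) -> PooledResult:
    if isinstance(result, ATEEstimate):
        return single_estimate_result(result)
    return result


def summarize(results: list[PooledResult], config: ScenarioConfig) -> ScenarioSummary:
    """Aggregate replication results into the summary-table metrics."""
    if not results:
        raise EmptySummaryError("all replications failed")
    truth = dgp.true_ate(config.scenario_id)
    deltas = np.array([r.delta_bar for r in results])
    ses = np.array([r.se for r in results])
    cover = np.array([covers(r, truth) for r in results])
    if len(results) > 1:
        mc_se = float(deltas.std(ddof=1))
    else:
        warnings.warn("mc_se undefined with a single replication; reporting 0")
        mc_se = 0.0
    return ScenarioSummary(
        config=config,
        est_mean=float(deltas.mean()),
        mc_se=mc_se,
        avg_se=float(ses.mean()),
        bias=float(deltas.mean() - truth),
        rmse=float(np.sqrt(np.mean((deltas - truth) ** 2))),
        coverage=float(cover.mean()),
        n_failed=config.reps - len(results),
    )


def _safe_replication(config: ScenarioConfig, rep_index: int):
    try:
        return _as_pooled(run_replication(config, rep_index))
    except CongenialMIError as exc:
        logger.warning("replication %d failed: %s", rep_index, exc)
        return None


def run_scenario(
    config: ScenarioConfig, n_jobs: int = 1, return_replications: bool = False
):
    """Run ``config.reps`` independent replications and summarize.

    Replications are independent and order-invariant; ``n_jobs`` > 1 farms
    them out with joblib.  Failed replications (degenerate fits or
    too-small strata, mostly at n=100) are logged and counted in
    ``n_failed``.
    """
    if n_jobs == 1:
        results = [_safe_replication(config, i) for i in range(config.reps)]
    else:
        results = Parallel(n_jobs=n_jobs)(
            delayed(_safe_replication)(config, i) for i in range(config.reps)
        )
    kept = [r for r in results if r is not None]
    summary = summarize(kept, config)
    if return_replications:
        return summary, kept
    return summary


# ---------------------------------------------------------------------------
# tables and configuration
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ["est", "mc_se", "avg_se", "bias", "rmse", "coverage"]


def table_frame(summaries: list[ScenarioSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        c = s.config
        rows.append(
            {
                "scenario": c.scenario_id,
                "pattern": c.pattern,
                "variant": c.variant,
                "n": c.n,
                "reps": c.reps,
                "m": c.m,
                "estimator": c.estimator_id,
                "est": s.est_mean,
                "mc_se": s.mc_se,
                "avg_se": s.avg_se,
                "bias": s.bias,
                "rmse": s.rmse,
                "coverage": s.coverage,
                "n_failed": s.n_failed,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "scenario",
            "pattern",
            "variant",
            "n",
            "reps",
            "m",
            "estimator",
            *_TABLE_COLUMNS,
            "n_failed",
        ],
    )


def write_table(summaries: list[ScenarioSummary], path) -> None:
    """Write one row per summary to CSV (full precision)."""
    table_frame(summaries).to_csv(path, index=False)


def render_table(summaries: list[ScenarioSummary]) -> pd.DataFrame:
    """Human-readable view with metrics rounded to 2 decimals."""
    df = table_frame(summaries)
    df[_TABLE_COLUMNS] = df[_TABLE_COLUMNS].round(2)
    return df


def config_from_dict(d: dict) -> ScenarioConfig:
    return ScenarioConfig(
        scenario_id=d["scenario"],
        pattern=d["pattern"],
        variant=d["variant"],
        n=int(d["n"]),
        reps=int(d.get("reps", 500)),
        m=int(d.get("m", 20)),
        base_seed=int(d.get("seed", 1)),
        estimator_id=d.get("estimator", "aipw"),
    )


def configs_from_yaml(path) -> list[ScenarioConfig]:
    """Read one config (mapping) or several (sequence of mappings) from YAML."""
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    if isinstance(payload, dict):
        payload = [payload]
    return [config_from_dict(d) for d in payload]


#: named full-grid convenience runs mirroring the summary tables:
#: (scenario, patterns, variants-per-pattern)
TABLE_GRIDS: dict[str, tuple[str, dict[str, list[str]]]] = {
    "table1": (
        "linear_het",
        {
            "confounder": [
                "correct",
                "oversaturated",
                "complete_case",
                "omits_precision",
                "omits_exposure",
                "omits_outcome",
                "missing_interaction",
            ],
            "outcome": [
                "correct",
                "oversaturated",
                "complete_case",
                "omits_precision",
                "omits_exposure",
                "omits_confounder",
                "missing_interaction",
            ],
        },
    ),
    "table2": (
        "linear_homog",
        {
            p: ["correct", "oversaturated", "complete_case", "missing_interaction"]
            for p in ("confounder", "outcome")
        },
    ),
    "table3": (
        "nonlinear_prec",
        {
            "confounder": [
                "correct",
                "misspecified_precision",
                "misspecified_precision_missing_interaction",
                "linear_both",
            ],
            "outcome": [
                "correct",
                "misspecified_precision",
                "misspecified_precision_missing_interaction",
            ],
        },
    ),
    "table4": (
        "s1_nl_x",
        {p: ["correct", "oversaturated", "misspecified_zc2"] for p in ("confounder", "outcome")},
    ),
    "table5": (
        "s2_nl_y",
        {p: ["correct", "oversaturated", "misspecified_zc2"] for p in ("confounder", "outcome")},
    ),
    "table6": (
        "s3_nl_both",
        {p: ["correct", "oversaturated", "misspecified_zc2"] for p in ("confounder", "outcome")},
    ),
}


def table_grid_configs(
    table: str,
    sample_sizes: tuple[int, ...] = SAMPLE_SIZES,
    reps: int = 500,
    m: int = 20,
    base_seed: int = 1,
    estimator_id: str = "aipw",
) -> list[ScenarioConfig]:
    """All ScenarioConfigs making up one named summary-table grid."""
    try:
        scenario, patterns = TABLE_GRIDS[table]
    except KeyError:
        raise InvalidArgumentError(
            f"unknown table {table!r}; known: {sorted(TABLE_GRIDS)}"
        ) from None
    return [
        ScenarioConfig(scenario, pattern, variant, n, reps, m, base_seed, estimator_id)
        for pattern, variants in patterns.items()
        for n in sample_sizes
        for variant in variants
    ]


def plot_coverage(summaries: list[ScenarioSummary], path) -> None:
    """Coverage-by-sample-size lines, one per variant (presentation only)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = table_frame(summaries)
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for variant, sub in df.groupby("variant"):
        sub = sub.sort_values("n")
        ax.plot(sub["n"], sub["coverage"], marker="o", label=variant)
    ax.axhline(0.95, ls="--", color="grey")
    ax.set_xlabel("sample size n")
    ax.set_ylabel("95% CI coverage")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
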