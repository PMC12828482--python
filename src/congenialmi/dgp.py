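"""Synthetic cohort generation and MAR missingness.

Six data-generating scenarios are supported, all with a binary exposure X,
a continuous outcome Y and a true average treatment effect of 1.

Single-confounder scenarios (covariates ``zi`` instrument, ``zp`` precision
variable, ``zc`` confounder):

``linear_het``
    Y = 0.5·X + ZC + 2·ZP + 0.5·X·ZC + ε  (heterogeneous effect)
``linear_homog``
    Y = X + ZC + 2·ZP + ε
``nonlinear_prec``
    Y = 0.5·X + ZC + 2·ZP² + 0.5·X·ZC + ε

with ZI, ZP ~ N(0,1), ZC ~ N(1,1) and
P(X=1) = (1 + exp{ZC − 2·ZI})⁻¹.

Two-confounder scenarios (``zc1`` partially missing later, ``zc2`` fully
observed), ZC1, ZC2 ~ N(1,1):

``s1_nl_x``
    P(X=1) = (1 + exp{ZC1 + ZC2²})⁻¹;  Y = 0.5X + ZC1 + ZC2 + 0.5X·ZC1 + ε
``s2_nl_y``
    P(X=1) = (1 + exp{ZC1 + ZC2})⁻¹;   Y = 0.5X + ZC1 + ZC2² + 0.5X·ZC1 + ε
``s3_nl_both``
    P(X=1) = (1 + exp{ZC1 + ZC2²})⁻¹;  Y = 0.5X + ZC1 + ZC2² + 0.5X·ZC1 + ε

Missingness (missing-at-random, one variable per pattern):

``outcome``     masks Y   with P(M=1) = (1 + exp{0.65 + ZC})⁻¹
``confounder``  masks ZC  with P(M=1) = (1 + exp{1.15 + 0.5·X})⁻¹

(ZC1 plays the role of ZC in two-confounder scenarios.)  Both mechanisms
yield roughly 20% marginal missingness.

Draw order within one generator stream is fixed and documented: covariates
in column order, then the exposure uniforms, then the outcome noise ε.
Missingness uses a separate stream (or the tail of the same one when a
single seed is given to :func:`induce_missingness`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import InvalidArgumentError

SINGLE_CONFOUNDER_SCENARIOS = ("linear_het", "linear_homog", "nonlinear_prec")
TWO_CONFOUNDER_SCENARIOS = ("s1_nl_x", "s2_nl_y", "s3_nl_both")
ALL_SCENARIOS = SINGLE_CONFOUNDER_SCENARIOS + TWO_CONFOUNDER_SCENARIOS

PATTERNS = ("confounder", "outcome")

#: mean of the confounder distribution; enters the closed-form ATE of the
#: heterogeneous scenarios as 0.5 + 0.5·E[ZC].
_ZC_MEAN = 1.0


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class CompleteData:
    """One fully observed simulated cohort.

    ``df`` holds columns ``zi, zp, zc, x, y`` (single-confounder scenarios)
    or ``zc1, zc2, x, y`` (two-confounder scenarios); ``x`` is 0/1.
    """

    df: pd.DataFrame
    scenario_id: str

    def __post_init__(self) -> None:
        x = np.asarray(self.df["x"])
        if not np.isin(x[~np.isnan(x)], (0, 1)).all():
            raise InvalidArgumentError("exposure must be binary 0/1")

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.df.columns if c not in ("x", "y")]

    def validate_complete(self) -> None:
        if self.df.isna().any().any():
            raise InvalidArgumentError("CompleteData contains missing entries")

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, scenario_id: str) -> "CompleteData":
        return cls(pd.read_csv(path), scenario_id)


@dataclass
class ObservedData:
    """A complete cohort plus a missingness mask on exactly one variable."""

    base: CompleteData
    pattern: str
    mask: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise InvalidArgumentError(f"unknown pattern {self.pattern!r}")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (self.base.n,):
            raise InvalidArgumentError("mask length must equal n")

    @property
    def n(self) -> int:
        return self.base.n

    @property
    def target_variable(self) -> str:
        """Name of the (single) variable subject to masking."""
        if self.pattern == "outcome":
            return "y"
        return "zc1" if "zc1" in self.base.df.columns else "zc"

    def observed_frame(self) -> pd.DataFrame:
        """The analyst's view: masked entries replaced by NaN."""
        out = self.base.df.copy()
        out.loc[self.mask, self.target_variable] = np.nan
        return out

    @property
    def n_missing(self) -> int:
        return int(self.mask.sum())

    def to_csv(self, path) -> None:
        """Write the observed view (masked entries as empty fields) plus mask."""
        out = self.observed_frame()
        out["missing"] = self.mask.astype(int)
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, scenario_id: str, pattern: str) -> "ObservedData":
        """Read an observed view back.

        True values of masked entries are not serialized; the reconstructed
        base carries NaN at masked positions and is suitable for analysis,
        not for oracle comparisons against the generating values.
        """
        df = pd.read_csv(path)
        mask = df.pop("missing").to_numpy(dtype=bool)
        return cls(CompleteData(df, scenario_id), pattern, mask)


# ---------------------------------------------------------------------------
# generating equations
# ---------------------------------------------------------------------------


def exposure_probability(scenario: str, df: pd.DataFrame) -> np.ndarray:
    """True P(X=1 | covariates) for a scenario, evaluated row-wise."""
    if scenario in SINGLE_CONFOUNDER_SCENARIOS:
        return expit(-(df["zc"].to_numpy() - 2.0 * df["zi"].to_numpy()))
    if scenario in ("s1_nl_x", "s3_nl_both"):
        return expit(-(df["zc1"].to_numpy() + df["zc2"].to_numpy() ** 2))
    if scenario == "s2_nl_y":
        return expit(-(df["zc1"].to_numpy() + df["zc2"].to_numpy()))
    raise InvalidArgumentError(f"unknown scenario {scenario!r}")


def outcome_mean(scenario: str, x: np.ndarray, df: pd.DataFrame) -> np.ndarray:
    """E[Y | X=x, covariates] — the noiseless outcome equation."""
    x = np.asarray(x, dtype=float)
    if scenario == "linear_het":
        return 0.5 * x + df["zc"] + 2.0 * df["zp"] + 0.5 * x * df["zc"]
    if scenario == "linear_homog":
        return x + df["zc"] + 2.0 * df["zp"]
    if scenario == "nonlinear_prec":
        return 0.5 * x + df["zc"] + 2.0 * df["zp"] ** 2 + 0.5 * x * df["zc"]
    if scenario == "s1_nl_x":
        return 0.5 * x + df["zc1"] + df["zc2"] + 0.5 * x * df["zc1"]
    if scenario in ("s2_nl_y", "s3_nl_both"):
        return 0.5 * x + df["zc1"] + df["zc2"] ** 2 + 0.5 * x * df["zc1"]
    raise InvalidArgumentError(f"unknown scenario {scenario!r}")


def missingness_probability(pattern: str, data: CompleteData) -> np.ndarray:
    """True P(M=1 | observed data) for the pattern's target variable."""
    df = data.df
    zc = df["zc1"] if "zc1" in df.columns else df["zc"]
    if pattern == "outcome":
        return expit(-(0.65 + zc.to_numpy()))
    if pattern == "confounder":
        return expit(-(1.15 + 0.5 * df["x"].to_numpy()))
    raise InvalidArgumentError(f"unknown pattern {pattern!r}")


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def make_single_confounder_data(n: int, scenario: str, seed) -> CompleteData:
    """Generate a complete cohort under a single-confounder scenario."""
    if scenario not in SINGLE_CONFOUNDER_SCENARIOS:
        raise InvalidArgumentError(f"unknown scenario {scenario!r}")
    if n < 2:
        raise InvalidArgumentError("n must be at least 2")
    rng = _as_rng(seed)
    df = pd.DataFrame(
        {
            "zi": rng.normal(0.0, 1.0, n),
            "zp": rng.normal(0.0, 1.0, n),
            "zc": rng.normal(1.0, 1.0, n),
        }
    )
    p = exposure_probability(scenario, df)
    df["x"] = (rng.uniform(size=n) < p).astype(float)
    eps = rng.normal(0.0, 1.0, n)
    df["y"] = outcome_mean(scenario, df["x"].to_numpy(), df) + eps
    return CompleteData(df, scenario)


def make_two_confounder_data(n: int, scenario: str, seed) -> CompleteData:
    """Generate a complete cohort under a two-confounder scenario."""
    if scenario not in TWO_CONFOUNDER_SCENARIOS:
        raise InvalidArgumentError(f"unknown scenario {scenario!r}")
    if n < 2:
        raise InvalidArgumentError("n must be at least 2")
    rng = _as_rng(seed)
    df = pd.DataFrame(
        {
            "zc1": rng.normal(1.0, 1.0, n),
            "zc2": rng.normal(1.0, 1.0, n),
        }
    )
    p = exposure_probability(scenario, df)
    df["x"] = (rng.uniform(size=n) < p).astype(float)
    eps = rng.normal(0.0, 1.0, n)
    df["y"] = outcome_mean(scenario, df["x"].to_numpy(), df) + eps
    return CompleteData(df, scenario)


def make_data(n: int, scenario: str, seed) -> CompleteData:
    """Dispatch to the single- or two-confounder generator by scenario label."""
    if scenario in SINGLE_CONFOUNDER_SCENARIOS:
        return make_single_confounder_data(n, scenario, seed)
    if scenario in TWO_CONFOUNDER_SCENARIOS:
        return make_two_confounder_data(n, scenario, seed)
    raise InvalidArgumentError(f"unknown scenario {scenario!r}")


def induce_missingness(data: CompleteData, pattern: str, seed) -> ObservedData:
    """Mask the pattern's target variable, independently per unit."""
    p = missingness_probability(pattern, data)
    rng = _as_rng(seed)
    mask = rng.uniform(size=data.n) < p
    return ObservedData(data, pattern, mask)


def true_ate(scenario: str) -> float:
    """Closed-form E[Y(1) − Y(0)] for a scenario.

    Heterogeneous-effect scenarios have Y(1) − Y(0) = 0.5 + 0.5·ZC (or ZC1),
    whose expectation is 0.5 + 0.5·E[ZC] = 1 since ZC ~ N(1,1); the
    homogeneous scenario has a unit coefficient on X.
    """
    if scenario == "linear_homog":
        return 1.0
    if scenario in ALL_SCENARIOS:
        return 0.5 + 0.5 * _ZC_MEAN
    raise InvalidArgumentError(f"unknown scenario {scenario!r}")
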