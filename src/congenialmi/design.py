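"""Design-matrix construction from declarative term lists.

A model's right-hand side is a list of :class:`Term` objects, each naming a
dataset variable and a transform: ``identity``, ``square`` (v²) or
``nspline`` (natural cubic spline basis of a given dimension).  Knots fitted
on one set of rows can be frozen and re-used when evaluating the basis on
new rows — required when predicting outcomes or imputations for units that
were not in the fitting set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateBasisError, InvalidArgumentError

TRANSFORMS = ("identity", "square", "nspline")


@dataclass(frozen=True)
class Term:
    variable: str
    transform: str = "identity"
    df: int | None = None  # basis dimension, nspline only

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise InvalidArgumentError(f"unknown transform {self.transform!r}")
        if self.transform == "nspline":
            if self.df is None or self.df < 1:
                raise InvalidArgumentError("nspline requires df >= 1")
        elif self.df is not None:
            raise InvalidArgumentError(f"{self.transform} takes no df")

    @property
    def key(self) -> str:
        if self.transform == "nspline":
            return f"ns({self.variable},{self.df})"
        if self.transform == "square":
            return f"{self.variable}^2"
        return self.variable

    def to_dict(self) -> dict:
        d = {"variable": self.variable, "transform": self.transform}
        if self.df is not None:
            d["df"] = self.df
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Term":
        return cls(d["variable"], d.get("transform", "identity"), d.get("df"))


@dataclass
class DesignMatrix:
    values: np.ndarray
    column_labels: list[str]
    intercept_included: bool
    knot_store: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


def natural_spline_basis(
    values: np.ndarray, df: int, knots: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Natural cubic spline basis of dimension ``df`` (no intercept column).

    Uses the truncated-power natural basis: with knots ξ₁ < … < ξ_K
    (K = df + 1), the basis is x together with
    d_k(x) − d_{K−1}(x) for k = 1 … K−2, where
    d_k(x) = [(x−ξ_k)₊³ − (x−ξ_K)₊³] / (ξ_K − ξ_k).
    Functions in this span are cubic between knots and linear beyond the
    boundary knots.  When ``knots`` is omitted, boundary knots sit at the
    min/max of ``values`` and the df−1 interior knots at evenly spaced
    quantiles (i/df for i = 1 … df−1).

    Returns ``(basis, knots)`` so the identical basis can be re-evaluated on
    new points.
    """
    x = np.asarray(values, dtype=float)
    if not np.isfinite(x).all():
        raise InvalidArgumentError("spline input contains non-finite values")
    if df < 1:
        raise InvalidArgumentError("df must be >= 1")
    if knots is None:
        probs = np.linspace(0.0, 1.0, df + 1)
        knots = np.quantile(x, probs)
    knots = np.asarray(knots, dtype=float)
    if len(knots) != df + 1 or len(np.unique(knots)) != df + 1:
        raise DegenerateBasisError(
            f"need {df + 1} distinct knots for a df={df} basis, got {knots!r}"
        )
    basis = np.empty((len(x), df))
    basis[:, 0] = x
    if df > 1:
        span = np.clip(x[:, None] - knots[None, :], 0.0, None) ** 3
        # d_k(x), k = 0 … K−2 in zero-based indexing
        d = (span[:, :-1] - span[:, -1:]) / (knots[-1] - knots[:-1])
        basis[:, 1:] = d[:, :-1] - d[:, -1:]
    return basis, knots


def build_design_matrix(
    data: pd.DataFrame,
    terms: list[Term],
    intercept: bool = True,
    knot_store: dict | None = None,
) -> DesignMatrix:
    """Concatenate term columns (in term order) into a design matrix.

    ``knot_store`` maps a spline term's key to its knot vector; knots absent
    from the store are fitted on ``data`` and recorded in the returned
    matrix's ``knot_store``, so a second call with that store re-evaluates
    the identical basis on prediction rows.
    """
    store = dict(knot_store) if knot_store else {}
    cols: list[np.ndarray] = []
    labels: list[str] = []
    if intercept:
        cols.append(np.ones(len(data)))
        labels.append("intercept")
    for term in terms:
        if term.variable not in data.columns:
            raise InvalidArgumentError(f"variable {term.variable!r} not in data")
        v = data[term.variable].to_numpy(dtype=float)
        if not np.isfinite(v).all():
            raise InvalidArgumentError(
                f"variable {term.variable!r} has non-finite entries"
            )
        if term.transform == "identity":
            cols.append(v)
            labels.append(term.key)
        elif term.transform == "square":
            cols.append(v**2)
            labels.append(term.key)
        else:
            basis, knots = natural_spline_basis(v, term.df, store.get(term.key))
            store[term.key] = knots
            cols.extend(basis.T)
            labels.extend(f"{term.key}[{j}]" for j in range(term.df))
    values = np.column_stack(cols) if cols else np.empty((len(data), 0))
    return DesignMatrix(values, labels, intercept, store)
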