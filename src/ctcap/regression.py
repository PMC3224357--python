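"""Height/weight effective-dose regression with BIC subset selection.

Candidate predictors are height (cm), height^2, weight (kg) and weight^2.
Model selection enumerates all subsets and minimizes

    BIC = n ln(RSS/n) + k ln(n),

with k counting the intercept; ties break toward fewer terms, then by term
order.  An optional univariate screen (default on) admits only terms with a
univariate slope p-value below 0.05 before the subset search.

The package also freezes the published predictive model

    E (mSv) = 18 + 0.067 H(cm) - 0.11 W(kg)

as :data:`PUBLISHED_MODEL`, kept separate from any refitted model.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .body import BodySpec
from .errors import ConfigurationError, InvalidMeasurementError, SingularDesignError

#: candidate terms in canonical order
TERMS = ("H", "H2", "W", "W2")


def term_value(term: str, spec: BodySpec) -> float:
    if term == "H":
        return spec.height_cm
    if term == "H2":
        return spec.height_cm ** 2
    if term == "W":
        return spec.weight_kg
    if term == "W2":
        return spec.weight_kg ** 2
    raise ConfigurationError(f"unknown regression term {term!r}")


@dataclass(frozen=True)
class RegressionDataset:
    """Paired (body, effective dose mSv) observations."""

    rows: tuple  # of (BodySpec, float)

    def __post_init__(self):
        if len(self.rows) < len(TERMS) + 2:
            raise ConfigurationError(
                f"need at least {len(TERMS) + 2} observations, got {len(self.rows)}")
        seen = {}
        for spec, dose in self.rows:
            key = (spec.height_cm, spec.weight_kg)
            if key in seen and not math.isclose(seen[key], dose, rel_tol=1e-12, abs_tol=1e-12):
                raise ConfigurationError(
                    f"duplicated (height, weight) {key} with conflicting doses")
            seen[key] = dose

    @property
    def n(self) -> int:
        return len(self.rows)

    def design(self, terms) -> np.ndarray:
        X = np.column_stack(
            [np.ones(self.n)]
            + [[term_value(t, s) for s, _ in self.rows] for t in terms]
        )
        return X

    @property
    def response(self) -> np.ndarray:
        return np.array([d for _, d in self.rows], dtype=float)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RegressionDataset":
        rows = tuple(
            (BodySpec(height_cm=float(r.height_cm), weight_kg=float(r.weight_kg)),
             float(r.effective_dose_mSv))
            for r in df.itertuples()
        )
        return cls(rows=rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "height_cm": [s.height_cm for s, _ in self.rows],
            "weight_kg": [s.weight_kg for s, _ in self.rows],
            "effective_dose_mSv": [d for _, d in self.rows],
        })


@dataclass(frozen=True)
class FittedModel:
    """Regression result: coefficients, fit statistics, selection metadata."""

    intercept: float
    coefficients: dict            # term -> mSv per unit
    included_terms: tuple
    r_squared: float
    bic: float
    p_values: dict = field(default_factory=dict)
    search_trace: tuple = ()      # ((terms, bic), ...) when selected by BIC

    def predict_raw(self, spec: BodySpec) -> float:
        return self.intercept + sum(
            c * term_value(t, spec) for t, c in self.coefficients.items()
        )


#: the published predictive model, frozen at its printed coefficients
PUBLISHED_MODEL = FittedModel(
    intercept=18.0,
    coefficients={"H": 0.067, "W": -0.11},
    included_terms=("H", "W"),
    r_squared=0.96,
    bic=float("nan"),
)


def _bic(n: int, rss: float, k: int, tss: float) -> float:
    # exact fits leave numerical-noise RSS whose log is meaningless; floor it
    floor = 1e-12 * max(tss, 1.0)
    return n * math.log(max(rss, floor) / n) + k * math.log(n)


def ols_fit(data: RegressionDataset, terms) -> FittedModel:
    """Ordinary least squares on the given term subset (intercept always included)."""
    terms = tuple(t for t in TERMS if t in set(terms))
    X = data.design(terms)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularDesignError(f"design matrix rank deficient for terms {terms}")
    res = sm.OLS(data.response, X).fit()
    rss = float(res.ssr)
    tss = float(res.centered_tss)
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss <= 1e-12 else 0.0)
    return FittedModel(
        intercept=float(res.params[0]),
        coefficients={t: float(res.params[i + 1]) for i, t in enumerate(terms)},
        included_terms=terms,
        r_squared=r2,
        bic=_bic(data.n, rss, X.shape[1], tss),
        p_values={t: float(res.pvalues[i + 1]) for i, t in enumerate(terms)},
    )


def univariate_screen(data: RegressionDataset, alpha: float = 0.05) -> tuple:
    """Terms with a significant univariate association with the response."""
    kept = []
    for t in TERMS:
        model = ols_fit(data, (t,))
        if model.p_values[t] < alpha:
            kept.append(t)
    return tuple(kept)


def select_by_bic(data: RegressionDataset, screen: bool = True,
                  alpha: float = 0.05) -> FittedModel:
    """Exhaustive minimum-BIC subset selection over the candidate terms.

    Ties break toward fewer terms, then lexicographically in canonical term
    order.  The full search trace is attached to the returned model.
    """
    candidates = univariate_screen(data, alpha) if screen else TERMS
    trace = []
    best = None
    best_key = None
    for r in range(len(candidates) + 1):
        for subset in itertools.combinations(candidates, r):
            model = ols_fit(data, subset)
            trace.append((subset, model.bic))
            key = (model.bic, len(subset), subset)
            if best is None or key < best_key:
                best = model
                best_key = key
    return FittedModel(
        intercept=best.intercept, coefficients=best.coefficients,
        included_terms=best.included_terms, r_squared=best.r_squared,
        bic=best.bic, p_values=best.p_values, search_trace=tuple(trace),
    )


@dataclass(frozen=True)
class Prediction:
    """A predicted effective dose; flags extrapolation beyond the training BMI span."""

    value_mSv: float
    extrapolated: bool = False
    note: str = ""

    def __float__(self) -> float:
        return self.value_mSv


def predict_effective_dose(model: FittedModel, spec: BodySpec,
                           bmi_range: tuple = (18.0, 36.0)) -> Prediction:
    """Evaluate a fitted model at a body spec, flagging out-of-range BMI."""
    value = model.predict_raw(spec)
    if not (bmi_range[0] <= spec.bmi <= bmi_range[1]):
        return Prediction(
            value_mSv=value, extrapolated=True,
            note=(f"BMI {spec.bmi:.1f} outside training range "
                  f"[{bmi_range[0]}, {bmi_range[1]}]"),
        )
    return Prediction(value_mSv=value)


def coefficient_percent_effect(model: FittedModel, reference_dose: float) -> dict:
    """Per-unit coefficient effects as percent of a reference effective dose."""
    if reference_dose <= 0:
        raise InvalidMeasurementError("reference dose must be > 0")
    return {t: 100.0 * c / reference_dose for t, c in model.coefficients.items()}
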