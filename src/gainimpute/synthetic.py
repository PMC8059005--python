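"""Synthetic mixed-type clinical tables.

A Gaussian copula couples all predictors; each margin is then shaped
independently: continuous variables are normal or shifted lognormal (the
lognormal sigma can be solved from a target skewness, which for a lognormal
is (e^{s^2}+2) * sqrt(e^{s^2}-1), monotone in s), and categorical variables
are obtained by thresholding the latent normal at the quantiles implied by
their target proportions.  Binary outcome variables (role = dependent, fully
observed) are Bernoulli draws from a logistic model on the standardized
predictors, so missing-at-random amputation driven by the outcomes has real
structure to exploit.

Two presets emulate the shape of large primary-care cohorts: ``dm_like``
(a diabetes-complications cohort: 15 continuous + 6 categorical predictors,
7 binary outcomes, default n = 50,000, skewness from near-symmetric to ~11
and minority proportions down to ~8.5%) and ``ht_like`` (a hypertension
programme cohort: 5 continuous + 5 categorical predictors, 2 outcomes,
default n = 10,000).  All preset parameter values are plausible clinical
magnitudes chosen for this synthetic generator — they are not estimates of
any real cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

from .schema import (
    CATEGORICAL,
    CONTINUOUS,
    DEPENDENT,
    INDEPENDENT,
    IncompleteTable,
    TableSchema,
    VariableSchema,
)


@dataclass(frozen=True)
class ContinuousSpec:
    """One continuous margin.

    ``family='normal'``: value = loc + scale * z.
    ``family='lognormal'``: value = loc + scale * exp(sigma * z); give either
    ``sigma`` or ``skewness`` (solved for sigma).
    """

    name: str
    family: str = "normal"
    loc: float = 0.0
    scale: float = 1.0
    sigma: float | None = None
    skewness: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("normal", "lognormal"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.family == "lognormal" and self.sigma is None and self.skewness is None:
            raise ValueError("lognormal margin needs sigma or target skewness")

    def resolved_sigma(self) -> float:
        if self.sigma is not None:
            return float(self.sigma)
        return sigma_for_skewness(self.skewness)


@dataclass(frozen=True)
class CategoricalSpec:
    name: str
    categories: tuple[str, ...]
    proportions: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.categories) != len(self.proportions) or len(self.categories) < 2:
            raise ValueError("categories and proportions must align (>= 2)")
        if abs(sum(self.proportions) - 1.0) > 1e-9 or min(self.proportions) <= 0:
            raise ValueError("proportions must be positive and sum to 1")


@dataclass(frozen=True)
class OutcomeSpec:
    """Binary outcome: Bernoulli(logistic(intercept + coef' standardized
    predictors)); ``coefficients`` maps predictor names to slopes (absent
    names get 0)."""

    name: str
    coefficients: dict[str, float] = field(default_factory=dict)
    intercept: float = -1.5


@dataclass
class SyntheticSpec:
    n: int
    continuous: list[ContinuousSpec]
    categorical: list[CategoricalSpec]
    outcomes: list[OutcomeSpec]
    correlation: np.ndarray | None = None  # over predictors, cont then cat
    seed: int = 0

    @property
    def predictor_names(self) -> list[str]:
        return [c.name for c in self.continuous] + [c.name for c in self.categorical]

    def validate(self) -> None:
        d = len(self.continuous) + len(self.categorical)
        if self.n < 1 or d < 1:
            raise ValueError("need n >= 1 and at least one predictor")
        names = self.predictor_names + [o.name for o in self.outcomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names")
        if self.correlation is not None:
            C = np.asarray(self.correlation, float)
            if C.shape != (d, d):
                raise ValueError(f"correlation must be {d}x{d}")
            if not np.allclose(C, C.T) or not np.allclose(np.diag(C), 1.0):
                raise ValueError("correlation must be symmetric with unit diagonal")
        for o in self.outcomes:
            unknown = set(o.coefficients) - set(self.predictor_names)
            if unknown:
                raise ValueError(f"outcome {o.name!r}: unknown predictors {unknown}")


def sigma_for_skewness(skew: float) -> float:
    """Invert the lognormal skewness formula (e^{s^2}+2)sqrt(e^{s^2}-1)."""
    if skew <= 0:
        raise ValueError("lognormal skewness target must be positive")

    def f(s: float) -> float:
        w = np.exp(s * s)
        return (w + 2.0) * np.sqrt(w - 1.0) - skew

    return float(brentq(f, 1e-9, 5.0, xtol=1e-12))


def build_schema(spec: SyntheticSpec) -> TableSchema:
    vs: list[VariableSchema] = []
    for c in spec.continuous:
        vs.append(VariableSchema(c.name, CONTINUOUS, role=INDEPENDENT))
    for c in spec.categorical:
        vs.append(
            VariableSchema(c.name, CATEGORICAL, categories=c.categories,
                           role=INDEPENDENT)
        )
    for o in spec.outcomes:
        vs.append(
            VariableSchema(o.name, CATEGORICAL, categories=("no", "yes"),
                           role=DEPENDENT)
        )
    return TableSchema(vs)


def generate(spec: SyntheticSpec) -> IncompleteTable:
    """Draw a complete table; bit-deterministic given ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    d = len(spec.continuous) + len(spec.categorical)
    if spec.correlation is None:
        L = np.eye(d)
    else:
        try:
            L = np.linalg.cholesky(np.asarray(spec.correlation, float))
        except np.linalg.LinAlgError:
            raise ValueError("correlation matrix is not positive definite") from None
    Z = rng.standard_normal((spec.n, d)) @ L.T

    df = pd.DataFrame(index=range(spec.n))
    std_cols: list[np.ndarray] = []
    for j, c in enumerate(spec.continuous):
        z = Z[:, j]
        if c.family == "normal":
            x = c.loc + c.scale * z
        else:
            x = c.loc + c.scale * np.exp(c.resolved_sigma() * z)
        df[c.name] = x
        std_cols.append(_standardize(x))
    for j, c in enumerate(spec.categorical):
        z = Z[:, len(spec.continuous) + j]
        cuts = norm.ppf(np.cumsum(c.proportions[:-1]))
        idx = np.searchsorted(cuts, z)
        df[c.name] = np.asarray(c.categories, object)[idx]
        std_cols.append(_standardize(idx.astype(float)))

    S = np.column_stack(std_cols)
    names = spec.predictor_names
    for o in spec.outcomes:
        coef = np.array([o.coefficients.get(nm, 0.0) for nm in names])
        p = expit(o.intercept + S @ coef)
        y = rng.random(spec.n) < p
        df[o.name] = np.where(y, "yes", "no").astype(object)

    return IncompleteTable.complete(df, build_schema(spec))


def _standardize(x: np.ndarray) -> np.ndarray:
    s = x.std()
    return (x - x.mean()) / (s if s > 0 else 1.0)


def _decay_correlation(d: int, rho: float = 0.5) -> np.ndarray:
    idx = np.arange(d)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def preset(name: str, n: int | None = None, seed: int = 0) -> SyntheticSpec:
    """Named dataset profiles: ``dm_like`` or ``ht_like``."""
    if name == "dm_like":
        return _dm_like(n or 50_000, seed)
    if name == "ht_like":
        return _ht_like(n or 10_000, seed)
    raise ValueError(f"unknown preset {name!r} (expected 'dm_like' or 'ht_like')")


def _dm_like(n: int, seed: int) -> SyntheticSpec:
    continuous = [
        ContinuousSpec("age", "normal", 64.0, 10.0),
        ContinuousSpec("sbp", "normal", 135.0, 18.0),
        ContinuousSpec("dbp", "normal", 76.0, 10.0),
        ContinuousSpec("ldl_c", "normal", 3.0, 0.9),
        ContinuousSpec("bmi", "normal", 25.5, 4.0),
        ContinuousSpec("waist", "normal", 88.0, 10.0),
        ContinuousSpec("tc", "normal", 5.0, 1.0),
        ContinuousSpec("dm_duration", "normal", 7.0, 5.0),
        ContinuousSpec("egfr", "lognormal", 30.0, 45.0, skewness=1.4),
        ContinuousSpec("hba1c", "lognormal", 5.0, 2.0, skewness=1.6),
        ContinuousSpec("hdl_c", "lognormal", 0.6, 0.6, skewness=2.7),
        ContinuousSpec("tg", "lognormal", 0.3, 1.2, skewness=3.9),
        ContinuousSpec("creatinine", "lognormal", 40.0, 35.0, skewness=4.1),
        ContinuousSpec("fasting_glucose", "lognormal", 3.5, 3.5, skewness=4.7),
        ContinuousSpec("urine_acr", "lognormal", 0.0, 2.0, skewness=11.45),
    ]
    categorical = [
        CategoricalSpec("lipid_drug", ("no", "yes"), (0.915, 0.085)),
        CategoricalSpec("smoker", ("no", "yes"), (0.8943, 0.1057)),
        CategoricalSpec("dm_treatment", ("no", "yes"), (0.895, 0.105)),
        CategoricalSpec("ht_drug", ("no", "yes"), (0.7032, 0.2968)),
        CategoricalSpec("sex", ("female", "male"), (0.5407, 0.4593)),
        CategoricalSpec("ht_history", ("no", "yes"), (0.5281, 0.4719)),
    ]
    outcomes = [
        OutcomeSpec("cvd", {"age": 0.7, "sbp": 0.6, "smoker": 0.5}, -1.6),
        OutcomeSpec("stroke", {"age": 0.6, "sbp": 0.7, "ht_history": 0.5}, -1.8),
        OutcomeSpec("ckd", {"creatinine": 0.8, "urine_acr": 0.6, "egfr": -0.6}, -1.7),
        OutcomeSpec("retinopathy", {"hba1c": 0.7, "dm_duration": 0.6}, -1.8),
        OutcomeSpec("neuropathy", {"hba1c": 0.6, "fasting_glucose": 0.5}, -1.9),
        OutcomeSpec("hospitalization", {"age": 0.5, "bmi": 0.5, "tg": 0.5}, -1.4),
        OutcomeSpec("death", {"age": 0.9, "creatinine": 0.5}, -2.0),
    ]
    return SyntheticSpec(
        n=n,
        continuous=continuous,
        categorical=categorical,
        outcomes=outcomes,
        correlation=_decay_correlation(21, 0.5),
        seed=seed,
    )


def _ht_like(n: int, seed: int) -> SyntheticSpec:
    continuous = [
        ContinuousSpec("age", "normal", 66.0, 11.0),
        ContinuousSpec("sbp", "normal", 140.0, 17.0),
        ContinuousSpec("charlson_index", "normal", 2.0, 1.2),
        ContinuousSpec("tc_hdl_ratio", "lognormal", 2.0, 1.4, skewness=3.14),
        ContinuousSpec("admissions", "lognormal", -0.5, 0.8, skewness=7.04),
    ]
    categorical = [
        CategoricalSpec("smoking", ("no", "yes"), (0.9255, 0.0745)),
        CategoricalSpec("ht_drugs", ("no", "yes"), (0.919, 0.081)),
        CategoricalSpec("lipid_drugs", ("no", "yes"), (0.9001, 0.0999)),
        CategoricalSpec("overweight", ("no", "yes"), (0.6211, 0.3789)),
        CategoricalSpec("sex", ("female", "male"), (0.5879, 0.4121)),
    ]
    outcomes = [
        OutcomeSpec("cvd", {"age": 0.7, "sbp": 0.6, "smoking": 0.5}, -1.5),
        OutcomeSpec("death", {"age": 0.9, "charlson_index": 0.6}, -2.0),
    ]
    return SyntheticSpec(
        n=n,
        continuous=continuous,
        categorical=categorical,
        outcomes=outcomes,
        correlation=_decay_correlation(10, 0.5),
        seed=seed,
    )


def demo_correlated_spec(
    n: int = 2000,
    seed: int = 0,
    rho: float = 0.9,
    n_cont: int = 3,
    n_cat: int = 2,
) -> SyntheticSpec:
    """Small equicorrelated mixed table for demonstrations and sanity
    experiments: with rho near 1 every variable is predictable from the
    others, so any imputer that uses covariate information should beat the
    column mean/mode."""
    d = n_cont + n_cat
    C = np.full((d, d), rho)
    np.fill_diagonal(C, 1.0)
    continuous = [
        ContinuousSpec(f"x{i}", "normal", 10.0 * (i + 1), 2.0 + i)
        for i in range(n_cont)
    ]
    categorical = [
        CategoricalSpec(f"c{i}", ("a", "b"), (0.65, 0.35)) for i in range(n_cat)
    ]
    outcomes = [OutcomeSpec("event", {"x0": 0.8, "c0": 0.6}, -0.5)]
    return SyntheticSpec(
        n=n,
        continuous=continuous,
        categorical=categorical,
        outcomes=outcomes,
        correlation=C,
        seed=seed,
    )
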