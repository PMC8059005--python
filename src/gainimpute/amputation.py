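"""Missing-at-random amputation of complete tables.

Missingness is introduced into each independent variable by an independent
per-entry Bernoulli draw whose probability is a logistic function of a linear
combination of the fully observed dependent variables:

    P(cell (i, j) missing) = sigmoid(c_j + w_j' z_i)

where ``z_i`` are the encoded, per-column standardized dependent variables of
row i, ``w_j`` is a standard-normal coefficient vector drawn per target
variable, and the intercept ``c_j`` is calibrated by bisection so that the
expected missingness of each target equals the nominal rate (defaults:
20% and 50%) on the calibration table.  Dependent variables are never
masked.  Replicate incomplete datasets use independently drawn mechanisms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, TransformerMixin

from .encoding import MixedEncoder
from .schema import IncompleteTable, TableSchema


@dataclass
class MarMechanism:
    """A calibrated MAR missingness mechanism.

    ``weights`` has one row per target (independent) variable over the
    encoded driver columns; ``driver_mean``/``driver_std`` standardize the
    encoded dependent variables the way they were at calibration time.
    """

    targets: list[str]
    drivers: list[str]
    weights: np.ndarray  # n_targets x n_driver_cols
    intercepts: np.ndarray  # n_targets
    rate: float
    driver_mean: np.ndarray = field(repr=False)
    driver_std: np.ndarray = field(repr=False)
    driver_blocks: list[tuple[str, int, int]] = field(repr=False)

    def to_record(self) -> dict:
        return {
            "targets": list(self.targets),
            "drivers": list(self.drivers),
            "rate": self.rate,
            "weights": self.weights.tolist(),
            "intercepts": self.intercepts.tolist(),
        }


def _encode_drivers(table: IncompleteTable) -> tuple[np.ndarray, list[tuple[str, int, int]]]:
    """Encode the dependent variables as a full-rank driver matrix.

    Continuous drivers are min-max scaled; categorical drivers use
    reference coding (the first category's indicator column is dropped) so
    that every mechanism weight is identifiable — a full one-hot block is
    collinear and would make the weights unrecoverable by regression.
    """
    dep = table.schema.dependent_names
    if not dep:
        raise ValueError("table has no dependent variables to drive MAR")
    sub_schema = TableSchema(v for v in table.schema if v.name in dep)
    sub = IncompleteTable(
        schema=sub_schema,
        values=table.values[dep],
        mask=table.mask[:, [table.schema.index(n) for n in dep]],
    )
    enc = MixedEncoder(sub_schema).fit(sub)
    Z_full, _ = enc.encode(sub)
    keep: list[int] = []
    blocks: list[tuple[str, int, int]] = []
    pos = 0
    for (name, start, stop), v in zip(enc.blocks_, sub_schema):
        cols = list(range(start, stop))
        if v.is_categorical:
            cols = cols[1:]  # reference coding
        keep.extend(cols)
        blocks.append((name, pos, pos + len(cols)))
        pos += len(cols)
    return Z_full[:, keep], blocks


def _standardize(Z: np.ndarray, mean: np.ndarray, std: np.ndarray) -> np.ndarray:
    return (Z - mean) / std


def calibrate_intercept(weights: np.ndarray, drivers: np.ndarray, rate: float) -> float:
    """Solve ``mean_i sigmoid(c + w'z_i) = rate`` for c by bisection.

    The mean is strictly increasing in c, so the root is unique; it is
    bracketed by widening and bisected to 1e-6.
    """
    if not 0.0 < rate < 1.0:
        raise ValueError(f"rate must be in (0,1), got {rate}")
    eta = drivers @ np.asarray(weights, float)

    def realized(c: float) -> float:
        return float(expit(c + eta).mean())

    lo, hi = -1.0, 1.0
    while realized(lo) > rate:
        lo *= 2.0
    while realized(hi) < rate:
        hi *= 2.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if realized(mid) < rate:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-9:
            break
    c = 0.5 * (lo + hi)
    assert abs(realized(c) - rate) < 1e-6
    return c


def draw_mechanism(table: IncompleteTable, rate: float, rng_seed: int) -> MarMechanism:
    """Draw a randomized, calibrated MAR mechanism for ``table``.

    Weights are independent standard normals per (target, encoded driver
    column); the mechanism is fully determined by ``rng_seed``.
    """
    if not 0.0 < rate < 1.0:
        raise ValueError(f"rate must be in (0,1), got {rate}")
    targets = table.schema.independent_names
    drivers = table.schema.dependent_names
    Z, blocks = _encode_drivers(table)
    mean = Z.mean(axis=0)
    std = Z.std(axis=0)
    std[std == 0] = 1.0  # constant driver column carries no signal
    Zs = _standardize(Z, mean, std)
    rng = np.random.default_rng(rng_seed)
    weights = rng.standard_normal((len(targets), Z.shape[1]))
    intercepts = np.array(
        [calibrate_intercept(weights[t], Zs, rate) for t in range(len(targets))]
    )
    return MarMechanism(
        targets=list(targets),
        drivers=list(drivers),
        weights=weights,
        intercepts=intercepts,
        rate=rate,
        driver_mean=mean,
        driver_std=std,
        driver_blocks=blocks,
    )


def standardized_drivers(table: IncompleteTable, mech: MarMechanism) -> np.ndarray:
    """The standardized driver matrix ``Z`` that ``mech`` acts on."""
    Z, _ = _encode_drivers(table)
    return _standardize(Z, mech.driver_mean, mech.driver_std)


def missingness_probabilities(table: IncompleteTable, mech: MarMechanism) -> np.ndarray:
    """Per-(row, target) missingness probabilities under ``mech``."""
    Zs = standardized_drivers(table, mech)
    return expit(mech.intercepts[None, :] + Zs @ mech.weights.T)


def ampute(table: IncompleteTable, mech: MarMechanism, rng_seed: int) -> IncompleteTable:
    """Apply ``mech`` to a complete table; deterministic given the seed."""
    if not table.is_complete:
        raise ValueError("ampute expects a complete table")
    probs = missingness_probabilities(table, mech)
    rng = np.random.default_rng(rng_seed)
    miss = rng.random(probs.shape) < probs
    mask = np.ones((table.n, table.d), dtype=bool)
    for t, name in enumerate(mech.targets):
        mask[:, table.schema.index(name)] = ~miss[:, t]
    return table.with_mask(mask)


def generate_replicates(
    table: IncompleteTable, rate: float, n_replicates: int = 10, rng_seed: int = 0
) -> list[IncompleteTable]:
    """Generate replicate incomplete datasets, each from a freshly drawn
    mechanism (default: ten per rate).

    Mechanism drawing and mask sampling use separate seeded streams so the
    replicate set is exactly reproducible.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    seeds = np.random.SeedSequence(rng_seed).generate_state(2 * n_replicates)
    out = []
    for r in range(n_replicates):
        mech = draw_mechanism(table, rate, int(seeds[2 * r] % (2**31)))
        out.append(ampute(table, mech, int(seeds[2 * r + 1] % (2**31))))
    return out


class MARAmputer(BaseEstimator, TransformerMixin):
    """Transformer that hides independent-variable cells MAR-style.

    ``fit`` draws and calibrates the mechanism on a complete DataFrame;
    ``transform`` returns a copy with NaN at the masked cells.

    Parameters
    ----------
    schema : TableSchema
    rate : float
        Nominal per-variable missingness rate in (0, 1).
    seed : int
        Seeds both mechanism drawing and mask sampling.
    """

    def __init__(self, schema: TableSchema, rate: float = 0.2, seed: int = 0):
        self.schema = schema
        self.rate = rate
        self.seed = seed

    def fit(self, X, y=None):
        table = IncompleteTable.complete(X, self.schema)
        mech_seed, self._mask_seed = (
            int(s % (2**31))
            for s in np.random.SeedSequence(self.seed).generate_state(2)
        )
        self.mechanism_ = draw_mechanism(table, self.rate, mech_seed)
        return self

    def transform(self, X):
        table = IncompleteTable.complete(X, self.schema)
        return ampute(table, self.mechanism_, self._mask_seed).values
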