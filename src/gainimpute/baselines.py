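"""Reference imputers for the benchmark harness.

``MeanModeImputer`` is the null baseline: column mean for continuous, modal
category for categorical.  ``ChainedImputer`` is an iterative per-variable
imputer in the missForest style: initialize by mean/mode, then repeatedly
re-fit a predictor for each variable on the currently completed data and
re-predict its missing cells, visiting variables in order of increasing
missingness, until the difference criterion first increases or the iteration
cap is reached.  The random-forest predictor uses the benchmark settings of
20 trees and sqrt-dimensionality feature sampling; a plain linear predictor
is available as a transparent alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import LinearRegression, LogisticRegression

from .schema import IncompleteTable, TableSchema


@dataclass(frozen=True)
class IterativeConfig:
    """Settings of the chained imputer.

    ``n_trees`` and the sqrt-of-dimensionality split sampling follow the
    benchmark's missForest configuration; ``max_iterations`` caps the
    chained passes at 10 by default.
    """

    predictor: str = "random_forest"  # or "linear"
    n_trees: int = 20
    max_iterations: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.predictor not in ("random_forest", "linear"):
            raise ValueError("predictor must be 'random_forest' or 'linear'")
        if self.n_trees < 1 or self.max_iterations < 0:
            raise ValueError("n_trees must be positive, max_iterations >= 0")


def impute_mean_mode(data: IncompleteTable) -> pd.DataFrame:
    """Column mean / modal category fill; mode ties break by schema order."""
    out = data.values.copy()
    for j, v in enumerate(data.schema):
        obs = data.mask[:, j]
        if not obs.any():
            raise ValueError(f"variable {v.name!r} is fully missing")
        col = out[v.name].to_numpy(copy=True)
        if v.is_continuous:
            col = col.astype(float)
            col[~obs] = col[obs].mean()
        else:
            col = col.astype(object)
            counts = [(col[obs] == c).sum() for c in v.categories]
            col[~obs] = v.categories[int(np.argmax(counts))]
        out[v.name] = col
    return out


def _feature_matrix(
    df: pd.DataFrame, schema: TableSchema, exclude: str
) -> np.ndarray:
    """Numeric design matrix from a completed frame, omitting ``exclude``."""
    cols = []
    for v in schema:
        if v.name == exclude:
            continue
        if v.is_continuous:
            cols.append(df[v.name].to_numpy(float)[:, None])
        else:
            vals = df[v.name].to_numpy(object)
            onehot = np.column_stack(
                [(vals == c).astype(float) for c in v.categories]
            )
            cols.append(onehot)
    return np.hstack(cols)


def _difference(
    new: pd.DataFrame, old: pd.DataFrame, data: IncompleteTable
) -> float:
    """missForest stopping statistic between successive imputations.

    Continuous: sum of squared changes normalized by the sum of squares of
    the new imputation; categorical: changed cells over missing cells.
    """
    schema = data.schema
    d_cont = num = den = 0.0
    d_cat_changed = d_cat_missing = 0.0
    for j, v in enumerate(schema):
        if v.role != "independent":
            continue
        miss = ~data.mask[:, j]
        if not miss.any():
            continue
        if v.is_continuous:
            a = new[v.name].to_numpy(float)
            b = old[v.name].to_numpy(float)
            num += float(((a - b) ** 2).sum())
            den += float((a**2).sum())
        else:
            a = new[v.name].to_numpy(object)
            b = old[v.name].to_numpy(object)
            d_cat_changed += float((a[miss] != b[miss]).sum())
            d_cat_missing += float(miss.sum())
    if den > 0:
        d_cont = num / den
    d_cat = d_cat_changed / d_cat_missing if d_cat_missing > 0 else 0.0
    return d_cont + d_cat


def _fit_predict(
    v, X_obs, y_obs, X_miss, config: IterativeConfig, seed: int
):
    if v.is_continuous:
        if config.predictor == "random_forest":
            est = RandomForestRegressor(
                n_estimators=config.n_trees,
                max_features="sqrt",
                random_state=seed,
                n_jobs=1,
            )
        else:
            est = LinearRegression()
        est.fit(X_obs, y_obs.astype(float))
        return est.predict(X_miss)
    classes = np.unique(y_obs.astype(str))
    if len(classes) == 1:
        return np.full(len(X_miss), classes[0], dtype=object)
    if config.predictor == "random_forest":
        est = RandomForestClassifier(
            n_estimators=config.n_trees,
            max_features="sqrt",
            random_state=seed,
            n_jobs=1,
        )
    else:
        est = LogisticRegression(max_iter=1000)
    est.fit(X_obs, y_obs.astype(str))
    return est.predict(X_miss).astype(object)


def impute_iterative(data: IncompleteTable, config: IterativeConfig) -> pd.DataFrame:
    """Chained imputation with the missForest loop and stopping rule.

    Deterministic given ``config.seed``; ``max_iterations=0`` reduces to the
    mean/mode baseline.
    """
    return _impute_iterative(data, config)[0]


def _impute_iterative(
    data: IncompleteTable, config: IterativeConfig
) -> tuple[pd.DataFrame, int, bool]:
    """Run the chained loop; returns (imputation, passes run, stopped early)."""
    if data.d < 2:
        raise ValueError("iterative imputation needs at least 2 variables")
    schema = data.schema
    current = impute_mean_mode(data)
    if config.max_iterations == 0:
        return current, 0, False

    miss_counts = {
        v.name: int((~data.mask[:, j]).sum()) for j, v in enumerate(schema)
    }
    order = [
        v.name
        for v in sorted(
            (v for v in schema if v.role == "independent" and miss_counts[v.name] > 0),
            key=lambda v: miss_counts[v.name],
        )
    ]
    if not order:
        return current, 0, False

    seeds = np.random.SeedSequence(config.seed).generate_state(
        config.max_iterations * len(order)
    )
    prev_diff = np.inf
    s = 0
    for it in range(config.max_iterations):
        new = current.copy()
        for name in order:
            j = schema.index(name)
            v = schema[name]
            obs = data.mask[:, j]
            X_full = _feature_matrix(new, schema, exclude=name)
            y = new[name].to_numpy()
            try:
                pred = _fit_predict(
                    v, X_full[obs], y[obs], X_full[~obs], config,
                    int(seeds[s] % (2**31)),
                )
            except Exception as exc:  # pragma: no cover - defensive
                raise RuntimeError(
                    f"predictor fit failed for variable {name!r} at "
                    f"iteration {it}: {exc}"
                ) from exc
            s += 1
            col = new[name].to_numpy(copy=True)
            col[~obs] = pred
            new[name] = col
        diff = _difference(new, current, data)
        if diff > prev_diff:
            # criterion increased: keep the previous iterate
            return current, it + 1, True
        current, prev_diff = new, diff
        if diff == 0.0:
            return current, it + 1, True
    return current, config.max_iterations, False


class MeanModeImputer(BaseEstimator, TransformerMixin):
    """Column mean / modal-category imputer (scikit-learn surface)."""

    def __init__(self, schema: TableSchema | None = None):
        self.schema = schema

    def fit(self, X: pd.DataFrame, y=None) -> "MeanModeImputer":
        data = IncompleteTable.from_dataframe(X, self.schema)
        self.means_ = {}
        self.modes_ = {}
        for j, v in enumerate(self.schema):
            obs = data.mask[:, j]
            if not obs.any():
                raise ValueError(f"variable {v.name!r} is fully missing")
            col = data.values[v.name].to_numpy()
            if v.is_continuous:
                self.means_[v.name] = float(col[obs].astype(float).mean())
            else:
                counts = [(col[obs] == c).sum() for c in v.categories]
                self.modes_[v.name] = v.categories[int(np.argmax(counts))]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        data = IncompleteTable.from_dataframe(X, self.schema)
        out = data.values.copy()
        for j, v in enumerate(self.schema):
            obs = data.mask[:, j]
            col = out[v.name].to_numpy(copy=True)
            fill = self.means_[v.name] if v.is_continuous else self.modes_[v.name]
            col[~obs] = fill
            out[v.name] = col
        return out


class ChainedImputer(BaseEstimator, TransformerMixin):
    """Iterative chained imputer (missForest-style) over DataFrames.

    The procedure is transductive — it runs on the frame handed to
    ``transform``; ``fit`` only validates parameters.
    """

    def __init__(
        self,
        schema: TableSchema | None = None,
        predictor: str = "random_forest",
        n_trees: int = 20,
        max_iterations: int = 10,
        seed: int = 0,
    ):
        self.schema = schema
        self.predictor = predictor
        self.n_trees = n_trees
        self.max_iterations = max_iterations
        self.seed = seed

    def _config(self) -> IterativeConfig:
        return IterativeConfig(
            predictor=self.predictor,
            n_trees=self.n_trees,
            max_iterations=self.max_iterations,
            seed=self.seed,
        )

    def fit(self, X: pd.DataFrame, y=None) -> "ChainedImputer":
        self._config()  # validate
        self.fitted_ = True
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        data = IncompleteTable.from_dataframe(X, self.schema)
        out, self.n_iter_, self.stopped_early_ = _impute_iterative(
            data, self._config()
        )
        return out
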