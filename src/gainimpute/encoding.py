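"""Encode mixed-type tables into the [0,1] matrix the GAIN networks train on.

Continuous variables are min-max scaled to [0,1] over their *observed* values
(sigmoid generator outputs then decode directly; out-of-range imputations are
clipped).  Categorical variables are one-hot encoded, one contiguous block of
columns per variable, in schema category order.  The encoded mask is defined
per variable and replicated across one-hot blocks: a categorical value is
observed or missing as a whole.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema import IncompleteTable, TableSchema


class DegenerateScaleError(ValueError):
    """A continuous variable has no spread among its observed values."""


@dataclass
class _Block:
    name: str
    start: int
    stop: int  # exclusive


class MixedEncoder:
    """Fit/transform-style encoder for mixed-type incomplete tables.

    Fitted attributes
    -----------------
    mins_, maxs_ : dict
        Observed min/max per continuous variable.
    blocks_ : list of (name, start, stop)
        Contiguous encoded-column range per variable, in schema order.
    width_ : int
        Total encoded width D.
    """

    def __init__(self, schema: TableSchema):
        self.schema = schema

    def fit(self, data: IncompleteTable) -> "MixedEncoder":
        if data.schema != self.schema:
            raise ValueError("data schema does not match encoder schema")
        self.mins_: dict[str, float] = {}
        self.maxs_: dict[str, float] = {}
        blocks: list[_Block] = []
        pos = 0
        for j, v in enumerate(self.schema):
            obs = data.mask[:, j]
            if v.is_continuous:
                vals = data.values[v.name].to_numpy(float)[obs]
                if len(np.unique(vals)) < 2:
                    raise DegenerateScaleError(
                        f"variable {v.name!r}: degenerate scale "
                        "(fewer than 2 distinct observed values)"
                    )
                self.mins_[v.name] = float(vals.min())
                self.maxs_[v.name] = float(vals.max())
                width = 1
            else:
                if not obs.any():
                    raise ValueError(f"variable {v.name!r}: no observed value")
                width = len(v.categories)
            blocks.append(_Block(v.name, pos, pos + width))
            pos += width
        self.blocks_ = [(b.name, b.start, b.stop) for b in blocks]
        self.width_ = pos
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "width_"):
            raise RuntimeError("encoder is not fitted")

    def encode(self, data: IncompleteTable) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(X, M)``: encoded values and encoded mask, both n x D.

        Missing cells get a 0 placeholder with mask 0; the variable-level
        mask is replicated across each categorical block.
        """
        self._check_fitted()
        n = data.n
        X = np.zeros((n, self.width_))
        M = np.zeros((n, self.width_))
        for j, v in enumerate(self.schema):
            _, start, stop = self.blocks_[j]
            obs = data.mask[:, j]
            M[:, start:stop] = obs[:, None]
            if v.is_continuous:
                lo, hi = self.mins_[v.name], self.maxs_[v.name]
                vals = data.values[v.name].to_numpy(float)
                scaled = np.clip((vals - lo) / (hi - lo), 0.0, 1.0)
                X[obs, start] = scaled[obs]
            else:
                col = data.values[v.name].to_numpy(object)
                index = {c: k for k, c in enumerate(v.categories)}
                for i in np.flatnonzero(obs):
                    try:
                        X[i, start + index[col[i]]] = 1.0
                    except KeyError:
                        raise ValueError(
                            f"row {i}, column {v.name!r}: value {col[i]!r} "
                            "outside schema categories"
                        ) from None
        return X, M

    def decode(self, X: np.ndarray) -> pd.DataFrame:
        """Invert the encoding: continuous rescale, categorical argmax.

        Argmax ties break deterministically toward the lowest category index.
        """
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.width_:
            raise ValueError(f"expected width {self.width_}, got {X.shape[1]}")
        df = pd.DataFrame(index=range(X.shape[0]))
        for j, v in enumerate(self.schema):
            _, start, stop = self.blocks_[j]
            if v.is_continuous:
                lo, hi = self.mins_[v.name], self.maxs_[v.name]
                y = np.clip(X[:, start], 0.0, 1.0)
                df[v.name] = lo + y * (hi - lo)
            else:
                idx = np.argmax(X[:, start:stop], axis=1)  # first max wins
                cats = np.asarray(v.categories, dtype=object)
                df[v.name] = cats[idx]
        return df

    def to_dict(self) -> dict:
        """Serialize the fitted state (schema-independent part) for reuse."""
        self._check_fitted()
        return {
            "mins": dict(self.mins_),
            "maxs": dict(self.maxs_),
            "blocks": [list(b) for b in self.blocks_],
            "width": self.width_,
        }

    @classmethod
    def from_dict(cls, schema: TableSchema, state: dict) -> "MixedEncoder":
        enc = cls(schema)
        enc.mins_ = {k: float(v) for k, v in state["mins"].items()}
        enc.maxs_ = {k: float(v) for k, v in state["maxs"].items()}
        enc.blocks_ = [(str(n), int(a), int(b)) for n, a, b in state["blocks"]]
        enc.width_ = int(state["width"])
        return enc

    def variable_mask(self, M: np.ndarray) -> np.ndarray:
        """Collapse an encoded n x D mask back to the n x d variable level."""
        self._check_fitted()
        cols = [M[:, start] for _, start, _ in self.blocks_]
        return np.column_stack(cols)


def mean_fill(X: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Replace missing encoded entries by their column's observed mean.

    For one-hot blocks this fills the observed class-frequency vector.  The
    modified GAIN feeds this mean-filled matrix to the generator in place of
    random noise.  Idempotent; observed entries are never changed.
    """
    X = np.asarray(X, dtype=float)
    M = np.asarray(M, dtype=float)
    counts = M.sum(axis=0)
    if (counts == 0).any():
        j = int(np.flatnonzero(counts == 0)[0])
        raise ValueError(f"encoded column {j} is fully missing; cannot mean-fill")
    means = (X * M).sum(axis=0) / counts
    return X * M + (1.0 - M) * means
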