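"""Mixed-type table data model: schema, mask, CSV round-trip and validation.

A dataset is an ``n x d`` table whose columns are declared *continuous* or
*categorical* by a schema sidecar, and whose observedness is an ``n x d``
binary mask (1 = observed).  Variables additionally carry a *role*:
``independent`` variables are imputation targets, ``dependent`` variables
(outcomes) are required to be fully observed and drive the missing-at-random
amputation mechanism.

Missing cells are empty fields in CSV and ``NaN`` in memory — a sentinel
distinct from any legal value (categorical values are strings, continuous
values are finite floats).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import yaml

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"
INDEPENDENT = "independent"
DEPENDENT = "dependent"


class SchemaValidationError(ValueError):
    """A table does not conform to its declared schema."""


@dataclass(frozen=True)
class VariableSchema:
    """Declaration of a single variable.

    Parameters
    ----------
    name : str
        Column name, unique within a dataset.
    kind : {"continuous", "categorical"}
    categories : tuple of str, optional
        Ordered category labels; required iff ``kind == "categorical"``.
        The order is significant: it fixes one-hot layout and tie-breaks.
    role : {"independent", "dependent"}
        Independent variables may be amputed/imputed; dependent variables
        are fully observed outcomes.
    """

    name: str
    kind: str
    categories: tuple[str, ...] | None = None
    role: str = INDEPENDENT

    def __post_init__(self) -> None:
        if not self.name:
            raise SchemaValidationError("variable name must be non-empty")
        if self.kind not in (CONTINUOUS, CATEGORICAL):
            raise SchemaValidationError(
                f"variable {self.name!r}: kind must be "
                f"'{CONTINUOUS}' or '{CATEGORICAL}', got {self.kind!r}"
            )
        if self.role not in (INDEPENDENT, DEPENDENT):
            raise SchemaValidationError(
                f"variable {self.name!r}: role must be "
                f"'{INDEPENDENT}' or '{DEPENDENT}', got {self.role!r}"
            )
        if self.kind == CATEGORICAL:
            if not self.categories:
                raise SchemaValidationError(
                    f"categorical variable {self.name!r} needs categories"
                )
            cats = tuple(str(c) for c in self.categories)
            if len(set(cats)) != len(cats):
                raise SchemaValidationError(
                    f"variable {self.name!r}: duplicate categories"
                )
            object.__setattr__(self, "categories", cats)
        elif self.categories is not None:
            raise SchemaValidationError(
                f"continuous variable {self.name!r} must not declare categories"
            )

    @property
    def is_continuous(self) -> bool:
        return self.kind == CONTINUOUS

    @property
    def is_categorical(self) -> bool:
        return self.kind == CATEGORICAL


class TableSchema:
    """Ordered collection of :class:`VariableSchema` with unique names."""

    def __init__(self, variables: Iterable[VariableSchema]):
        self.variables: tuple[VariableSchema, ...] = tuple(variables)
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise SchemaValidationError("duplicate variable names in schema")
        if not names:
            raise SchemaValidationError("schema must declare at least one variable")
        self._by_name = {v.name: v for v in self.variables}

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.variables)

    def __iter__(self) -> Iterator[VariableSchema]:
        return iter(self.variables)

    def __getitem__(self, key: str | int) -> VariableSchema:
        if isinstance(key, str):
            try:
                return self._by_name[key]
            except KeyError:
                raise KeyError(f"unknown variable {key!r}") from None
        return self.variables[key]

    def __contains__(self, name: object) -> bool:
        return name in self._by_name

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TableSchema) and self.variables == other.variables

    def index(self, name: str) -> int:
        return [v.name for v in self.variables].index(name)

    # -- views --------------------------------------------------------------
    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    @property
    def continuous_names(self) -> list[str]:
        return [v.name for v in self.variables if v.is_continuous]

    @property
    def categorical_names(self) -> list[str]:
        return [v.name for v in self.variables if v.is_categorical]

    @property
    def independent_names(self) -> list[str]:
        return [v.name for v in self.variables if v.role == INDEPENDENT]

    @property
    def dependent_names(self) -> list[str]:
        return [v.name for v in self.variables if v.role == DEPENDENT]

    # -- serialization ------------------------------------------------------
    def to_records(self) -> list[dict]:
        recs = []
        for v in self.variables:
            r: dict = {"name": v.name, "kind": v.kind, "role": v.role}
            if v.is_categorical:
                r["categories"] = list(v.categories)
            recs.append(r)
        return recs

    @classmethod
    def from_records(cls, records: Sequence[dict]) -> "TableSchema":
        return cls(
            VariableSchema(
                name=str(r["name"]),
                kind=r["kind"],
                categories=tuple(r["categories"]) if r.get("categories") else None,
                role=r.get("role", INDEPENDENT),
            )
            for r in records
        )

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"variables": self.to_records()}, fh, sort_keys=False)

    @classmethod
    def load(cls, path: str | Path) -> "TableSchema":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict) or "variables" not in doc:
            raise SchemaValidationError(f"{path}: expected a 'variables' list")
        return cls.from_records(doc["variables"])


@dataclass
class IncompleteTable:
    """A mixed-type table together with its observedness mask.

    ``values`` holds continuous columns as float64 and categorical columns as
    object (str); cells with ``mask == False`` carry NaN.  Row order is
    significant and preserved — masks are positional.
    """

    schema: TableSchema
    values: pd.DataFrame
    mask: np.ndarray = field(repr=False)  # n x d bool, True = observed

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise SchemaValidationError(
                f"mask shape {self.mask.shape} != values shape {self.values.shape}"
            )
        if list(self.values.columns) != self.schema.names:
            raise SchemaValidationError("values columns do not match schema order")

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, schema: TableSchema) -> "IncompleteTable":
        """Build from a DataFrame using NaN as the missing sentinel."""
        df = _coerce_types(df, schema)
        mask = ~df.isna().to_numpy()
        out = cls(schema=schema, values=df, mask=mask)
        return out

    @classmethod
    def complete(cls, df: pd.DataFrame, schema: TableSchema) -> "IncompleteTable":
        """Build from a fully observed DataFrame; NaNs are rejected."""
        df = _coerce_types(df, schema)
        if df.isna().to_numpy().any():
            raise SchemaValidationError("complete table contains missing cells")
        return cls(schema=schema, values=df, mask=np.ones(df.shape, dtype=bool))

    # -- basic views --------------------------------------------------------
    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    @property
    def is_complete(self) -> bool:
        return bool(self.mask.all())

    def mask_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.mask.astype(int), columns=self.schema.names, index=self.values.index
        )

    def copy(self) -> "IncompleteTable":
        return IncompleteTable(self.schema, self.values.copy(), self.mask.copy())

    def with_mask(self, mask: np.ndarray) -> "IncompleteTable":
        """Return a copy re-masked by ``mask`` (cells newly hidden become NaN)."""
        mask = np.asarray(mask, dtype=bool)
        df = self.values.copy()
        for j, name in enumerate(self.schema.names):
            hide = ~mask[:, j]
            if hide.any():
                col = df[name].to_numpy(copy=True)
                if self.schema[name].is_continuous:
                    col = col.astype(float)
                else:
                    col = col.astype(object)
                col[hide] = np.nan
                df[name] = col
        return IncompleteTable(self.schema, df, mask & self.mask)


def _coerce_types(df: pd.DataFrame, schema: TableSchema) -> pd.DataFrame:
    unknown = [c for c in df.columns if c not in schema]
    if unknown:
        raise SchemaValidationError(f"unknown column(s) {unknown}")
    missing_cols = [n for n in schema.names if n not in df.columns]
    if missing_cols:
        raise SchemaValidationError(f"column(s) {missing_cols} absent from data")
    df = df[schema.names].copy()
    for v in schema:
        if v.is_continuous:
            df[v.name] = pd.to_numeric(df[v.name], errors="raise").astype(float)
        else:
            col = df[v.name].astype(object)
            col = col.where(~pd.isna(col), np.nan)
            obs = ~pd.isna(col)
            col[obs] = col[obs].astype(str)
            df[v.name] = col
    return df


# ---------------------------------------------------------------------------
# validation


def validate(data: IncompleteTable) -> list[str]:
    """Check every type invariant; return human-readable violations.

    An empty list means the table is valid.  Violations name the row,
    column and rule; they are returned, never raised.
    """
    out: list[str] = []
    schema = data.schema
    for j, v in enumerate(schema):
        col = data.values[v.name].to_numpy()
        obs = data.mask[:, j]
        if v.role == DEPENDENT and not obs.all():
            rows = np.flatnonzero(~obs)[:5].tolist()
            out.append(
                f"column {v.name!r}: dependent variables must be fully observed "
                f"(masked rows {rows}...)"
            )
        if v.is_continuous:
            vals = col.astype(float)
            bad = obs & ~np.isfinite(vals)
            for i in np.flatnonzero(bad)[:20]:
                out.append(
                    f"row {i}, column {v.name!r}: observed continuous cell "
                    f"is not finite ({vals[i]!r})"
                )
        else:
            cats = set(v.categories)
            for i in np.flatnonzero(obs):
                val = col[i]
                if not isinstance(val, str) or val not in cats:
                    out.append(
                        f"row {i}, column {v.name!r}: value {val!r} not in "
                        f"categories {list(v.categories)}"
                    )
        # masked cells must carry the sentinel
        hidden = ~obs
        if hidden.any():
            cells = pd.isna(col[hidden])
            if not cells.all():
                i = np.flatnonzero(hidden)[np.flatnonzero(~cells)[0]]
                out.append(
                    f"row {i}, column {v.name!r}: masked cell carries a value "
                    "instead of the missing sentinel"
                )
    return out


# ---------------------------------------------------------------------------
# CSV I/O


def read_table(path: str | Path, schema_path: str | Path) -> IncompleteTable:
    """Read a data CSV plus schema sidecar; empty cells denote missing."""
    schema = TableSchema.load(schema_path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    unknown = [c for c in raw.columns if c not in schema]
    if unknown:
        raise SchemaValidationError(f"{path}: unknown column(s) {unknown}")
    absent = [n for n in schema.names if n not in raw.columns]
    if absent:
        raise SchemaValidationError(f"{path}: column(s) {absent} absent")
    raw = raw[schema.names]
    n = len(raw)
    df = pd.DataFrame(index=range(n))
    mask = np.ones((n, len(schema)), dtype=bool)
    for j, v in enumerate(schema):
        cells = raw[v.name].to_numpy(dtype=object)
        empty = np.array([c == "" for c in cells])
        mask[:, j] = ~empty
        if v.is_continuous:
            vals = np.full(n, np.nan)
            for i in np.flatnonzero(~empty):
                try:
                    vals[i] = float(cells[i])
                except ValueError:
                    raise SchemaValidationError(
                        f"row {i}, column {v.name!r}: non-numeric continuous "
                        f"cell {cells[i]!r}"
                    ) from None
            df[v.name] = vals
        else:
            cats = set(v.categories)
            vals = np.full(n, np.nan, dtype=object)
            for i in np.flatnonzero(~empty):
                if cells[i] not in cats:
                    raise SchemaValidationError(
                        f"row {i}, column {v.name!r}: value {cells[i]!r} not in "
                        f"categories {list(v.categories)}"
                    )
                vals[i] = cells[i]
            df[v.name] = vals
    return IncompleteTable(schema=schema, values=df, mask=mask)


def write_table(
    data: IncompleteTable,
    path: str | Path,
    schema_path: str | Path | None = None,
    mask_path: str | Path | None = None,
) -> None:
    """Write the data CSV (missing = empty field) and optional sidecars.

    Continuous cells are serialized with ``repr`` so that a re-parse is
    bit-stable; ``read_table(write_table(x))`` reproduces values, mask and
    schema exactly.
    """
    out = pd.DataFrame(index=data.values.index)
    for j, v in enumerate(data.schema):
        col = data.values[v.name].to_numpy(dtype=object)
        obs = data.mask[:, j]
        cells = np.full(len(col), "", dtype=object)
        if v.is_continuous:
            for i in np.flatnonzero(obs):
                cells[i] = repr(float(col[i]))
        else:
            cells[obs] = col[obs]
        out[v.name] = cells
    out.to_csv(path, index=False)
    if schema_path is not None:
        data.schema.save(schema_path)
    if mask_path is not None:
        write_mask(data.mask, data.schema, mask_path)


def write_mask(mask: np.ndarray, schema: TableSchema, path: str | Path) -> None:
    pd.DataFrame(np.asarray(mask, dtype=int), columns=schema.names).to_csv(
        path, index=False
    )


def read_mask(path: str | Path, schema: TableSchema) -> np.ndarray:
    df = pd.read_csv(path)
    if list(df.columns) != schema.names:
        raise SchemaValidationError(f"{path}: mask columns do not match schema")
    arr = df.to_numpy()
    if not np.isin(arr, (0, 1)).all():
        raise SchemaValidationError(f"{path}: mask entries must be 0/1")
    return arr.astype(bool)
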