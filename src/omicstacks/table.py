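"""Typed, rectangular tables — the universal payload for omic layers.

A :class:`TypedTable` is an ordered collection of named, typed columns.
Three column kinds cover the mixed data types found across omic layers:

``integer``
    64-bit signed integers (sample counts, read counts, genomic positions).
``real``
    double-precision floats (metabolite abundances, BMI, quality metrics).
``text``
    variable-length strings (sample ids, feature ids, genotypes).

Nulls (``None``) are allowed in every kind.  Values are validated at
construction time so the storage backends can trust their payloads and
keep appends all-or-nothing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError

KINDS = ("integer", "real", "text")

#: dtypes that map to each kind when converting from pandas
_INT_DTYPES = "iu"
_FLOAT_DTYPES = "f"


@dataclass(frozen=True)
class ColumnSpec:
    """Name, kind and nullability of one column."""

    name: str
    kind: str
    nullable: bool = True

    def __post_init__(self) -> None:
        if not self.name or not isinstance(self.name, str):
            raise SchemaError("column name must be a non-empty string")
        if '"' in self.name or "\x00" in self.name:
            raise SchemaError(f"column name contains forbidden character: {self.name!r}")
        if self.kind not in KINDS:
            raise SchemaError(f"unknown column kind {self.kind!r}; expected one of {KINDS}")


@dataclass(frozen=True)
class TableSchema:
    """Ordered list of column specs; names unique after case-folding."""

    columns: tuple[ColumnSpec, ...]

    def __init__(self, columns: Iterable[ColumnSpec]):
        cols = tuple(columns)
        seen: set[str] = set()
        for c in cols:
            folded = c.name.casefold()
            if folded in seen:
                raise SchemaError(f"duplicate column name (case-insensitive): {c.name!r}")
            seen.add(folded)
        object.__setattr__(self, "columns", cols)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.columns]

    @property
    def kinds(self) -> list[str]:
        return [c.kind for c in self.columns]

    def __len__(self) -> int:
        return len(self.columns)

    def __getitem__(self, name: str) -> ColumnSpec:
        for c in self.columns:
            if c.name == name:
                return c
        raise KeyError(name)


def _check_value(value: Any, kind: str) -> Any:
    """Validate/coerce one cell; returns the canonical Python value."""
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    if kind == "integer":
        if isinstance(value, bool):
            raise SchemaError(f"boolean {value!r} is not an integer value")
        if isinstance(value, (int, np.integer)):
            return int(value)
        if isinstance(value, (float, np.floating)) and float(value).is_integer():
            return int(value)
        raise SchemaError(f"value {value!r} does not conform to kind 'integer'")
    if kind == "real":
        if isinstance(value, bool):
            raise SchemaError(f"boolean {value!r} is not a real value")
        if isinstance(value, (int, float, np.integer, np.floating)):
            return float(value)
        raise SchemaError(f"value {value!r} does not conform to kind 'real'")
    # text
    if isinstance(value, str):
        return value
    raise SchemaError(f"value {value!r} does not conform to kind 'text'")


@dataclass
class TypedTable:
    """Rectangular collection of typed columns.

    Parameters
    ----------
    schema:
        Column names, kinds and nullability, in order.
    columns:
        Mapping of column name to value sequence.  All sequences must have
        equal length and every value must conform to its column kind (or be
        null).
    """

    schema: TableSchema
    _data: dict[str, list] = field(repr=False)

    def __init__(self, schema: TableSchema, columns: Mapping[str, Sequence]):
        extra = set(columns) - set(schema.names)
        missing = set(schema.names) - set(columns)
        if extra or missing:
            raise SchemaError(
                f"columns do not match schema (missing={sorted(missing)}, extra={sorted(extra)})"
            )
        data: dict[str, list] = {}
        n_rows: int | None = None
        for spec in schema.columns:
            values = [_check_value(v, spec.kind) for v in columns[spec.name]]
            if n_rows is None:
                n_rows = len(values)
            elif len(values) != n_rows:
                raise SchemaError(
                    f"column {spec.name!r} has {len(values)} values, expected {n_rows}"
                )
            data[spec.name] = values
        self.schema = schema
        self._data = data

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_columns(cls, items: Sequence[tuple[str, str, Sequence]]) -> "TypedTable":
        """Build from ``(name, kind, values)`` triples."""
        schema = TableSchema(ColumnSpec(name, kind) for name, kind, _ in items)
        return cls(schema, {name: values for name, _, values in items})

    @classmethod
    def from_pandas(cls, df: pd.DataFrame) -> "TypedTable":
        """Infer kinds from dtypes: integer dtypes map to ``integer``, float
        dtypes to ``real``, everything else to ``text``.  NaN/NA become null.
        """
        specs: list[ColumnSpec] = []
        data: dict[str, list] = {}
        for name in df.columns:
            series = df[name]
            if series.dtype.kind in _INT_DTYPES or str(series.dtype).startswith(("Int", "UInt")):
                kind = "integer"
            elif series.dtype.kind in _FLOAT_DTYPES or str(series.dtype).startswith("Float"):
                kind = "real"
            else:
                kind = "text"
            specs.append(ColumnSpec(str(name), kind))
            values = [None if pd.isna(v) else v for v in series.tolist()]
            data[str(name)] = values
        return cls(TableSchema(specs), data)

    def to_pandas(self) -> pd.DataFrame:
        """Integer columns without nulls become int64, with nulls Int64;
        real columns float64; text columns object."""
        out = {}
        for spec in self.schema.columns:
            values = self._data[spec.name]
            if spec.kind == "integer":
                dtype = "Int64" if any(v is None for v in values) else "int64"
                out[spec.name] = pd.array(values, dtype=dtype)
            elif spec.kind == "real":
                out[spec.name] = pd.array(
                    [np.nan if v is None else v for v in values], dtype="float64"
                )
            else:
                out[spec.name] = pd.array(values, dtype="object")
        return pd.DataFrame(out, columns=self.schema.names)

    # -- accessors ------------------------------------------------------------

    @property
    def n_rows(self) -> int:
        if not self.schema.columns:
            return 0
        return len(self._data[self.schema.columns[0].name])

    @property
    def n_columns(self) -> int:
        return len(self.schema.columns)

    def column(self, name: str) -> list:
        if name not in self._data:
            raise KeyError(name)
        return list(self._data[name])

    def rows(self) -> list[tuple]:
        names = self.schema.names
        return list(zip(*(self._data[n] for n in names))) if names else []

    def select(self, names: Sequence[str]) -> "TypedTable":
        """Projection preserving row order; requested column order respected."""
        specs = []
        for n in names:
            try:
                specs.append(self.schema[n])
            except KeyError:
                raise NotFoundErrorFor(n)
        schema = TableSchema(specs)
        return TypedTable(schema, {n: self._data[n] for n in names})

    def filter_rows(self, keep: Sequence[bool]) -> "TypedTable":
        return TypedTable(
            self.schema,
            {n: [v for v, k in zip(self._data[n], keep) if k] for n in self.schema.names},
        )

    def slice_rows(self, start: int, stop: int) -> "TypedTable":
        return TypedTable(
            self.schema, {n: self._data[n][start:stop] for n in self.schema.names}
        )

    def concat(self, other: "TypedTable") -> "TypedTable":
        if self.schema.names != other.schema.names or self.schema.kinds != other.schema.kinds:
            raise SchemaError("cannot concatenate tables with different schemas")
        return TypedTable(
            self.schema,
            {n: self._data[n] + other._data[n] for n in self.schema.names},
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TypedTable):
            return NotImplemented
        return (
            self.schema.names == other.schema.names
            and self.schema.kinds == other.schema.kinds
            and self._data == other._data
        )

    def __repr__(self) -> str:
        return f"TypedTable({self.n_rows} rows x {self.n_columns} columns)"


def NotFoundErrorFor(name: str):
    from .errors import NotFoundError

    return NotFoundError(f"column not found: {name!r}")


def as_typed_table(data) -> TypedTable:
    """Accept a TypedTable or a pandas DataFrame."""
    if isinstance(data, TypedTable):
        return data
    if isinstance(data, pd.DataFrame):
        return TypedTable.from_pandas(data)
    raise TypeError(f"expected TypedTable or DataFrame, got {type(data).__name__}")
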