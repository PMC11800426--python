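"""Stack-level and layer-level operations over one single-file store.

A *stack* is the collection of all omic layers stored in one database file
plus their metadata catalogue.  Stack-level operations act across layers
(create, drop, tag queries, joins); layer-level operations act within one
layer (load, select, extend, annotate).

Every layer carries a :class:`LayerMetadata` record (name, free-form tag,
free-form description) in a reserved metadata table inside the same file,
so a stack stays a single portable artifact.  Tags group layers: tagging
both metabolite layers ``"metabolomics"`` lets ``layers_with_tag`` retrieve
them together.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .backend import DEFAULT_ENGINE, StoreBackend, detect_engine, open_store
from .errors import DuplicateError, JoinError, NotFoundError, SchemaError
from .table import TableSchema, TypedTable, as_typed_table


@dataclass(frozen=True)
class LayerMetadata:
    """Catalogue record for one layer."""

    name: str
    tag: str = ""
    description: str = ""


@dataclass(frozen=True)
class LayerInfo:
    """Schema, row count and annotation of a layer, without its values."""

    schema: TableSchema
    n_rows: int
    metadata: LayerMetadata


class Stack:
    """All layers stored in one single-file database, plus their catalogue.

    Parameters
    ----------
    path:
        Database file; created if absent.
    engine:
        ``"rowstore"`` or ``"columnstore"``.  When omitted, an existing
        file's recorded engine is reused and new files default to the
        column-oriented engine.
    """

    def __init__(self, path: str | Path, engine: str | None = None):
        if engine is None:
            engine = detect_engine(path) or DEFAULT_ENGINE
        self.handle: StoreBackend = open_store(path, engine)

    @property
    def path(self) -> str:
        return self.handle.path

    @property
    def engine(self) -> str:
        return self.handle.engine

    def close(self) -> None:
        self.handle.close()

    def __enter__(self) -> "Stack":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def __repr__(self) -> str:
        return f"Stack({self.path!r}, engine={self.engine!r}, layers={self.layers()})"

    # -- stack-level operations ------------------------------------------------

    def layers(self) -> list[str]:
        return self.handle.list_tables()

    def store_layer(self, name: str, data, if_exists: str = "fail") -> None:
        """Create a layer from a TypedTable or DataFrame, all-or-nothing.

        The table, its rows and its (empty) metadata record are written in
        one transaction.
        """
        table = as_typed_table(data)
        if name in self.layers():
            if if_exists == "fail":
                raise DuplicateError(f"layer already exists: {name!r}")
        with self.handle.transaction():
            self.handle.create_table(name, table.schema, if_exists=if_exists)
            self.handle.append_rows(name, table)
            self.handle.meta_upsert(name, tag="", description="")

    def drop_layer(self, name: str) -> None:
        """Remove table and metadata record atomically."""
        self._require_layer(name)
        with self.handle.transaction():
            self.handle.drop_table(name)
            self.handle.meta_delete(name)

    def annotate_layer(
        self, name: str, tag: str | None = None, description: str | None = None
    ) -> None:
        """Update only the provided metadata fields; idempotent."""
        self._require_layer(name)
        self.handle.meta_upsert(name, tag=tag, description=description)

    def layers_with_tag(self, tag: str) -> list[str]:
        """Names of all layers annotated with exactly this tag, sorted."""
        return sorted(name for name, t, _d in self.handle.meta_all() if t == tag)

    def catalogue(self) -> list[LayerMetadata]:
        return [LayerMetadata(n, t, d) for n, t, d in self.handle.meta_all()]

    def join_layers(self, names: Sequence[str], on: str) -> TypedTable:
        """Inner equi-join of ≥2 layers on a shared column, left-to-right.

        The join column appears once; duplicate non-key column names from a
        right layer are suffixed ``__<layer>``.  Row order follows the
        leftmost layer's stored order.
        """
        if len(names) < 2:
            raise JoinError("join requires at least two layers")
        frames = []
        for name in names:
            self._require_layer(name)
            table = self.load_layer(name)
            if on not in table.schema.names:
                raise JoinError(f"layer {name!r} has no column {on!r}")
            frames.append((name, table.to_pandas()))
        _, merged = frames[0]
        for name, right in frames[1:]:
            clash = (set(merged.columns) & set(right.columns)) - {on}
            right = right.rename(columns={c: f"{c}__{name}" for c in clash})
            merged = merged.merge(right, on=on, how="inner", sort=False)
        return TypedTable.from_pandas(merged)

    # -- layer-level operations --------------------------------------------------

    def load_layer(self, name: str) -> TypedTable:
        self._require_layer(name)
        return self.handle.read_table(name)

    def load_column(self, name: str, columns: str | Sequence[str]) -> TypedTable:
        self._require_layer(name)
        if isinstance(columns, str):
            columns = [columns]
        return self.handle.read_columns(name, columns)

    def select_rows(self, name: str, column: str, values: Iterable) -> TypedTable:
        self._require_layer(name)
        return self.handle.read_where(name, column, values)

    def layer_info(self, name: str) -> LayerInfo:
        self._require_layer(name)
        schema, n = self.handle.table_schema(name)
        meta = self.handle.meta_get(name) or ("", "")
        return LayerInfo(schema, n, LayerMetadata(name, meta[0], meta[1]))

    def extend_layer_rows(self, name: str, data) -> None:
        """Append rows; columns are aligned by NAME (order-insensitive)."""
        self._require_layer(name)
        table = as_typed_table(data)
        stored, _ = self.handle.table_schema(name)
        if sorted(table.schema.names) != sorted(stored.names):
            raise SchemaError(
                f"row extension columns {table.schema.names} do not match "
                f"layer {name!r} columns {stored.names}"
            )
        if table.schema.names != stored.names:
            table = table.select(stored.names)
        self.handle.append_rows(name, table)

    def extend_layer_columns(self, name: str, data) -> None:
        """Add columns; alignment is POSITIONAL with strict length equality."""
        self._require_layer(name)
        self.handle.add_columns(name, as_typed_table(data))

    # -- helpers -----------------------------------------------------------------

    def _require_layer(self, name: str) -> None:
        if name not in self.layers():
            raise NotFoundError(f"layer not found: {name!r}")


def create_stack(path: str | Path, engine: str | None = None) -> Stack:
    """Open or create a stack; the column-oriented engine is the default."""
    return Stack(path, engine)


def export_layer_csv(stack: Stack, name: str, out_path: str | Path) -> None:
    """Write a layer as UTF-8 CSV with a header row."""
    stack.load_layer(name).to_pandas().to_csv(out_path, index=False)


def import_layer_csv(
    stack: Stack, name: str, csv_path: str | Path, if_exists: str = "fail"
) -> None:
    """Store a CSV file (header row required) as a layer."""
    df = pd.read_csv(csv_path)
    stack.store_layer(name, df, if_exists=if_exists)
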