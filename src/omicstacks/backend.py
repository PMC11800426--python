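"""Engine-agnostic storage contract with two concrete single-file engines.

Two physical layouts are provided behind one contract:

``rowstore``
    A row-oriented layout: each logical table is one SQL table, rows stored
    contiguously.  Favors per-row transactions and small frequent writes.

``columnstore``
    A column-oriented layout built on the same embedded storage engine:
    each logical column lives in its own single-column physical table, and
    rows are aligned positionally across column tables by insertion-order
    rowid.  Favors whole-column scans and column-wise extension, the access
    pattern of feature-as-rows omic layers.

Both engines keep an entire stack in exactly one database file, honor ACID
appends (one transaction per ``append_rows`` call), and guarantee stable
insertion order via the monotone rowid each physical table maintains.
Reserved internal tables (``_store_info``, ``_layers_meta`` and the
columnstore catalog) are hidden from ``list_tables`` and their names are
rejected for user tables.
"""

from __future__ import annotations

import logging
import sqlite3
from abc import ABC, abstractmethod
from contextlib import contextmanager
from pathlib import Path
from typing import Iterable, Sequence

from .errors import (
    AlignmentError,
    AppendError,
    ConfigurationError,
    DuplicateError,
    NotFoundError,
    QueryError,
    SchemaError,
    StorageError,
)
from .table import KINDS, ColumnSpec, TableSchema, TypedTable, _check_value

logger = logging.getLogger(__name__)

ENGINES = ("rowstore", "columnstore")
DEFAULT_ENGINE = "columnstore"

_KIND_TO_SQL = {"integer": "INTEGER", "real": "REAL", "text": "TEXT"}
_SQL_TO_KIND = {v: k for k, v in _KIND_TO_SQL.items()}

#: names (and the leading underscore prefix) reserved for internal tables
RESERVED_PREFIX = "_"
_META_TABLE = "_layers_meta"
_INFO_TABLE = "_store_info"


def _quote(identifier: str) -> str:
    return '"' + identifier.replace('"', '""') + '"'


def _validate_table_name(name: str) -> None:
    if not name or not isinstance(name, str):
        raise SchemaError("table name must be a non-empty string")
    if '"' in name or "\x00" in name:
        raise SchemaError(f"table name contains forbidden character: {name!r}")
    if name.startswith(RESERVED_PREFIX):
        raise SchemaError(
            f"table name {name!r} collides with the reserved internal prefix {RESERVED_PREFIX!r}"
        )
    if name.lower().startswith("sqlite_"):
        raise SchemaError(f"table name {name!r} is reserved by the storage engine")


class StoreBackend(ABC):
    """One open connection to one single-file store.

    Also serves as the ``StoreHandle``: it carries ``path`` and ``engine``
    and all data for a stack lives in that single file.
    """

    engine: str

    def __init__(self, path: str | Path):
        self.path = str(path)
        parent = Path(self.path).resolve().parent
        if not parent.is_dir():
            raise StorageError(f"parent directory does not exist: {parent}")
        try:
            self._conn = sqlite3.connect(self.path, isolation_level=None, check_same_thread=False)
            self._conn.execute("PRAGMA foreign_keys=ON")
            self._conn.execute("PRAGMA busy_timeout=30000")
            # write-ahead logging: committed transactions survive process
            # crashes, readers never block behind the single writer, and
            # small frequent commits avoid a full fsync each
            self._conn.execute("PRAGMA journal_mode=WAL")
            self._conn.execute("PRAGMA synchronous=NORMAL")
        except sqlite3.Error as exc:  # pragma: no cover - rare I/O failure
            raise StorageError(f"cannot open store at {self.path}: {exc}") from exc
        self._txn_depth = 0
        try:
            self._init_file()
        except sqlite3.DatabaseError as exc:
            self._conn.close()
            raise StorageError(f"file is not a valid store: {self.path} ({exc})") from exc

    # -- lifecycle ------------------------------------------------------------

    def _init_file(self) -> None:
        with self.transaction():
            self._conn.execute(
                f"CREATE TABLE IF NOT EXISTS {_INFO_TABLE} (key TEXT PRIMARY KEY, value TEXT)"
            )
            row = self._conn.execute(
                f"SELECT value FROM {_INFO_TABLE} WHERE key='engine'"
            ).fetchone()
            if row is None:
                self._conn.execute(
                    f"INSERT INTO {_INFO_TABLE} (key, value) VALUES ('engine', ?)",
                    (self.engine,),
                )
            elif row[0] != self.engine:
                raise ConfigurationError(
                    f"store {self.path} was created with engine {row[0]!r}, "
                    f"cannot open as {self.engine!r}"
                )
            self._conn.execute(
                f"CREATE TABLE IF NOT EXISTS {_META_TABLE} "
                "(name TEXT PRIMARY KEY, tag TEXT NOT NULL DEFAULT '', "
                "description TEXT NOT NULL DEFAULT '')"
            )
            self._create_engine_tables()

    def _create_engine_tables(self) -> None:
        """Engine-specific catalog tables; default none."""

    def close(self) -> None:
        self._conn.close()

    def __enter__(self) -> "StoreBackend":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    @contextmanager
    def transaction(self):
        """Nestable write transaction; the outermost level commits.

        One ``append_rows`` call is exactly one transaction, so chunked
        ingestion commits per chunk.
        """
        if self._txn_depth > 0:
            self._txn_depth += 1
            try:
                yield
            finally:
                self._txn_depth -= 1
            return
        self._conn.execute("BEGIN IMMEDIATE")
        self._txn_depth = 1
        try:
            yield
        except BaseException:
            self._conn.execute("ROLLBACK")
            logger.debug("transaction rolled back on %s", self.path)
            raise
        finally:
            self._txn_depth = 0
        self._conn.execute("COMMIT")
        logger.debug("transaction committed on %s", self.path)

    # -- metadata catalogue (shared by both engines) --------------------------

    def meta_upsert(self, name: str, tag: str | None = None, description: str | None = None) -> None:
        with self.transaction():
            self._conn.execute(
                f"INSERT INTO {_META_TABLE} (name) VALUES (?) ON CONFLICT(name) DO NOTHING",
                (name,),
            )
            if tag is not None:
                self._conn.execute(
                    f"UPDATE {_META_TABLE} SET tag=? WHERE name=?", (tag, name)
                )
            if description is not None:
                self._conn.execute(
                    f"UPDATE {_META_TABLE} SET description=? WHERE name=?",
                    (description, name),
                )

    def meta_get(self, name: str) -> tuple[str, str] | None:
        row = self._conn.execute(
            f"SELECT tag, description FROM {_META_TABLE} WHERE name=?", (name,)
        ).fetchone()
        return None if row is None else (row[0], row[1])

    def meta_delete(self, name: str) -> None:
        with self.transaction():
            self._conn.execute(f"DELETE FROM {_META_TABLE} WHERE name=?", (name,))

    def meta_all(self) -> list[tuple[str, str, str]]:
        return list(
            self._conn.execute(
                f"SELECT name, tag, description FROM {_META_TABLE} ORDER BY name"
            )
        )

    # -- storage contract ------------------------------------------------------

    def create_table(self, name: str, schema: TableSchema, if_exists: str = "fail") -> None:
        _validate_table_name(name)
        if if_exists not in ("fail", "replace"):
            raise ConfigurationError(f"if_exists must be 'fail' or 'replace', got {if_exists!r}")
        if len(schema) < 1:
            raise SchemaError("a stored table needs at least one column")
        for spec in schema.columns:
            if spec.name.startswith(RESERVED_PREFIX):
                raise SchemaError(f"column name {spec.name!r} uses the reserved prefix")
        exists = name in self.list_tables()
        if exists and if_exists == "fail":
            raise DuplicateError(f"table already exists: {name!r}")
        with self.transaction():
            if exists:
                self._drop_impl(name)
            self._create_impl(name, schema)

    def append_rows(self, name: str, data: TypedTable) -> int:
        stored, _ = self.table_schema(name)
        if stored.names != data.schema.names or stored.kinds != data.schema.kinds:
            raise AppendError(
                f"schema mismatch appending to {name!r}: stored "
                f"{list(zip(stored.names, stored.kinds))}, got "
                f"{list(zip(data.schema.names, data.schema.kinds))}"
            )
        if data.n_rows == 0:
            return 0
        with self.transaction():
            self._append_impl(name, data)
        return data.n_rows

    def add_columns(self, name: str, data: TypedTable) -> None:
        stored, n_rows = self.table_schema(name)
        if data.n_columns == 0:
            return
        if data.n_rows != n_rows:
            raise AlignmentError(
                f"new columns have {data.n_rows} rows but table {name!r} has {n_rows}"
            )
        existing = {c.casefold() for c in stored.names}
        for spec in data.schema.columns:
            if spec.name.casefold() in existing:
                raise SchemaError(f"column already exists in {name!r}: {spec.name!r}")
            if spec.name.startswith(RESERVED_PREFIX):
                raise SchemaError(f"column name {spec.name!r} uses the reserved prefix")
        with self.transaction():
            self._add_columns_impl(name, data)

    def read_table(self, name: str) -> TypedTable:
        schema, _ = self.table_schema(name)
        return self.read_columns(name, schema.names)

    @abstractmethod
    def read_columns(self, name: str, columns: Sequence[str]) -> TypedTable:
        """Projection preserving row order; requested column order respected."""

    def read_where(self, name: str, column: str, values: Iterable) -> TypedTable:
        schema, _ = self.table_schema(name)
        if column not in schema.names:
            raise NotFoundError(f"column not found in {name!r}: {column!r}")
        values = list(values)
        if not values:
            raise QueryError("value set for read_where must be non-empty")
        kind = schema[column].kind
        try:
            checked = [_check_value(v, kind) for v in values]
        except SchemaError as exc:
            raise QueryError(f"value set is not kind-compatible with {column!r}: {exc}") from exc
        if any(v is None for v in checked):
            raise QueryError("null is not a valid membership value")
        return self._read_where_impl(name, schema, column, checked)

    def drop_table(self, name: str) -> None:
        if name not in self.list_tables():
            return
        with self.transaction():
            self._drop_impl(name)

    @abstractmethod
    def list_tables(self) -> list[str]:
        """User tables only; reserved internal tables are hidden."""

    @abstractmethod
    def table_schema(self, name: str) -> tuple[TableSchema, int]:
        """Schema (names, kinds, in order) and current row count."""

    # -- engine-specific primitives -------------------------------------------

    @abstractmethod
    def _create_impl(self, name: str, schema: TableSchema) -> None: ...

    @abstractmethod
    def _append_impl(self, name: str, data: TypedTable) -> None: ...

    @abstractmethod
    def _add_columns_impl(self, name: str, data: TypedTable) -> None: ...

    @abstractmethod
    def _read_where_impl(
        self, name: str, schema: TableSchema, column: str, values: list
    ) -> TypedTable: ...

    @abstractmethod
    def _drop_impl(self, name: str) -> None: ...

    # -- shared helpers --------------------------------------------------------

    def _require_table(self, name: str) -> None:
        if name not in self.list_tables():
            raise NotFoundError(f"table not found: {name!r}")

    def _membership_temp(self, values: list) -> str:
        """Load membership values into a temp table; avoids parameter limits."""
        self._conn.execute("DROP TABLE IF EXISTS temp._member_vals")
        self._conn.execute("CREATE TEMP TABLE _member_vals (v)")
        self._conn.executemany("INSERT INTO temp._member_vals VALUES (?)", [(v,) for v in values])
        return "temp._member_vals"


class RowStoreBackend(StoreBackend):
    """Row-oriented layout: one SQL table per logical table."""

    engine = "rowstore"

    def _create_impl(self, name: str, schema: TableSchema) -> None:
        cols = ", ".join(f"{_quote(c.name)} {_KIND_TO_SQL[c.kind]}" for c in schema.columns)
        self._conn.execute(f"CREATE TABLE {_quote(name)} ({cols})")

    def _append_impl(self, name: str, data: TypedTable) -> None:
        names = data.schema.names
        placeholders = ", ".join("?" for _ in names)
        collist = ", ".join(_quote(n) for n in names)
        self._conn.executemany(
            f"INSERT INTO {_quote(name)} ({collist}) VALUES ({placeholders})",
            data.rows(),
        )

    def _add_columns_impl(self, name: str, data: TypedTable) -> None:
        rowids = [r[0] for r in self._conn.execute(
            f"SELECT rowid FROM {_quote(name)} ORDER BY rowid"
        )]
        for spec in data.schema.columns:
            self._conn.execute(
                f"ALTER TABLE {_quote(name)} ADD COLUMN {_quote(spec.name)} {_KIND_TO_SQL[spec.kind]}"
            )
            self._conn.executemany(
                f"UPDATE {_quote(name)} SET {_quote(spec.name)}=? WHERE rowid=?",
                zip(data.column(spec.name), rowids),
            )

    def read_columns(self, name: str, columns: Sequence[str]) -> TypedTable:
        schema, _ = self.table_schema(name)
        specs = []
        for c in columns:
            if c not in schema.names:
                raise NotFoundError(f"column not found in {name!r}: {c!r}")
            specs.append(schema[c])
        collist = ", ".join(_quote(c) for c in columns)
        rows = self._conn.execute(
            f"SELECT {collist} FROM {_quote(name)} ORDER BY rowid"
        ).fetchall()
        out_schema = TableSchema(specs)
        data = {c: [r[i] for r in rows] for i, c in enumerate(columns)}
        return TypedTable(out_schema, data)

    def _read_where_impl(self, name, schema, column, values):
        temp = self._membership_temp(values)
        collist = ", ".join(_quote(c) for c in schema.names)
        rows = self._conn.execute(
            f"SELECT {collist} FROM {_quote(name)} "
            f"WHERE {_quote(column)} IN (SELECT v FROM {temp}) ORDER BY rowid"
        ).fetchall()
        data = {c: [r[i] for r in rows] for i, c in enumerate(schema.names)}
        return TypedTable(schema, data)

    def _drop_impl(self, name: str) -> None:
        self._conn.execute(f"DROP TABLE IF EXISTS {_quote(name)}")

    def list_tables(self) -> list[str]:
        rows = self._conn.execute(
            "SELECT name FROM sqlite_master WHERE type='table' ORDER BY name"
        ).fetchall()
        return [
            r[0]
            for r in rows
            if not r[0].startswith(RESERVED_PREFIX) and not r[0].lower().startswith("sqlite_")
        ]

    def table_schema(self, name: str) -> tuple[TableSchema, int]:
        self._require_table(name)
        info = self._conn.execute(f"PRAGMA table_info({_quote(name)})").fetchall()
        specs = [ColumnSpec(r[1], _SQL_TO_KIND.get(r[2].upper(), "text")) for r in info]
        n = self._conn.execute(f"SELECT COUNT(*) FROM {_quote(name)}").fetchone()[0]
        return TableSchema(specs), n


class ColumnStoreBackend(StoreBackend):
    """Column-oriented layout: one single-column physical table per column.

    Rows align across column tables by insertion-order rowid: all inserts
    append the same number of values to every column table inside one
    transaction, and rows are never deleted individually, so the i-th rowid
    of every column table addresses the same logical row.
    """

    engine = "columnstore"

    def _create_engine_tables(self) -> None:
        self._conn.execute(
            "CREATE TABLE IF NOT EXISTS _tables "
            "(tid INTEGER PRIMARY KEY AUTOINCREMENT, name TEXT UNIQUE NOT NULL)"
        )
        self._conn.execute(
            "CREATE TABLE IF NOT EXISTS _columns "
            "(tid INTEGER NOT NULL, cid INTEGER NOT NULL, name TEXT NOT NULL, "
            "kind TEXT NOT NULL, pos INTEGER NOT NULL, PRIMARY KEY (tid, cid))"
        )

    # catalog helpers

    def _tid(self, name: str) -> int:
        row = self._conn.execute("SELECT tid FROM _tables WHERE name=?", (name,)).fetchone()
        if row is None:
            raise NotFoundError(f"table not found: {name!r}")
        return row[0]

    def _cols(self, tid: int) -> list[tuple[int, str, str]]:
        return list(
            self._conn.execute(
                "SELECT cid, name, kind FROM _columns WHERE tid=? ORDER BY pos", (tid,)
            )
        )

    @staticmethod
    def _phys(tid: int, cid: int) -> str:
        return f"_c{tid}_{cid}"

    def _create_impl(self, name: str, schema: TableSchema) -> None:
        cur = self._conn.execute("INSERT INTO _tables (name) VALUES (?)", (name,))
        tid = cur.lastrowid
        for pos, spec in enumerate(schema.columns):
            self._conn.execute(
                "INSERT INTO _columns (tid, cid, name, kind, pos) VALUES (?,?,?,?,?)",
                (tid, pos, spec.name, spec.kind, pos),
            )
            self._conn.execute(
                f"CREATE TABLE {self._phys(tid, pos)} (v {_KIND_TO_SQL[spec.kind]})"
            )

    def _append_impl(self, name: str, data: TypedTable) -> None:
        tid = self._tid(name)
        for (cid, cname, _kind) in self._cols(tid):
            self._conn.executemany(
                f"INSERT INTO {self._phys(tid, cid)} (v) VALUES (?)",
                [(v,) for v in data.column(cname)],
            )

    def _add_columns_impl(self, name: str, data: TypedTable) -> None:
        tid = self._tid(name)
        existing = self._cols(tid)
        next_cid = max((c[0] for c in existing), default=-1) + 1
        next_pos = len(existing)
        for spec in data.schema.columns:
            self._conn.execute(
                "INSERT INTO _columns (tid, cid, name, kind, pos) VALUES (?,?,?,?,?)",
                (tid, next_cid, spec.name, spec.kind, next_pos),
            )
            self._conn.execute(
                f"CREATE TABLE {self._phys(tid, next_cid)} (v {_KIND_TO_SQL[spec.kind]})"
            )
            self._conn.executemany(
                f"INSERT INTO {self._phys(tid, next_cid)} (v) VALUES (?)",
                [(v,) for v in data.column(spec.name)],
            )
            next_cid += 1
            next_pos += 1

    def read_columns(self, name: str, columns: Sequence[str]) -> TypedTable:
        tid = self._tid(name)
        bycol = {cname: (cid, kind) for cid, cname, kind in self._cols(tid)}
        specs, data = [], {}
        for c in columns:
            if c not in bycol:
                raise NotFoundError(f"column not found in {name!r}: {c!r}")
            cid, kind = bycol[c]
            specs.append(ColumnSpec(c, kind))
            data[c] = [
                r[0]
                for r in self._conn.execute(
                    f"SELECT v FROM {self._phys(tid, cid)} ORDER BY rowid"
                )
            ]
        return TypedTable(TableSchema(specs), data)

    def _read_where_impl(self, name, schema, column, values):
        tid = self._tid(name)
        bycol = {cname: (cid, kind) for cid, cname, kind in self._cols(tid)}
        fcid, _ = bycol[column]
        temp = self._membership_temp(values)
        self._conn.execute("DROP TABLE IF EXISTS temp._member_rids")
        self._conn.execute(
            "CREATE TEMP TABLE _member_rids AS "
            f"SELECT rowid AS r FROM {self._phys(tid, fcid)} "
            f"WHERE v IN (SELECT v FROM {temp}) ORDER BY r"
        )
        data = {}
        for c in schema.names:
            cid, _kind = bycol[c]
            data[c] = [
                r[0]
                for r in self._conn.execute(
                    f"SELECT v FROM {self._phys(tid, cid)} "
                    "WHERE rowid IN (SELECT r FROM temp._member_rids) ORDER BY rowid"
                )
            ]
        return TypedTable(schema, data)

    def _drop_impl(self, name: str) -> None:
        tid = self._tid(name)
        for (cid, _cname, _kind) in self._cols(tid):
            self._conn.execute(f"DROP TABLE IF EXISTS {self._phys(tid, cid)}")
        self._conn.execute("DELETE FROM _columns WHERE tid=?", (tid,))
        self._conn.execute("DELETE FROM _tables WHERE tid=?", (tid,))

    def list_tables(self) -> list[str]:
        return [r[0] for r in self._conn.execute("SELECT name FROM _tables ORDER BY name")]

    def table_schema(self, name: str) -> tuple[TableSchema, int]:
        tid = self._tid(name)
        cols = self._cols(tid)
        specs = [ColumnSpec(cname, kind) for _cid, cname, kind in cols]
        if cols:
            n = self._conn.execute(
                f"SELECT COUNT(*) FROM {self._phys(tid, cols[0][0])}"
            ).fetchone()[0]
        else:  # pragma: no cover - tables always have >=1 column
            n = 0
        return TableSchema(specs), n


_BACKENDS = {"rowstore": RowStoreBackend, "columnstore": ColumnStoreBackend}


def open_store(path: str | Path, engine: str = DEFAULT_ENGINE) -> StoreBackend:
    """Open (creating if absent) a single-file store with the given engine.

    Opening an existing file with a different engine than it was created
    with is a configuration error; the stored engine marker is checked.
    """
    if engine not in _BACKENDS:
        raise ConfigurationError(f"unknown engine {engine!r}; expected one of {ENGINES}")
    return _BACKENDS[engine](path)


def detect_engine(path: str | Path) -> str | None:
    """Engine id recorded in an existing store file, or None if absent/new."""
    p = Path(path)
    if not p.exists() or p.stat().st_size == 0:
        return None
    try:
        conn = sqlite3.connect(str(p))
        try:
            row = conn.execute(
                f"SELECT value FROM {_INFO_TABLE} WHERE key='engine'"
            ).fetchone()
        finally:
            conn.close()
    except sqlite3.Error as exc:
        raise StorageError(f"file is not a valid store: {path} ({exc})") from exc
    return None if row is None else row[0]
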