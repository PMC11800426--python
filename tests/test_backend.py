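"""Storage-contract tests, run identically against both engines."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omicstacks.backend import open_store
from omicstacks.errors import (
    AlignmentError,
    AppendError,
    ConfigurationError,
    DuplicateError,
    NotFoundError,
    QueryError,
    SchemaError,
)
from omicstacks.table import ColumnSpec, TableSchema, TypedTable

from conftest import ENGINES, random_table


def _demo_table(n=5):
    return TypedTable.from_columns([
        ("sample_id", "text", [f"S{i}" for i in range(n)]),
        ("age", "integer", list(range(20, 20 + n))),
        ("bmi", "real", [20.0 + 0.5 * i for i in range(n)]),
    ])


class TestOpenStore:
    def test_unknown_engine_rejected(self, tmp_path):
        with pytest.raises(ConfigurationError):
            open_store(tmp_path / "x.db", "graphstore")

    def test_missing_parent_directory(self, tmp_path):
        from omicstacks.errors import StorageError
        with pytest.raises(StorageError):
            open_store(tmp_path / "nope" / "x.db", "rowstore")

    def test_persistence_across_reopen(self, tmp_path, engine):
        path = tmp_path / "p.db"
        with open_store(path, engine) as h:
            h.create_table("cohort", _demo_table().schema)
            h.append_rows("cohort", _demo_table())
        with open_store(path, engine) as h2:
            assert h2.list_tables() == ["cohort"]
            assert h2.read_table("cohort") == _demo_table()

    def test_engine_mismatch_on_existing_file(self, tmp_path):
        path = tmp_path / "m.db"
        open_store(path, "rowstore").close()
        with pytest.raises(ConfigurationError):
            open_store(path, "columnstore")


class TestCreateDropList:
    def test_create_preserves_schema_order(self, store):
        t = _demo_table()
        store.create_table("cohort", t.schema)
        schema, n = store.table_schema("cohort")
        assert schema.names == ["sample_id", "age", "bmi"]
        assert schema.kinds == ["text", "integer", "real"]
        assert n == 0

    def test_replace_resets_contents(self, store):
        store.create_table("t", _demo_table().schema)
        store.append_rows("t", _demo_table())
        store.create_table("t", _demo_table().schema, if_exists="replace")
        assert store.table_schema("t")[1] == 0

    def test_duplicate_fails_and_reserved_names_rejected(self, store):
        store.create_table("t", _demo_table().schema)
        with pytest.raises(DuplicateError):
            store.create_table("t", _demo_table().schema)
        with pytest.raises(SchemaError):
            store.create_table("_layers_meta", _demo_table().schema, if_exists="replace")
        with pytest.raises(SchemaError):
            TableSchema([ColumnSpec("a", "integer"), ColumnSpec("a", "integer")])

    def test_list_hides_internal_tables_and_drop_updates_list(self, store):
        for name in ("a", "b", "c"):
            store.create_table(name, _demo_table().schema)
        assert store.list_tables() == ["a", "b", "c"]
        store.drop_table("b")
        assert store.list_tables() == ["a", "c"]
        store.drop_table("b")  # idempotent-safe
        with pytest.raises(NotFoundError):
            store.table_schema("b")

    def test_identifier_with_dots_and_dashes(self, store):
        t = TypedTable.from_columns([("HMDB00001.v2-x", "real", [1.5])])
        store.create_table("metas", t.schema)
        store.append_rows("metas", t)
        assert store.read_table("metas") == t


class TestAppend:
    def test_append_returns_count_and_round_trips(self, store):
        t = _demo_table(100)
        store.create_table("cohort", t.schema)
        assert store.append_rows("cohort", t) == 100
        assert store.read_table("cohort") == t

    def test_empty_append_changes_nothing(self, store):
        t = _demo_table(3)
        store.create_table("t", t.schema)
        store.append_rows("t", t)
        assert store.append_rows("t", t.slice_rows(0, 0)) == 0
        assert store.read_table("t") == t

    def test_schema_mismatch_leaves_rows_unchanged(self, store):
        """Oracle: full re-read before and after the failing append."""
        t = _demo_table(4)
        store.create_table("t", t.schema)
        store.append_rows("t", t)
        before = store.read_table("t")
        bad = TypedTable.from_columns([
            ("sample_id", "text", ["X"]),
            ("age", "text", ["not-a-number"]),  # kind differs from stored
            ("bmi", "real", [1.0]),
        ])
        with pytest.raises(AppendError):
            store.append_rows("t", bad)
        assert store.read_table("t") == before


class TestAddColumns:
    def test_equals_one_shot_construction(self, store):
        """Oracle: the same table built whole in one create+append."""
        base = _demo_table(7)
        extra = TypedTable.from_columns([("score", "real", [float(i) for i in range(7)])])
        store.create_table("grown", base.schema)
        store.append_rows("grown", base)
        store.add_columns("grown", extra)

        whole = TypedTable(
            TableSchema(list(base.schema.columns) + list(extra.schema.columns)),
            {**{n: base.column(n) for n in base.schema.names},
             "score": extra.column("score")},
        )
        store.create_table("oneshot", whole.schema)
        store.append_rows("oneshot", whole)
        assert store.read_table("grown") == store.read_table("oneshot") == whole

    def test_zero_columns_is_identity(self, store):
        t = _demo_table(3)
        store.create_table("t", t.schema)
        store.append_rows("t", t)
        store.add_columns("t", TypedTable(TableSchema([]), {}))
        assert store.read_table("t") == t

    def test_wrong_length_and_collision_leave_table_unchanged(self, store):
        t = _demo_table(3)
        store.create_table("t", t.schema)
        store.append_rows("t", t)
        with pytest.raises(AlignmentError):
            store.add_columns("t", TypedTable.from_columns([("x", "integer", [1])]))
        with pytest.raises(SchemaError):
            store.add_columns("t", TypedTable.from_columns([("AGE", "integer", [1, 2, 3])]))
        assert store.read_table("t") == t


class TestReads:
    def test_projection_and_identity(self, store):
        t = _demo_table(6)
        store.create_table("t", t.schema)
        store.append_rows("t", t)
        one = store.read_columns("t", ["bmi"])
        assert one.schema.names == ["bmi"] and one.n_rows == 6
        assert store.read_columns("t", ["bmi", "sample_id"]).schema.names == ["bmi", "sample_id"]
        assert store.read_columns("t", t.schema.names) == store.read_table("t")
        with pytest.raises(NotFoundError, match="height"):
            store.read_columns("t", ["height"])

    def test_read_empty_table_keeps_schema(self, store):
        store.create_table("t", _demo_table().schema)
        out = store.read_table("t")
        assert out.n_rows == 0
        assert out.schema.names == ["sample_id", "age", "bmi"]

    def test_read_where_matches_linear_scan(self, store):
        rng = np.random.default_rng(42)
        t = TypedTable.from_columns([
            ("k", "integer", [int(v) for v in rng.integers(0, 10, size=80)]),
            ("v", "real", [float(v) for v in rng.normal(size=80)]),
        ])
        store.create_table("t", t.schema)
        store.append_rows("t", t)
        for values in ([3], [0, 7, 9], [42]):
            got = store.read_where("t", "k", values)
            keep = [k in values for k in t.column("k")]
            assert got == t.filter_rows(keep)

    def test_read_where_errors(self, store):
        t = _demo_table(3)
        store.create_table("t", t.schema)
        store.append_rows("t", t)
        with pytest.raises(QueryError):
            store.read_where("t", "age", [])
        with pytest.raises(QueryError):
            store.read_where("t", "age", ["twenty"])
        assert store.read_where("t", "age", [999]).n_rows == 0

    def test_row_count_matches_full_read(self, store):
        t = _demo_table(11)
        store.create_table("t", t.schema)
        store.append_rows("t", t)
        assert store.table_schema("t")[1] == store.read_table("t").n_rows == 11


class TestCrossEngine:
    def test_random_op_sequences_agree(self, tmp_path):
        """The same randomized create/append/add/read/drop script replayed
        on both engines yields value-identical reads."""
        rng = np.random.default_rng(7)
        handles = [open_store(tmp_path / f"{e}.db", e) for e in ENGINES]
        try:
            live: list[str] = []
            for step in range(40):
                op = rng.choice(["create", "append", "add_col", "drop"])
                if op == "create" or not live:
                    name = f"t{step}"
                    t = random_table(rng, n_rows=int(rng.integers(0, 30)))
                    for h in handles:
                        h.create_table(name, t.schema)
                        h.append_rows(name, t)
                    live.append(name)
                elif op == "append":
                    name = live[rng.integers(0, len(live))]
                    schema, n = handles[0].table_schema(name)
                    extra = random_table(rng, n_rows=int(rng.integers(0, 10)),
                                         n_cols=len(schema))
                    aligned = TypedTable(schema, {
                        s.name: [_coerce(v, s.kind) for v in extra.column(e.name)]
                        for s, e in zip(schema.columns, extra.schema.columns)
                    })
                    for h in handles:
                        h.append_rows(name, aligned)
                elif op == "add_col":
                    name = live[rng.integers(0, len(live))]
                    _, n = handles[0].table_schema(name)
                    col = TypedTable.from_columns(
                        [(f"x{step}", "real", [float(i) for i in range(n)])])
                    for h in handles:
                        h.add_columns(name, col)
                else:
                    name = live.pop(rng.integers(0, len(live)))
                    for h in handles:
                        h.drop_table(name)
                assert handles[0].list_tables() == handles[1].list_tables()
            for name in handles[0].list_tables():
                assert handles[0].read_table(name) == handles[1].read_table(name)
        finally:
            for h in handles:
                h.close()


def _coerce(v, kind):
    if v is None:
        return None
    if kind == "integer":
        return int(v) if not isinstance(v, str) else len(v)
    if kind == "real":
        return float(v) if not isinstance(v, str) else float(len(v))
    return str(v)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10**6))
def test_property_round_trip_both_engines(tmp_path_factory, seed):
    """Any valid mixed-kind table survives store→read exactly: values,
    column order, row order, and float precision."""
    rng = np.random.default_rng(seed)
    t = random_table(rng)
    base = tmp_path_factory.mktemp("rt")
    for eng in ENGINES:
        with open_store(base / f"{seed}_{eng}.db", eng) as h:
            h.create_table("t", t.schema)
            h.append_rows("t", t)
            assert h.read_table("t") == t
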