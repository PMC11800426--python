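"""Shared fixtures: per-engine stores/stacks and a random-table generator."""

import numpy as np
import pytest

from omicstacks.backend import open_store
from omicstacks.stack import Stack
from omicstacks.table import ColumnSpec, TableSchema, TypedTable

ENGINES = ("rowstore", "columnstore")


@pytest.fixture(params=ENGINES)
def engine(request):
    return request.param


@pytest.fixture
def store(tmp_path, engine):
    handle = open_store(tmp_path / f"{engine}.db", engine)
    yield handle
    handle.close()


@pytest.fixture
def stack(tmp_path, engine):
    s = Stack(tmp_path / f"stack_{engine}.db", engine)
    yield s
    s.close()


@pytest.fixture
def both_stacks(tmp_path):
    """One rowstore and one columnstore stack over separate files."""
    stacks = [Stack(tmp_path / f"pair_{e}.db", e) for e in ENGINES]
    yield stacks
    for s in stacks:
        s.close()


def random_table(rng: np.random.Generator, n_rows=None, n_cols=None,
                 with_nulls=True, prefix="c") -> TypedTable:
    """Property-style random mixed-kind table with optional nulls."""
    if n_cols is None:
        n_cols = int(rng.integers(1, 8))
    if n_rows is None:
        n_rows = int(rng.integers(0, 120))
    specs, data = [], {}
    for i in range(n_cols):
        kind = ("integer", "real", "text")[rng.integers(0, 3)]
        name = f"{prefix}{i}_{kind[0]}"
        specs.append(ColumnSpec(name, kind))
        if kind == "integer":
            values = [int(v) for v in rng.integers(-(10**12), 10**12, size=n_rows)]
        elif kind == "real":
            values = [float(v) for v in rng.normal(0, 1e6, size=n_rows)]
        else:
            values = ["".join(rng.choice(list("ACGT-._ αβ"), size=rng.integers(0, 12)))
                      for _ in range(n_rows)]
        if with_nulls and n_rows:
            for j in np.flatnonzero(rng.random(n_rows) < 0.1):
                values[j] = None
        data[name] = values
    return TypedTable(TableSchema(specs), data)
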