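"""Benchmark harness: time store/retrieve/extend operations across layer
sizes and summarize scaling with a regression through the origin.

Scaling is summarized by the no-intercept model ``time = beta * size``:
the slope ``beta`` (seconds per megabyte) is the quantity of interest and
a zero-size payload must take zero time, so the model has no intercept.
The closed-form least-squares slope is ``b = sum(x*y) / sum(x**2)`` with
standard error ``sqrt((RSS / (n - 1)) / sum(x**2))`` — one parameter is
estimated, leaving ``n - 1`` residual degrees of freedom — and the 95%
confidence interval is ``b ± t(0.975, n-1) * SE``.

Payload size is measured as the in-memory footprint of the payload in MB,
never its on-disk size.  Absolute runtimes are hardware-bound and are
never asserted anywhere; only the harness records them.
"""

from __future__ import annotations

import csv
import io
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ConfigurationError, InsufficientDataError, QueryError
from .simulate import FeatureMatrixSpec, placeholder_feature_ids, simulate_feature_matrix
from .stack import Stack
from .table import TypedTable

OPERATIONS = ("store", "retrieve", "extend_col", "row_query")


@dataclass(frozen=True)
class SlopeEstimate:
    """No-intercept regression slope with its 95% CI."""

    slope: float
    ci_low: float
    ci_high: float
    df: int
    n: int


@dataclass(frozen=True)
class BenchRecord:
    """One timed operation on one payload."""

    layer_name: str
    operation: str
    data_size_mb: float
    runtime_s: float
    engine: str


def fit_origin_regression(x: Sequence[float], y: Sequence[float]) -> SlopeEstimate:
    """Least-squares fit of ``y = beta * x`` with a 95% CI on the slope.

    ``x`` are payload sizes in MB (all strictly positive), ``y`` runtimes
    in seconds.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InsufficientDataError("x and y must have equal length")
    n = x.size
    if n < 2:
        raise InsufficientDataError(f"need at least 2 observations, got {n}")
    if np.any(x <= 0):
        raise QueryError("all sizes must be > 0")
    sxx = float(np.dot(x, x))
    b = float(np.dot(x, y)) / sxx
    resid = y - b * x
    df = n - 1
    se = float(np.sqrt((float(np.dot(resid, resid)) / df) / sxx))
    t = float(stats.t.ppf(0.975, df))
    return SlopeEstimate(slope=b, ci_low=b - t * se, ci_high=b + t * se, df=df, n=n)


def _payload_mb(table: TypedTable) -> float:
    df = table.to_pandas()
    return float(df.memory_usage(deep=True, index=False).sum()) / 1e6


def _payload_for_size(size_mb: float, seed: int) -> TypedTable:
    """Feature matrix (100 samples of 8-byte reals) sized to ~size_mb."""
    n_features = max(1, int(size_mb * 1e6 / (100 * 8)))
    ids = placeholder_feature_ids("gene", n_features)
    return simulate_feature_matrix(
        FeatureMatrixSpec(ids, n_samples=100, value_kind="real", decimals=4, seed=seed)
    )


def run_benchmark(
    workdir: str | Path,
    sizes_mb: Sequence[float],
    operations: Sequence[str] = ("store", "retrieve"),
    engines: Sequence[str] = ("rowstore", "columnstore"),
    repeats: int = 1,
    seed: int = 0,
) -> list[BenchRecord]:
    """Time each engine × size × operation on identical synthetic payloads.

    For every cell a fresh layer is built from a payload deterministic in
    (size, seed) — hence identical across engines — and the operation is
    timed with a monotonic clock.  Chunked VCF ingestion is deliberately
    not an operation here: its per-chunk disk round-trips put it on a
    different scaling regime, so it is excluded from the regression input.
    Raw repeats are recorded, not averaged.
    """
    if not sizes_mb:
        raise InsufficientDataError("size grid must be non-empty")
    for op in operations:
        if op not in OPERATIONS:
            raise ConfigurationError(f"unknown operation {op!r}; expected one of {OPERATIONS}")
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    records: list[BenchRecord] = []
    for size_idx, size in enumerate(sizes_mb):
        payload = _payload_for_size(size, seed + size_idx)
        mb = _payload_mb(payload)
        extra = TypedTable.from_columns(
            [("bench_extra", "real", [float(i) for i in range(payload.n_rows)])]
        )
        probe_ids = payload.column("feature_id")[:: max(1, payload.n_rows // 100)]
        for engine in engines:
            for op in operations:
                for rep in range(repeats):
                    db = workdir / f"bench_{engine}_{size_idx}_{op}_{rep}.db"
                    db.unlink(missing_ok=True)
                    stack = Stack(db, engine)
                    layer = f"bench_{size_idx}"
                    try:
                        if op == "store":
                            t0 = time.perf_counter()
                            stack.store_layer(layer, payload)
                            dt = time.perf_counter() - t0
                        else:
                            stack.store_layer(layer, payload)
                            t0 = time.perf_counter()
                            if op == "retrieve":
                                stack.load_layer(layer)
                            elif op == "extend_col":
                                stack.extend_layer_columns(layer, extra)
                            elif op == "row_query":
                                stack.select_rows(layer, "feature_id", probe_ids)
                            dt = time.perf_counter() - t0
                        records.append(BenchRecord(layer, op, mb, dt, engine))
                    finally:
                        stack.close()
                        db.unlink(missing_ok=True)
    return records


def fit_records(records: Sequence[BenchRecord]) -> dict[tuple[str, str], SlopeEstimate]:
    """Per (engine, operation) origin-regression slopes, when >= 2 points."""
    cells: dict[tuple[str, str], list[BenchRecord]] = {}
    for r in records:
        cells.setdefault((r.engine, r.operation), []).append(r)
    return {
        key: fit_origin_regression([r.data_size_mb for r in rs], [r.runtime_s for r in rs])
        for key, rs in cells.items()
        if len(rs) >= 2
    }


def records_to_csv(records: Sequence[BenchRecord], out_path: str | Path) -> None:
    """Fixed column order: layer_name,operation,data_size_mb,runtime_s,engine."""
    with open(out_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["layer_name", "operation", "data_size_mb", "runtime_s", "engine"])
        for r in records:
            w.writerow([r.layer_name, r.operation, repr(r.data_size_mb), repr(r.runtime_s), r.engine])


def report(records: Sequence[BenchRecord]) -> str:
    """Human-readable summary: per-cell slopes in ms/MB with 95% CI, then
    the raw records."""
    if not records:
        raise InsufficientDataError("no benchmark records to report")
    buf = io.StringIO()
    buf.write("engine       operation    slope[ms/MB]   95% CI [ms/MB]        n\n")
    for (engine, op), est in sorted(fit_records(records).items()):
        buf.write(
            f"{engine:<12} {op:<12} {est.slope * 1e3:>12.3f}   "
            f"[{est.ci_low * 1e3:.3f}, {est.ci_high * 1e3:.3f}]   {est.n:>4d}\n"
        )
    buf.write("\nlayer_name  operation  data_size_mb  runtime_s  engine\n")
    for r in records:
        buf.write(
            f"{r.layer_name}  {r.operation}  {r.data_size_mb:.3f}  {r.runtime_s:.4f}  {r.engine}\n"
        )
    return buf.getvalue()
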