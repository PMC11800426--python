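"""Chunked VCF ingestion and variant queries against a stored layer.

A VCF file becomes one layer: the nine fixed columns (``chrom``, ``pos``,
``id``, ``ref``, ``alt``, ``qual``, ``filter``, ``info``, ``format``) plus
one text column per sample.  ``pos`` is stored as a true integer so
position queries compare integers, never strings; every other field is
stored as raw text, byte-faithful to the input line — INFO and FORMAT are
never decomposed into typed columns, and contig names are never normalized
("chr1" and "1" stay distinct).

Files are streamed in chunks of a configurable number of data lines
(default 100,000), one transaction per chunk, so arbitrarily large VCFs
ingest without residing in memory.  Gzip input is detected by magic bytes,
not file extension.  The ``##`` meta-header is preserved in the layer's
description metadata (truncated at :data:`HEADER_DESCRIPTION_LIMIT`).
"""

from __future__ import annotations

import gzip
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

from .errors import IngestError, NotFoundError, ParseError, QueryError, SchemaError
from .stack import Stack
from .table import ColumnSpec, TableSchema, TypedTable

FIXED_COLUMNS = ("chrom", "pos", "id", "ref", "alt", "qual", "filter", "info", "format")
_VCF_FIXED_HEADER = ("#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT")

#: maximum number of characters of "##" meta-header kept in the description
HEADER_DESCRIPTION_LIMIT = 65536


def _open_maybe_gzip(path: str | Path) -> IO[str]:
    """Open plain or gzip text transparently; gzip detected by magic bytes."""
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


@dataclass(frozen=True)
class VCFHeader:
    """Parsed VCF header: ``##`` meta-lines plus the sample id list."""

    meta_lines: tuple[str, ...]
    sample_ids: tuple[str, ...]


def _parse_header(fh: IO[str]) -> tuple[VCFHeader, int]:
    """Read meta-lines and the #CHROM line; returns header and lines consumed."""
    meta: list[str] = []
    n = 0
    for line in fh:
        n += 1
        line = line.rstrip("\n")
        if line.startswith("##"):
            meta.append(line)
            continue
        if line.startswith("#CHROM"):
            fields = line.split("\t")
            if tuple(fields[:9]) != _VCF_FIXED_HEADER:
                raise ParseError(
                    f"malformed #CHROM line at line {n}: expected fixed columns "
                    f"{'/'.join(_VCF_FIXED_HEADER)}"
                )
            samples = tuple(fields[9:])
            if not samples:
                raise ParseError("VCF has no sample columns; a genotyped VCF is required")
            return VCFHeader(tuple(meta), samples), n
        raise ParseError(f"unexpected non-header line before #CHROM at line {n}")
    raise ParseError("no #CHROM header line found")


def _layer_schema(sample_ids: Sequence[str]) -> TableSchema:
    specs = [
        ColumnSpec("chrom", "text"),
        ColumnSpec("pos", "integer"),
        ColumnSpec("id", "text"),
        ColumnSpec("ref", "text"),
        ColumnSpec("alt", "text"),
        ColumnSpec("qual", "text"),
        ColumnSpec("filter", "text"),
        ColumnSpec("info", "text"),
        ColumnSpec("format", "text"),
    ]
    specs.extend(ColumnSpec(s, "text") for s in sample_ids)
    return TableSchema(specs)


def _parse_data_line(line: str, n_samples: int, line_no: int) -> tuple:
    fields = line.split("\t")
    if len(fields) != 9 + n_samples:
        raise IngestError(
            f"malformed VCF data line {line_no}: expected {9 + n_samples} fields, "
            f"got {len(fields)}"
        )
    try:
        pos = int(fields[1])
    except ValueError:
        raise IngestError(f"malformed VCF data line {line_no}: POS {fields[1]!r} is not an integer")
    if pos < 1:
        raise IngestError(f"malformed VCF data line {line_no}: POS must be >= 1, got {pos}")
    if not fields[3] or not fields[4]:
        raise IngestError(f"malformed VCF data line {line_no}: empty REF or ALT")
    return (fields[0], pos, *fields[2:])


def ingest_vcf(
    stack: Stack,
    path: str | Path,
    layer_name: str,
    chunk_size: int = 100_000,
    if_exists: str = "fail",
) -> int:
    """Stream a (possibly gzip-compressed) VCF into a layer.

    Data lines are appended in chunks of ``chunk_size`` lines, one
    transaction per chunk.  Returns the total number of data lines stored.
    A malformed header aborts before any write; a malformed data line
    aborts mid-file but previously committed chunks are retained.
    """
    if chunk_size < 1:
        raise QueryError(f"chunk_size must be >= 1, got {chunk_size}")
    with _open_maybe_gzip(path) as fh:
        header, header_lines = _parse_header(fh)
        schema = _layer_schema(header.sample_ids)
        description = "\n".join(header.meta_lines)[:HEADER_DESCRIPTION_LIMIT]
        with stack.handle.transaction():
            stack.handle.create_table(layer_name, schema, if_exists=if_exists)
            stack.handle.meta_upsert(layer_name, tag="", description=description)

        total = 0
        chunk: list[tuple] = []
        names = schema.names

        def flush() -> int:
            if not chunk:
                return 0
            data = {name: [row[i] for row in chunk] for i, name in enumerate(names)}
            n = stack.handle.append_rows(layer_name, TypedTable(schema, data))
            chunk.clear()
            return n

        for offset, line in enumerate(fh, start=header_lines + 1):
            line = line.rstrip("\n")
            if not line:
                continue
            chunk.append(_parse_data_line(line, len(header.sample_ids), offset))
            if len(chunk) >= chunk_size:
                total += flush()
        total += flush()
    return total


def layer_samples(stack: Stack, layer_name: str) -> list[str]:
    """Sample ids of a VCF layer (columns after the nine fixed ones)."""
    info = stack.layer_info(layer_name)
    names = info.schema.names
    if tuple(names[:9]) != FIXED_COLUMNS:
        raise SchemaError(f"layer {layer_name!r} is not a VCF layer")
    return names[9:]


def sample_genotype_column(stack: Stack, layer_name: str, sample_id: str) -> TypedTable:
    """All stored variants' field for one sample, in stored row order."""
    samples = layer_samples(stack, layer_name)
    if sample_id not in samples:
        raise NotFoundError(
            f"sample {sample_id!r} not in layer {layer_name!r}; available: {samples}"
        )
    return stack.load_column(layer_name, sample_id)


def position_query(
    stack: Stack,
    layer_name: str,
    chrom: str,
    positions: Iterable[int],
    columns: Sequence[str],
) -> TypedTable:
    """Rows with matching contig AND position in the given set, projected.

    Positions are matched by integer set membership; results keep stored
    row order.
    """
    positions = list(positions)
    if not positions:
        raise QueryError("position set must be non-empty")
    for p in positions:
        if not isinstance(p, int) or isinstance(p, bool) or p < 1:
            raise QueryError(f"positions must be integers >= 1, got {p!r}")
    hits = stack.select_rows(layer_name, "pos", positions)
    keep = [c == chrom for c in hits.column("chrom")]
    return hits.filter_rows(keep).select(list(columns))


@dataclass(frozen=True)
class PositionQuery:
    """One position query in a batch."""

    layer_name: str
    chrom: str
    positions: tuple[int, ...]
    columns: tuple[str, ...]


@dataclass
class BatchResult:
    """Per-query outcome: a result table or the error that query raised."""

    table: TypedTable | None = None
    error: Exception | None = field(default=None, repr=False)

    @property
    def ok(self) -> bool:
        return self.error is None


def run_query_batch(
    stack: Stack, queries: Sequence[PositionQuery], workers: int = 1
) -> list[BatchResult]:
    """Execute a read-only batch of position queries, optionally in parallel.

    Each worker opens its own read connection to the stack's file, so the
    batch is safe for concurrent readers (no writer may be active).
    Results are returned in query order and are identical to sequential
    execution; a failing query is reported in its slot without aborting
    the batch.
    """
    if workers < 1:
        raise QueryError(f"workers must be >= 1, got {workers}")

    def run_one(q: PositionQuery) -> BatchResult:
        local = Stack(stack.path, stack.engine)
        try:
            return BatchResult(table=position_query(local, q.layer_name, q.chrom,
                                                    list(q.positions), list(q.columns)))
        except Exception as exc:
            return BatchResult(error=exc)
        finally:
            local.close()

    if workers == 1:
        return [run_one(q) for q in queries]
    with ThreadPoolExecutor(max_workers=workers) as pool:
        return list(pool.map(run_one, queries))


# -- column transforms ----------------------------------------------------------

def _identity(values: list) -> list:
    return list(values)


#: registry of pure column transforms usable by add_variant_column
TRANSFORMS: dict[str, callable] = {"identity": _identity}


def register_transform(tag: str, fn) -> None:
    """Register a pure list-to-list transform under a tag."""
    TRANSFORMS[tag] = fn


def _infer_kind(values: list) -> str:
    kinds = {type(v) for v in values if v is not None}
    if kinds <= {int}:
        return "integer"
    if kinds <= {int, float}:
        return "real"
    return "text"


def add_variant_column(
    stack: Stack,
    layer_name: str,
    source_column: str,
    transform_tag: str = "identity",
    new_name: str | None = None,
) -> None:
    """Read a column, apply a registered pure transform, append the result
    as a new column (positional alignment, same row count by construction).

    The default transform is an identity copy under ``<source>_<tag>``.
    """
    if transform_tag not in TRANSFORMS:
        raise NotFoundError(
            f"unknown transform {transform_tag!r}; registered: {sorted(TRANSFORMS)}"
        )
    if new_name is None:
        new_name = f"{source_column}_{transform_tag}"
    source = stack.load_column(layer_name, source_column)
    values = TRANSFORMS[transform_tag](source.column(source_column))
    out = TypedTable(
        TableSchema([ColumnSpec(new_name, _infer_kind(values))]), {new_name: values}
    )
    stack.extend_layer_columns(layer_name, out)


def export_vcf(stack: Stack, layer_name: str, out_path: str | Path) -> None:
    """Re-serialize a VCF layer: stored meta-header plus tab-joined rows."""
    info = stack.layer_info(layer_name)
    samples = layer_samples(stack, layer_name)
    table = stack.load_layer(layer_name)
    with open(out_path, "w", encoding="utf-8") as fh:
        if info.metadata.description:
            fh.write(info.metadata.description + "\n")
        fh.write("\t".join(_VCF_FIXED_HEADER + tuple(samples)) + "\n")
        for row in table.rows():
            fh.write("\t".join(str(v) for v in row) + "\n")
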