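# Methods

## Storage model

A stack is one embedded database file holding user layers, a reserved
metadata catalogue (`_layers_meta`: name, tag, description) and a store
marker (`_store_info`), so the whole dataset distributes as a single
portable artifact. Two physical layouts implement one storage contract.

**Row store.** One SQL table per layer. Column kinds map as
integer → 64-bit SQL integer, real → double precision, text →
variable-length string — lossless for the data shapes targeted here
(counts up to millions of rows, 4-decimal floats; doubles round-trip
exactly at full precision). Identifiers are quoted, so feature ids
containing dots and dashes (`HMDB00001.v2-x`) are legal column names;
names colliding with the reserved `_` prefix are rejected.

**Column store.** SQL tables are unordered bags, and column-oriented
engines shine when whole columns are scanned or appended. The column
store keeps each logical column in its own single-column physical table.
Positional alignment holds because every append writes the same number of
values to every column table inside one transaction, rows are never
deleted individually, and each physical table's implicit rowid increases
monotonically with insertion: the i-th rowid of every column table
addresses the same logical row. Column-wise extension is then a pure
table creation plus bulk insert — no rewrite of existing data — and a
single-column load touches only that column's pages.

**Row order.** The contract guarantees reads in insertion order on both
engines via an explicit `ORDER BY rowid`. This is a design choice of this
package: positional column extension is meaningless without a stable row
order, so the order is made part of the contract rather than left to the
engine's scan order.

**Transactions.** Each `append_rows` call is exactly one transaction
(all rows or none), so chunked ingestion commits per chunk and a failure
mid-chunk leaves the observable row count unchanged. Multi-step
operations (`store_layer`, `drop_layer`) nest inside one outer
transaction so the catalogue and the physical tables can never diverge.
The store runs in write-ahead-logging mode with `synchronous=NORMAL`:
committed transactions survive process crashes, readers never block
behind the single writer, and small frequent commits avoid a full fsync
each. (A WAL sidecar file exists while a store is open; it is folded back
into the main file on close.) The trade-off — an OS-level crash or power
loss may roll back the most recent commits, though never corrupt the
file — is acceptable for an analysis store. Concurrent writers are out of
scope; the contract is single-writer, many-readers.

**Engine marker.** The file records which engine created it. Reopening
with the other engine is a configuration error, and `Stack(path)` with no
engine argument reuses the recorded engine (new files default to the
column store). Nothing in the contract requires this, but silently
reading a columnar file as a row store would surface internal tables, so
detection is the safer default.

**Nulls** are allowed in every kind and stored as SQL NULL. Row-value
membership queries follow SQL semantics: a null never matches any
membership set (identical to the in-memory scan oracle, which compares
against non-null values only).

## Stack and layer semantics

- `store_layer` defaults to `if_exists="fail"`; replacing resets the
  tag/description to empty, since the new contents need not share the old
  annotation's meaning.
- One tag string per layer. Tag queries are a pure function of the
  catalogue (`layers_with_tag` returns a lexicographically sorted list).
- `extend_layer_rows` aligns by column **name** (order-insensitive),
  mirroring append semantics; `extend_layer_columns` aligns
  **positionally** with strict length equality, mirroring
  column-addition semantics. The asymmetry is deliberate: new rows carry
  their own headers, new columns do not carry row keys.
- `join_layers` is an inner equi-join, folded left-to-right over loaded
  layers with the dataframe library's merge; the join column appears
  once and duplicate non-key names from a right layer are suffixed
  `__<layer>`. Result order follows the leftmost layer's stored order
  (ties in right-layer order), matching a nested-loop oracle.
- The recommended layer orientation is features as rows and samples as
  columns — the orientation the column store optimizes — but it is not
  enforced: the cohort layer itself is naturally samples-as-rows.

## VCF layers

A VCF file becomes a layer with the nine fixed columns plus one text
column per sample. Decisions:

- `pos` is a true integer column; all other fields are stored as **raw
  text**. Position and sample queries never need INFO/FORMAT
  decomposition, and raw storage keeps re-serialization byte-faithful
  (tab-joining a stored row reproduces the input data line, given the
  canonical integer spelling of POS that VCF writers emit).
- Coordinates stay 1-based throughout, per the format; no half-open
  conversion anywhere. Contig names are stored verbatim — `chr1` and `1`
  are never conflated.
- Gzip input is detected by magic bytes (`1f 8b`), not file extension.
- The `##` meta-header is preserved in the layer's *description*
  metadata, truncated at 65,536 characters (documented constant), which
  keeps the one-table-per-layer model; export reconstructs the header
  from it.
- Chunked ingestion commits one transaction per chunk (default 100,000
  lines). A malformed header aborts before any write; a malformed data
  line aborts with its line number while previously committed chunks are
  retained, so a partial ingest is inspectable rather than silently
  dropped.
- Query batches open one read connection per worker thread; results are
  returned in query order, each slot holding either a table or that
  query's error, and are bit-identical to sequential execution.

## Synthetic data generators

The generators emulate the *shapes* of a small multi-omic study — sizes,
types, ranges, decimal precisions — with uniform draws:

| layer | contents | distribution |
|---|---|---|
| `cohort` | 100 samples: id, gender, age, BMI | age uniform integers [20, 50]; BMI uniform [20, 40] rounded to 2 decimals; gender uniform {F, M} |
| `blood_metas`, `urine_metas` | metabolite × sample abundances | uniform [0, 1000], 4 decimals |
| `rnaseq` | gene × sample counts | uniform integers [0, 1000] |
| `microbiome` | species × sample counts | uniform integers [0, 1000] |
| `vcf` | variants per chromosome | positions unit-incremented from 100,000; REF/ALT uniform single bases, REF ≠ ALT; genotypes uniform phased {0\|0, 0\|1, 1\|0, 1\|1}; INFO metrics uniform |

Choices where the emulated design was open:

- **Gender** has no stated distribution; uniform {"F", "M"} text.
- **Genotypes**: imputed call sets are typically phased, so the phased
  alphabet is the default; `phased=False` switches to {0/0, 0/1, 1/1}.
- **INFO metrics**: pipelines attach many caller- and imputation-quality
  fields; two representative stand-ins are emitted — a quality-like key
  `QD` uniform in [0, 100] and an imputation-accuracy-like key `R2`
  uniform in [0, 1] — configurable via `VCFSimSpec.info_keys`.
- **QUAL/FILTER** are "." and "PASS".
- **Feature ids** are deterministic placeholders shaped like public
  catalogue ids (`HMDB-SYN-000001`, `ENSG-SYN-000001`, `GUT-SYN-000001`);
  real id lists from the metabolite/gene-annotation/microbiome catalogues
  can be passed instead wherever `feature_ids` is accepted, but are never
  downloaded by the package.

What the generators do **not** emulate — and hence what passing tests do
not show about real data: biological covariance between features and
layers, realistic abundance distributions (real omics data are heavy
tailed, not uniform), allele frequencies and linkage disequilibrium,
missingness patterns, multi-allelic sites, and single-cell sparse
matrices (deliberately out of scope; dedicated sparse-matrix tooling
already covers them). The tests therefore establish *data-management*
correctness — typed round-trips, ordering, atomicity, cross-engine
equivalence — not statistical realism.

Default sizes are desk-scale (e.g. the demo stack uses 100 samples, tens
to hundreds of features per layer, 2 contigs × 100 variants; the
acceptance checks use up to 10,000-line VCFs and 10⁵-value matrices) so
the whole suite runs in well under a minute of compute; study-scale
counts (millions of variants) are reachable through the same specs by
configuration only.

## Benchmark harness and the origin regression

Storage/retrieval scaling is summarized by regression through the origin,
`time = β·size`: a zero-byte payload must take zero time, so the model has
no intercept. The closed-form slope is `β̂ = Σxy/Σx²`. The standard error
uses an `n − 1` residual degrees-of-freedom denominator — one parameter
is estimated — giving `SE = √((RSS/(n−1))/Σx²)` and the 95% CI
`β̂ ± t₀.₉₇₅,ₙ₋₁·SE`. This choice is validated two ways: the slope and CI
match a general-purpose least-squares solver to 1e-12 relative, and a
1,000-replicate simulation confirms ~95% CI coverage of the true slope.

Payload size is the in-memory footprint of the payload in MB (deep
dataframe memory usage), never its on-disk size. Payloads are
deterministic per (size, seed) and therefore identical across engines in
each cell. Raw repeat timings are recorded, not averaged; the regression
consumes all raw points. Chunked VCF ingestion is excluded from the
regression input: its per-chunk disk round-trips put it on a different
scaling regime than in-memory payload writes. Absolute runtimes are
hardware-bound and are never asserted in tests; the only timing
comparison in the suite (column- vs row-store retrieval) is directional
and warn-only.

## Numerical and degenerate-input choices

- Real values round-trip at full double precision (no string formatting
  in the storage path).
- Integer columns accept whole-valued floats (2.0 → 2) at the boundary;
  booleans are rejected as neither integers nor reals.
- Zero-row appends and zero-column extensions are identities; an empty
  membership set is a query error (an empty filter is almost always a
  caller bug, unlike an empty *result*).
- `fit_origin_regression` requires n ≥ 2 and all sizes strictly positive.
- NaN input values are treated as nulls at table construction.

## Known limitations

- Single writer per store; no server mode, no horizontal scaling, no
  secondary indexes, no arbitrary SQL passthrough, no schema migration or
  layer versioning.
- The byte-fidelity guarantee for VCF re-serialization assumes canonical
  integer POS spellings (no leading zeros), which standard writers emit.
- `table_schema` reconstructs kinds from the stored layout; per-column
  nullability is not persisted (all stored columns are nullable).
- The columnstore's catalog adds two small internal tables per stack and
  one physical table per column; stacks with very many columns pay a
  per-table metadata overhead.
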