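"""Synthetic multi-omic data generators.

These emulate a small multi-omic study: a 100-sample cohort table, blood
and urine metabolomes (4-decimal uniform abundances in [0, 1000]), bulk
RNA-seq counts and gut-microbiome species counts (uniform integers in
[0, 1000]), and an imputed germline short-variant VCF whose positions run
contiguously from 100,000 within each chromosome.  Values are drawn from
uniform distributions — the generators emulate data *shapes* (sizes,
types, ranges, precisions), not biological covariance structure, allele
frequencies or linkage disequilibrium.

Feature identifiers are deterministic placeholders shaped like the public
catalogues they stand in for (HMDB metabolites, ENSEMBL gene ids,
gut-microbiome species); real id lists can be supplied instead wherever a
``feature_ids`` argument is accepted.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Mapping, Sequence

import numpy as np

from .errors import SpecError
from .stack import Stack
from .table import ColumnSpec, TableSchema, TypedTable

#: phased genotype alphabet for simulated sample fields (imputed data are
#: typically phased); set ``phased=False`` for the unphased equivalents
PHASED_GENOTYPES = ("0|0", "0|1", "1|0", "1|1")
UNPHASED_GENOTYPES = ("0/0", "0/1", "1/1")

_BASES = ("A", "C", "G", "T")

#: default first variant position on every simulated chromosome
VCF_START_POS = 100_000


def _sample_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"S{i:0{width}d}" for i in range(1, n + 1)]


@dataclass(frozen=True)
class CohortSpec:
    """Cohort characteristics table: sample id, gender, age, BMI."""

    n_samples: int = 100
    age_range: tuple[int, int] = (20, 50)
    bmi_range: tuple[float, float] = (20.0, 40.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 0:
            raise SpecError(f"n_samples must be >= 0, got {self.n_samples}")


def simulate_cohort(spec: CohortSpec = CohortSpec()) -> TypedTable:
    """Cohort layer: ages uniform integers in the closed age range, BMI
    uniform reals rounded to exactly 2 decimals, gender uniform in {F, M}.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    lo_a, hi_a = spec.age_range
    lo_b, hi_b = spec.bmi_range
    schema = TableSchema(
        [
            ColumnSpec("sample_id", "text"),
            ColumnSpec("gender", "text"),
            ColumnSpec("age", "integer"),
            ColumnSpec("bmi", "real"),
        ]
    )
    return TypedTable(
        schema,
        {
            "sample_id": _sample_ids(n),
            "gender": [("F", "M")[i] for i in rng.integers(0, 2, size=n)],
            "age": [int(a) for a in rng.integers(lo_a, hi_a + 1, size=n)],
            "bmi": [round(float(b), 2) for b in rng.uniform(lo_b, hi_b, size=n)],
        },
    )


@dataclass(frozen=True)
class FeatureMatrixSpec:
    """Feature-by-sample uniform value matrix (features as rows)."""

    feature_ids: tuple[str, ...]
    n_samples: int = 100
    value_kind: str = "real"
    value_range: tuple[float, float] = (0.0, 1000.0)
    decimals: int = 4
    seed: int = 0

    def __init__(self, feature_ids: Sequence[str], n_samples: int = 100,
                 value_kind: str = "real", value_range: tuple[float, float] = (0.0, 1000.0),
                 decimals: int = 4, seed: int = 0):
        ids = tuple(feature_ids)
        if len(set(ids)) != len(ids):
            raise SpecError("feature ids must be unique")
        if value_kind not in ("integer", "real"):
            raise SpecError(f"value_kind must be 'integer' or 'real', got {value_kind!r}")
        if value_kind == "real" and decimals < 0:
            raise SpecError("decimals must be >= 0 for real values")
        if n_samples < 0:
            raise SpecError(f"n_samples must be >= 0, got {n_samples}")
        object.__setattr__(self, "feature_ids", ids)
        object.__setattr__(self, "n_samples", n_samples)
        object.__setattr__(self, "value_kind", value_kind)
        object.__setattr__(self, "value_range", value_range)
        object.__setattr__(self, "decimals", decimals)
        object.__setattr__(self, "seed", seed)


def simulate_feature_matrix(spec: FeatureMatrixSpec) -> TypedTable:
    """Feature matrix with features as rows: first column ``feature_id``,
    then one column per sample.

    Real values are uniform in the closed range, rounded to
    ``spec.decimals``; integer values are uniform integers in the closed
    range.
    """
    rng = np.random.default_rng(spec.seed)
    n_feat, n_samp = len(spec.feature_ids), spec.n_samples
    lo, hi = spec.value_range
    specs = [ColumnSpec("feature_id", "text")]
    specs += [ColumnSpec(s, spec.value_kind) for s in _sample_ids(n_samp)]
    data: dict[str, list] = {"feature_id": list(spec.feature_ids)}
    for sample in _sample_ids(n_samp):
        if spec.value_kind == "integer":
            data[sample] = [int(v) for v in rng.integers(int(lo), int(hi) + 1, size=n_feat)]
        else:
            data[sample] = [
                round(float(v), spec.decimals) for v in rng.uniform(lo, hi, size=n_feat)
            ]
    return TypedTable(TableSchema(specs), data)


_ID_PREFIXES = {"metabolite": "HMDB-SYN-", "gene": "ENSG-SYN-", "species": "GUT-SYN-"}


def placeholder_feature_ids(kind: str, count: int) -> list[str]:
    """Deterministic, unique, kind-prefixed feature ids.

    Stand-ins shaped like ids from the public metabolite / gene annotation /
    gut-microbiome catalogues; user-supplied real id lists are accepted by
    every generator that takes ``feature_ids``.
    """
    if kind not in _ID_PREFIXES:
        raise SpecError(f"unknown feature kind {kind!r}; expected one of {sorted(_ID_PREFIXES)}")
    if count < 0:
        raise SpecError(f"count must be >= 0, got {count}")
    prefix = _ID_PREFIXES[kind]
    return [f"{prefix}{i:06d}" for i in range(1, count + 1)]


@dataclass(frozen=True)
class VCFSimSpec:
    """Per-chromosome variant counts for the synthetic VCF writer."""

    per_chrom_counts: Mapping[str, int]
    n_samples: int = 10
    start_pos: int = VCF_START_POS
    seed: int = 0
    compress: bool = False
    phased: bool = True
    info_keys: tuple[tuple[str, float, float], ...] = (("QD", 0.0, 100.0), ("R2", 0.0, 1.0))

    def __post_init__(self) -> None:
        for chrom, count in self.per_chrom_counts.items():
            if count < 0:
                raise SpecError(f"variant count for {chrom!r} must be >= 0, got {count}")
        if self.n_samples < 0:
            raise SpecError(f"n_samples must be >= 0, got {self.n_samples}")
        if self.start_pos < 1:
            raise SpecError(f"start_pos must be >= 1, got {self.start_pos}")


def simulate_vcf(spec: VCFSimSpec, out_path: str | Path) -> dict[str, int]:
    """Write a synthetic genotyped VCF; returns per-contig data-line counts.

    Within each contig, positions run ``start_pos, start_pos+1, ...`` for
    exactly the requested count.  REF and ALT are uniform single bases with
    REF != ALT; sample fields are uniform phased (or unphased) genotypes;
    INFO carries uniform-real metrics (default a quality-like key in
    [0, 100] and an imputation-accuracy-like key in [0, 1]); QUAL is "."
    and FILTER "PASS".  Output is gzip-compressed when ``spec.compress``.
    """
    rng = np.random.default_rng(spec.seed)
    samples = _sample_ids(spec.n_samples)
    genotypes = PHASED_GENOTYPES if spec.phased else UNPHASED_GENOTYPES
    counts: dict[str, int] = {}

    opener = gzip.open if spec.compress else open
    fh: IO[str]
    with opener(out_path, "wt", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=omicstacks-simulate\n")
        for chrom in spec.per_chrom_counts:
            fh.write(f"##contig=<ID={chrom}>\n")
        for key, lo, hi in spec.info_keys:
            fh.write(
                f'##INFO=<ID={key},Number=1,Type=Float,Description="Uniform metric in [{lo},{hi}]">\n'
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("\t".join(
            ("#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT", *samples)
        ) + "\n")
        for chrom, count in spec.per_chrom_counts.items():
            for i in range(count):
                pos = spec.start_pos + i
                r = int(rng.integers(0, 4))
                a = int(rng.integers(0, 3))
                if a >= r:  # uniform over the three non-REF bases
                    a += 1
                ref, alt = _BASES[r], _BASES[a]
                info = ";".join(
                    f"{key}={rng.uniform(lo, hi):.4f}" for key, lo, hi in spec.info_keys
                )
                gts = [genotypes[g] for g in rng.integers(0, len(genotypes), size=len(samples))]
                fh.write("\t".join(
                    (chrom, str(pos), ".", ref, alt, ".", "PASS", info, "GT", *gts)
                ) + "\n")
            counts[chrom] = count
    return counts


def build_demo_stack(
    path: str | Path,
    engine: str | None = None,
    seed: int = 0,
    n_samples: int = 100,
    n_metabolites: int = 50,
    n_genes: int = 200,
    n_species: int = 100,
    vcf_counts: Mapping[str, int] | None = None,
    vcf_samples: int = 10,
) -> Stack:
    """Build a small-scale stack with all six study layers.

    Layers: ``cohort``, ``blood_metas``, ``urine_metas``, ``rnaseq``,
    ``microbiome`` and ``vcf``.  The metabolite layers are tagged
    ``metabolomics``.  Sizes are desk-scale defaults; pass larger counts to
    approach study scale.  Deterministic for a given seed.
    """
    from .vcf import ingest_vcf  # local import to avoid a cycle

    stack = Stack(path, engine)
    stack.store_layer("cohort", simulate_cohort(CohortSpec(n_samples=n_samples, seed=seed)))
    stack.annotate_layer("cohort", description="simulated cohort characteristics")

    for i, name in enumerate(("blood_metas", "urine_metas")):
        ids = placeholder_feature_ids("metabolite", n_metabolites)
        layer = simulate_feature_matrix(
            FeatureMatrixSpec(ids, n_samples=n_samples, value_kind="real",
                              decimals=4, seed=seed + 1 + i)
        )
        stack.store_layer(name, layer)
        stack.annotate_layer(name, tag="metabolomics",
                             description=f"simulated {name.split('_')[0]} metabolome")

    rnaseq = simulate_feature_matrix(
        FeatureMatrixSpec(placeholder_feature_ids("gene", n_genes), n_samples=n_samples,
                          value_kind="integer", seed=seed + 3)
    )
    stack.store_layer("rnaseq", rnaseq)
    stack.annotate_layer("rnaseq", tag="transcriptomics",
                         description="simulated bulk RNA-seq counts")

    microbiome = simulate_feature_matrix(
        FeatureMatrixSpec(placeholder_feature_ids("species", n_species), n_samples=n_samples,
                          value_kind="integer", seed=seed + 4)
    )
    stack.store_layer("microbiome", microbiome)
    stack.annotate_layer("microbiome", tag="metagenomics",
                         description="simulated gut microbiome species counts")

    if vcf_counts is None:
        vcf_counts = {"chr1": 100, "chr2": 100}
    vcf_path = Path(path).with_suffix(".synthetic.vcf")
    simulate_vcf(VCFSimSpec(vcf_counts, n_samples=vcf_samples, seed=seed + 5), vcf_path)
    ingest_vcf(stack, vcf_path, "vcf")
    stack.annotate_layer("vcf", tag="genomics")
    vcf_path.unlink()
    return stack
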