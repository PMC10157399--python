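"""Read, write and index the heterogeneous annotated variant store.

The store is a directory of per-sample, per-analysis variant tables:
tab-separated text derived from VCF (hg19 coordinates), with the eight VCF
core columns first and a pipeline-version-dependent set of custom annotation
columns after them (population allele frequencies, in-silico scores, OMIM and
ClinVar fields).  Missing annotation cells are rendered as a single gap token,
``"."`` by default.  Analysis provenance (sample, timestamp, pipeline version)
lives in a JSON or YAML manifest at the store root, never in filesystem
metadata, so that store listings are reproducible.
"""

from __future__ import annotations

import csv
import json
import re
import warnings
from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path

import yaml

from .exceptions import (
    AmbiguousAnalysisError,
    MalformedStoreError,
    ParseWarning,
    SchemaMismatchError,
)

# ---------------------------------------------------------------------------
# Column registry
# ---------------------------------------------------------------------------

#: The eight mandatory VCF-derived columns, always present and first.
CORE_COLUMNS: tuple[str, ...] = (
    "CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO",
)

GENE_COLUMN = "GENE"
PROTEIN_COLUMN = "PROTEIN_CHANGE"

#: Population allele-frequency sources (fractions in [0, 1]).
AF_COLUMNS: tuple[str, ...] = (
    "ESP_AF", "EXAC_AF", "GNOMAD_EXOME_AF", "GNOMAD_GENOME_AF",
)

#: Numeric annotation columns: occurrence counts, in-silico scores and
#: constraint metrics.  OE_* are the gnomAD observed/expected LoF ratio and
#: its 90% CI bounds; SPIP is a splice predictor; CCR a regional constraint
#: percentile.  The last five arrived with the v2 pipeline.
SCORE_COLUMNS: tuple[str, ...] = (
    "GNOMAD_EXOME_AC", "INTERNAL_CONTROL_AC", "BATCH_AC",
    "POLYPHEN", "GERP", "GRANTHAM", "CADD", "MISZ", "PLI",
    "OE", "OE_LOWER", "OE_UPPER", "SPIP", "CCR",
)

OMIM_COLUMNS: tuple[str, ...] = ("OMIM_NAME", "OMIM_NUMBER", "OMIM_MODE")
CLINVAR_COLUMN = "CLINVAR"

_V2_ONLY = ("OE", "OE_LOWER", "OE_UPPER", "SPIP", "CCR")


def column_kind(name: str) -> str:
    """Classify a column name into the row field that stores it."""
    if name in CORE_COLUMNS:
        return "core"
    if name == GENE_COLUMN:
        return "gene"
    if name == PROTEIN_COLUMN:
        return "protein"
    if name in AF_COLUMNS:
        return "af"
    if name in SCORE_COLUMNS:
        return "score"
    if name in OMIM_COLUMNS:
        return "omim"
    if name == CLINVAR_COLUMN:
        return "clinvar"
    return "extra"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of one variant: chrom / 1-based pos (hg19) / ref / alt.

    Symbolic alts ``DEL`` and ``DUP`` are used for variants transcribed from
    HGVS-g deletion/duplication strings; the affected span is encoded in the
    length of the ``N``-placeholder ref.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")


_HGVS_SUB = re.compile(r"^(?P<chrom>[^:]+):g\.(?P<pos>\d+)(?P<ref>[ACGTN]+)>(?P<alt>[ACGTN]+)$")
_HGVS_SPAN = re.compile(r"^(?P<chrom>[^:]+):g\.(?P<start>\d+)(?:_(?P<end>\d+))?(?P<op>del|dup)$")


def parse_hgvs_g(text: str) -> VariantKey:
    """Parse a genomic HGVS string (``chr6:g.31637615T>C``) into a key.

    Substitutions keep literal ref/alt; ``del``/``dup`` become symbolic alts
    ``DEL``/``DUP`` with an ``N``-run ref spanning the stated interval.
    """
    m = _HGVS_SUB.match(text)
    if m:
        return VariantKey(m["chrom"], int(m["pos"]), m["ref"], m["alt"])
    m = _HGVS_SPAN.match(text)
    if m:
        start = int(m["start"])
        end = int(m["end"]) if m["end"] else start
        if end < start:
            raise ValueError(f"HGVS span end < start in {text!r}")
        return VariantKey(m["chrom"], start, "N" * (end - start + 1), m["op"].upper())
    raise ValueError(f"unparseable genomic HGVS string: {text!r}")


def format_hgvs_g(key: VariantKey) -> str:
    """Inverse of :func:`parse_hgvs_g` for report rendering."""
    if key.alt in ("DEL", "DUP"):
        span = len(key.ref)
        op = key.alt.lower()
        if span == 1:
            return f"{key.chrom}:g.{key.pos}{op}"
        return f"{key.chrom}:g.{key.pos}_{key.pos + span - 1}{op}"
    return f"{key.chrom}:g.{key.pos}{key.ref}>{key.alt}"


@dataclass(frozen=True)
class AnnotationSchema:
    """Ordered column set of one pipeline version of the variant table."""

    columns: tuple[str, ...]
    version_tag: str
    gap_token: str = "."

    def __post_init__(self) -> None:
        if len(set(self.columns)) != len(self.columns):
            dupes = sorted({c for c in self.columns if self.columns.count(c) > 1})
            raise MalformedStoreError(f"duplicate columns in schema: {dupes}")
        if tuple(self.columns[:8]) != CORE_COLUMNS:
            raise MalformedStoreError(
                "the eight VCF core columns must be present and first; got "
                f"{self.columns[:8]}"
            )

    @property
    def annotation_columns(self) -> tuple[str, ...]:
        return self.columns[8:]


_COMMON_ANNOTATIONS = (
    (GENE_COLUMN, PROTEIN_COLUMN)
    + AF_COLUMNS
    + ("GNOMAD_EXOME_AC", "INTERNAL_CONTROL_AC", "BATCH_AC",
       "POLYPHEN", "GERP", "GRANTHAM", "CADD", "MISZ", "PLI")
    + OMIM_COLUMNS
    + (CLINVAR_COLUMN,)
)

#: First-generation pipeline schema (pre-2020).
SCHEMA_V1 = AnnotationSchema(CORE_COLUMNS + _COMMON_ANNOTATIONS, "v1")

#: Second-generation schema: adds o/e with CI bounds, SPiP and CCR.
SCHEMA_V2 = AnnotationSchema(CORE_COLUMNS + _COMMON_ANNOTATIONS + _V2_ONLY, "v2")

#: Union of all known pipeline schemas; the harmonization target.
MASTER_SCHEMA = replace(SCHEMA_V2, version_tag="master")

SCHEMAS: dict[str, AnnotationSchema] = {"v1": SCHEMA_V1, "v2": SCHEMA_V2, "master": MASTER_SCHEMA}


@dataclass(frozen=True)
class AnalysisFile:
    """One per-sample analysis artifact with its provenance."""

    path: str
    sample_id: str
    analysis_timestamp: datetime
    schema: AnnotationSchema = field(compare=False)

    @property
    def version_tag(self) -> str:
        return self.schema.version_tag

    def sort_key(self) -> tuple:
        return (self.sample_id, self.analysis_timestamp, self.schema.version_tag, self.path)


@dataclass
class AnnotatedVariantRow:
    """One variant observation in one sample from one analysis file.

    Annotation values absent from the source schema are missing (``None``),
    never silently zero; ``extra_fields`` preserves verbatim any column the
    registry does not recognise.
    """

    key: VariantKey
    sample_id: str
    gene: str = ""
    protein_change: str | None = None
    af_fields: dict[str, float | None] = field(default_factory=dict)
    score_fields: dict[str, float | None] = field(default_factory=dict)
    omim_fields: dict[str, str | None] = field(default_factory=dict)
    clinvar_field: str | None = None
    extra_fields: dict[str, str] = field(default_factory=dict)
    id_field: str = "."
    qual: str = "."
    filter_field: str = "."
    info: str = "."
    source_file: AnalysisFile | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        for name, value in self.af_fields.items():
            if value is not None and not (0.0 <= value <= 1.0):
                raise ValueError(f"AF field {name} out of [0,1]: {value}")

    def get_cell(self, column: str) -> str | float | None:
        """Value of ``column`` for this row, or None when missing."""
        kind = column_kind(column)
        if kind == "core":
            return {
                "CHROM": self.key.chrom, "POS": self.key.pos, "ID": self.id_field,
                "REF": self.key.ref, "ALT": self.key.alt, "QUAL": self.qual,
                "FILTER": self.filter_field, "INFO": self.info,
            }[column]
        if kind == "gene":
            return self.gene or None
        if kind == "protein":
            return self.protein_change
        if kind == "af":
            return self.af_fields.get(column)
        if kind == "score":
            return self.score_fields.get(column)
        if kind == "omim":
            return self.omim_fields.get(column)
        if kind == "clinvar":
            return self.clinvar_field
        return self.extra_fields.get(column)

    def populated_columns(self) -> set[str]:
        """Non-core columns whose value would be lost if dropped on write."""
        cols: set[str] = set(self.extra_fields)
        if self.gene:
            cols.add(GENE_COLUMN)
        if self.protein_change is not None:
            cols.add(PROTEIN_COLUMN)
        for mapping in (self.af_fields, self.score_fields, self.omim_fields):
            cols.update(k for k, v in mapping.items() if v is not None)
        if self.clinvar_field is not None:
            cols.add(CLINVAR_COLUMN)
        return cols

    def text_cells(self, columns: tuple[str, ...]) -> list[str]:
        """All cell values of ``columns`` rendered as text (for word search)."""
        out = []
        for col in columns:
            v = self.get_cell(col)
            out.append("" if v is None else str(v))
        return out


# ---------------------------------------------------------------------------
# Table reading / writing
# ---------------------------------------------------------------------------

_CHR_PREFIX = re.compile(r"^chr", re.IGNORECASE)


def _chrom_style(chrom: str) -> str:
    return "chr-prefixed" if _CHR_PREFIX.match(chrom) else "bare"


def _parse_numeric(raw: str, column: str, path, line_no: int, *, is_af: bool) -> float | None:
    try:
        value = float(raw)
    except ValueError:
        warnings.warn(
            f"{path}:{line_no}: non-numeric value {raw!r} in column {column}; set missing",
            ParseWarning,
            stacklevel=3,
        )
        return None
    if is_af and not (0.0 <= value <= 1.0):
        warnings.warn(
            f"{path}:{line_no}: AF {value} in column {column} outside [0,1]; set missing",
            ParseWarning,
            stacklevel=3,
        )
        return None
    return value


def read_variant_table(
    path,
    schema_hint: AnnotationSchema | None = None,
    *,
    has_header: bool = True,
    sample_id: str | None = None,
    analysis: AnalysisFile | None = None,
) -> list[AnnotatedVariantRow]:
    """Parse one tab-separated annotated variant table into rows.

    With a header, columns named in ``schema_hint`` but absent from the file
    are reported missing on every row (the schema-gap case); file columns
    beyond the hint are preserved verbatim.  Without a header, cells map
    positionally onto ``schema_hint`` (then required).

    Raises
    ------
    MalformedStoreError
        If any data line has fewer than eight columns (the VCF core), if
        chromosome label styles are mixed within the file, or if POS is not
        a positive integer.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if analysis is not None:
        sample_id = analysis.sample_id
        if schema_hint is None:
            schema_hint = analysis.schema
    if sample_id is None:
        sample_id = path.stem.split(".")[0]

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        lines = list(reader)

    if has_header:
        if not lines:
            raise MalformedStoreError(f"{path}: empty file, header expected")
        file_columns = tuple(lines[0])
        data = lines[1:]
        first_line = 2
        if len(file_columns) < 8:
            raise MalformedStoreError(
                f"{path}:1: header has {len(file_columns)} columns, need at least 8"
            )
    else:
        if schema_hint is None:
            raise MalformedStoreError(f"{path}: headerless table requires a schema hint")
        file_columns = schema_hint.columns
        data = lines
        first_line = 1

    gap = (schema_hint or MASTER_SCHEMA).gap_token
    target_columns = schema_hint.columns if schema_hint is not None else file_columns
    rows: list[AnnotatedVariantRow] = []
    style: str | None = None

    for offset, cells in enumerate(data):
        line_no = first_line + offset
        if not cells or (len(cells) == 1 and not cells[0].strip()):
            continue
        if len(cells) < 8:
            raise MalformedStoreError(
                f"{path}:{line_no}: {len(cells)} columns, the 8 VCF core columns are mandatory"
            )
        named = dict(zip(file_columns, cells))
        # columns beyond the named schema are preserved positionally
        extras_positional = {
            f"EXTRA_{i}": v for i, v in enumerate(cells[len(file_columns):])
        }

        try:
            pos = int(named["POS"])
        except ValueError:
            raise MalformedStoreError(
                f"{path}:{line_no}: non-integer POS {named['POS']!r}"
            ) from None
        chrom = named["CHROM"]
        this_style = _chrom_style(chrom)
        if style is None:
            style = this_style
        elif style != this_style:
            raise MalformedStoreError(
                f"{path}:{line_no}: mixed chromosome label styles "
                f"({style} vs {this_style}); normalise the store upstream"
            )
        try:
            key = VariantKey(chrom, pos, named["REF"], named["ALT"])
        except ValueError as exc:
            raise MalformedStoreError(f"{path}:{line_no}: {exc}") from None

        af: dict[str, float | None] = {}
        score: dict[str, float | None] = {}
        omim: dict[str, str | None] = {}
        gene = ""
        protein = None
        clinvar = None
        extras = dict(extras_positional)
        for col in target_columns[8:]:
            raw = named.get(col)
            missing = raw is None or raw == gap or raw == ""
            kind = column_kind(col)
            if kind == "af":
                af[col] = None if missing else _parse_numeric(raw, col, path, line_no, is_af=True)
            elif kind == "score":
                score[col] = None if missing else _parse_numeric(raw, col, path, line_no, is_af=False)
            elif kind == "omim":
                omim[col] = None if missing else raw
            elif kind == "clinvar":
                clinvar = None if missing else raw
            elif kind == "gene":
                gene = "" if missing else raw
            elif kind == "protein":
                protein = None if missing else raw
            else:
                if not missing:
                    extras[col] = raw
        # file columns not covered by the target schema are kept verbatim
        for col in file_columns[8:]:
            if col not in target_columns and col in named and named[col] not in (gap, ""):
                extras[col] = named[col]

        rows.append(AnnotatedVariantRow(
            key=key, sample_id=sample_id, gene=gene, protein_change=protein,
            af_fields=af, score_fields=score, omim_fields=omim,
            clinvar_field=clinvar, extra_fields=extras,
            id_field=named.get("ID", "."), qual=named.get("QUAL", "."),
            filter_field=named.get("FILTER", "."), info=named.get("INFO", "."),
            source_file=analysis,
        ))
    return rows


def _render_cell(value, gap: str) -> str:
    if value is None or value == "":
        return gap
    if isinstance(value, float) and value.is_integer():
        return str(int(value))
    return str(value)


def write_variant_table(rows, schema: AnnotationSchema, path) -> Path:
    """Write rows as a rectangular TSV under ``schema``; missing cells -> gap.

    Raises :class:`SchemaMismatchError` if any row carries a populated column
    the schema cannot express.
    """
    path = Path(path)
    for i, row in enumerate(rows):
        missing = sorted(row.populated_columns() - set(schema.columns))
        if missing:
            raise SchemaMismatchError(
                f"row {i} ({row.key.chrom}:{row.key.pos}) carries columns not in "
                f"schema {schema.version_tag!r}: {missing}"
            )
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write("\t".join(schema.columns) + "\n")
        for row in rows:
            cells = [_render_cell(row.get_cell(col), schema.gap_token) for col in schema.columns]
            fh.write("\t".join(cells) + "\n")
    return path


# ---------------------------------------------------------------------------
# Store scanning
# ---------------------------------------------------------------------------

MANIFEST_NAMES = ("manifest.json", "manifest.yaml", "manifest.yml")


@dataclass
class VariantStore:
    """An indexed collection of analysis files rooted at one directory."""

    root: Path
    files: list[AnalysisFile]

    @property
    def index(self) -> dict[str, list[AnalysisFile]]:
        idx: dict[str, list[AnalysisFile]] = {}
        for f in self.files:
            idx.setdefault(f.sample_id, []).append(f)
        return idx

    def iter_rows(self):
        """Yield every row of every analysis file, in store order."""
        for f in self.files:
            yield from read_variant_table(self.root / f.path, analysis=f)


def load_manifest(path) -> list[dict]:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix == ".json":
        doc = json.loads(text)
    else:
        doc = yaml.safe_load(text)
    if isinstance(doc, dict):
        doc = doc.get("files", [])
    return doc


def scan_store(root) -> VariantStore:
    """Index a store directory via its manifest.

    The listing is sorted by (sample_id, analysis_timestamp, version_tag,
    path) and is therefore independent of filesystem enumeration order.
    An exact (sample, timestamp, version) collision is an ambiguity error.
    """
    root = Path(root)
    if not root.is_dir():
        raise MalformedStoreError(f"store root {root} is not a directory")
    manifest_path = next((root / n for n in MANIFEST_NAMES if (root / n).exists()), None)
    if manifest_path is None:
        if any(root.glob("*.tsv")):
            raise MalformedStoreError(
                f"{root}: variant tables present but no manifest "
                f"({' / '.join(MANIFEST_NAMES)}); analysis timestamps must come "
                "from a manifest, not file mtimes"
            )
        return VariantStore(root=root, files=[])

    files = []
    for i, entry in enumerate(load_manifest(manifest_path)):
        try:
            tag = entry["version_tag"]
            if tag not in SCHEMAS:
                raise MalformedStoreError(
                    f"{manifest_path}: entry {i}: unknown version_tag {tag!r} "
                    f"(known: {sorted(SCHEMAS)})"
                )
            files.append(AnalysisFile(
                path=entry["path"],
                sample_id=entry["sample_id"],
                analysis_timestamp=datetime.fromisoformat(entry["analysis_timestamp"]),
                schema=SCHEMAS[tag],
            ))
        except KeyError as exc:
            raise MalformedStoreError(
                f"{manifest_path}: entry {i} lacks required field {exc}"
            ) from None
    files.sort(key=AnalysisFile.sort_key)
    seen: dict[tuple, str] = {}
    for f in files:
        ident = (f.sample_id, f.analysis_timestamp, f.version_tag)
        if ident in seen and seen[ident] != f.path:
            raise AmbiguousAnalysisError(
                f"sample {f.sample_id}: analyses {seen[ident]!r} and {f.path!r} "
                f"tie on timestamp {f.analysis_timestamp.isoformat()} and "
                f"version {f.version_tag!r}; ordering is undefined"
            )
        seen[ident] = f.path
        if not (root / f.path).exists():
            raise MalformedStoreError(f"manifest references missing file {f.path!r}")
    return VariantStore(root=root, files=files)


def read_vcf(path, schema: AnnotationSchema = MASTER_SCHEMA, *, sample_id: str | None = None):
    """Optional ingestion path: map VCF 4.x records onto annotated rows.

    The eight core columns come from the record itself; INFO keys whose names
    match configured annotation columns are lifted into AF/score fields and
    all other INFO content is ignored.
    """
    from cyvcf2 import VCF  # deferred: optional dependency

    path = str(path)
    if sample_id is None:
        sample_id = Path(path).stem.split(".")[0]
    rows = []
    for rec in VCF(path):
        for alt in rec.ALT:
            af: dict[str, float | None] = {}
            score: dict[str, float | None] = {}
            gene = ""
            for key, value in dict(rec.INFO).items():
                kind = column_kind(key)
                if kind == "af":
                    af[key] = float(value)
                elif kind == "score":
                    score[key] = float(value)
                elif kind == "gene":
                    gene = str(value)
            rows.append(AnnotatedVariantRow(
                key=VariantKey(rec.CHROM, rec.POS, rec.REF, alt),
                sample_id=sample_id, gene=gene,
                af_fields=af, score_fields=score,
                id_field=rec.ID or ".",
                qual="." if rec.QUAL is None else str(rec.QUAL),
                filter_field=rec.FILTER or "PASS",
            ))
    return rows
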