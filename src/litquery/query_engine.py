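"""Whole-word gene queries over the variant store.

Two query generations are modelled.  The *v1* query is the plain
``grep -w GENE`` over every analysis table: raw matched rows, duplicates
across re-analyses included, column sets disordered across pipeline
versions.  The *v2* query post-processes the same hits: re-analysis
duplicates are removed (only the most recent analysis of each sample is
kept) and rows are harmonized onto a master schema with gaps marked, so one
gene query yields one intelligible rectangular table.  The *end-point*
re-query runs all previously searched genes once more against the grown
store and reports only observations not seen before, tracked in an
append-only ledger.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path

from .exceptions import AmbiguousAnalysisError, SchemaMismatchError
from .store_io import (
    MASTER_SCHEMA,
    AnnotatedVariantRow,
    AnnotationSchema,
    VariantKey,
    VariantStore,
    column_kind,
    read_variant_table,
)

#: Word characters for whole-word matching: hyphen included so that HGNC
#: symbols like ``NKX2-5`` are single tokens and ``grep -w``'s "GENE1 must
#: not match GENE10" behaviour is preserved.  Matching is case-sensitive.
_TOKEN_SPLIT = re.compile(r"[^A-Za-z0-9_-]+")


def tokenize(text: str) -> list[str]:
    """Split free text into word tokens under the package word-boundary rule."""
    return [t for t in _TOKEN_SPLIT.split(text) if t]


@dataclass
class QueryResult:
    """Outcome of one gene query in one mode."""

    gene: str
    mode: str  # "v1" | "v2"
    rows: list[AnnotatedVariantRow]
    schema: AnnotationSchema | None = None
    query_timestamp: datetime | None = None

    @property
    def line_count(self) -> int:
        return len(self.rows)


def _row_matches(row: AnnotatedVariantRow, gene: str, columns, full_line: bool) -> bool:
    if full_line:
        return any(gene in tokenize(cell) for cell in row.text_cells(columns))
    return gene in tokenize(row.gene)


def grep_word_v1(
    gene: str,
    store: VariantStore,
    *,
    full_line: bool = False,
    query_timestamp: datetime | None = None,
) -> QueryResult:
    """The basic whole-word query: every matching line of every analysis file.

    Duplicate observations across re-analyses of the same sample are
    retained — that is the v1 semantics.  By default only the gene-symbol
    column is searched; ``full_line=True`` searches every text field of the
    line (true grep emulation).
    """
    if not gene:
        raise ValueError("gene symbol must be non-empty")
    rows: list[AnnotatedVariantRow] = []
    seen_symbol = False
    for f in store.files:
        columns = f.schema.columns
        for row in read_variant_table(store.root / f.path, analysis=f):
            if gene in tokenize(row.gene):
                seen_symbol = True
            if _row_matches(row, gene, columns, full_line):
                rows.append(row)
    if store.files and not seen_symbol:
        warnings.warn(
            f"symbol {gene!r} absent from every file in the store "
            "(no alias resolution is attempted)",
            UserWarning,
            stacklevel=2,
        )
    return QueryResult(gene=gene, mode="v1", rows=rows, query_timestamp=query_timestamp)


def dedup_latest(rows: list[AnnotatedVariantRow]) -> list[AnnotatedVariantRow]:
    """Keep, per (sample, variant), only the most recently analyzed row.

    Ties on timestamp break by pipeline version tag descending, then path;
    a hard tie is ambiguous and raises.  Output order is deterministic:
    sample, then genomic position.
    """
    best: dict[tuple[str, VariantKey], AnnotatedVariantRow] = {}
    for row in rows:
        if row.source_file is None or row.source_file.analysis_timestamp is None:
            raise ValueError(
                f"row {row.key.chrom}:{row.key.pos} in sample {row.sample_id!r} "
                "has no analysis timestamp; cannot deduplicate"
            )
        ident = (row.sample_id, row.key)
        incumbent = best.get(ident)
        if incumbent is None:
            best[ident] = row
            continue
        a, b = incumbent.source_file, row.source_file
        rank_a = (a.analysis_timestamp, a.version_tag, a.path)
        rank_b = (b.analysis_timestamp, b.version_tag, b.path)
        if rank_a == rank_b and a.path == b.path:
            # duplicate line within one file: keep first
            continue
        if rank_a == rank_b:
            raise AmbiguousAnalysisError(
                f"sample {row.sample_id}: analyses {a.path!r} and {b.path!r} tie "
                "on timestamp and version; 'most recent' is undefined"
            )
        if rank_b > rank_a:
            best[ident] = row
    return [best[k] for k in sorted(best, key=lambda t: (t[0], t[1]))]


def harmonize_rows(
    rows: list[AnnotatedVariantRow], master: AnnotationSchema = MASTER_SCHEMA
) -> list[AnnotatedVariantRow]:
    """Express every row under the master schema, gaps marked missing.

    Rows from older pipeline versions gain explicit missing entries for the
    annotations their schema lacked, so that all rows are rectangular under
    ``master``.  A row carrying a column the master cannot express raises
    :class:`SchemaMismatchError` naming the column.
    """
    master_cols = set(master.columns)
    out = []
    for row in rows:
        unexpressible = sorted(row.populated_columns() - master_cols)
        if unexpressible:
            raise SchemaMismatchError(
                f"row {row.key.chrom}:{row.key.pos} carries columns absent from "
                f"master schema: {unexpressible}"
            )
        af = dict(row.af_fields)
        score = dict(row.score_fields)
        omim = dict(row.omim_fields)
        for col in master.annotation_columns:
            kind = column_kind(col)
            if kind == "af":
                af.setdefault(col, None)
            elif kind == "score":
                score.setdefault(col, None)
            elif kind == "omim":
                omim.setdefault(col, None)
        out.append(replace(row, af_fields=af, score_fields=score, omim_fields=omim))
    return out


def query_gene_v2(
    gene: str,
    store: VariantStore,
    master: AnnotationSchema = MASTER_SCHEMA,
    *,
    full_line: bool = False,
    query_timestamp: datetime | None = None,
) -> QueryResult:
    """The scripted query: whole-word match, dedup-latest, harmonize."""
    v1 = grep_word_v1(gene, store, full_line=full_line, query_timestamp=query_timestamp)
    rows = harmonize_rows(dedup_latest(v1.rows), master)
    return QueryResult(
        gene=gene, mode="v2", rows=rows, schema=master, query_timestamp=query_timestamp
    )


# ---------------------------------------------------------------------------
# End-point re-query
# ---------------------------------------------------------------------------


@dataclass
class SeenLedger:
    """Append-only record of (gene, sample, variant) observations reported."""

    entries: dict[tuple[str, str, VariantKey], str] = field(default_factory=dict)

    def __contains__(self, item: tuple[str, str, VariantKey]) -> bool:
        return item in self.entries

    def add(self, gene: str, sample_id: str, key: VariantKey, first_seen: str = "") -> None:
        self.entries.setdefault((gene, sample_id, key), first_seen)

    @classmethod
    def load(cls, path) -> "SeenLedger":
        ledger = cls()
        path = Path(path)
        if not path.exists():
            return ledger
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                rec = json.loads(line)
                key = VariantKey(rec["chrom"], rec["pos"], rec["ref"], rec["alt"])
                ledger.add(rec["gene"], rec["sample"], key, rec.get("first_seen", ""))
        return ledger

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for (gene, sample, key), first_seen in sorted(
                self.entries.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2])
            ):
                fh.write(json.dumps({
                    "gene": gene, "sample": sample, "chrom": key.chrom,
                    "pos": key.pos, "ref": key.ref, "alt": key.alt,
                    "first_seen": first_seen,
                }) + "\n")


def requery_endpoint(
    alerts,
    store: VariantStore,
    ledger: SeenLedger,
    *,
    query_timestamp: datetime | None = None,
) -> dict[str, QueryResult]:
    """Re-run v2 queries for all alert genes; return only unseen observations.

    The ledger is updated in place with every returned (gene, sample,
    variant) entry, so repeating the call on an unchanged store yields empty
    deltas and the union of incremental deltas over a growing store equals a
    single final query.
    """
    stamp = "" if query_timestamp is None else query_timestamp.isoformat()
    genes = sorted({a.gene for a in alerts})
    out: dict[str, QueryResult] = {}
    for gene in genes:
        result = query_gene_v2(gene, store, query_timestamp=query_timestamp)
        fresh = [r for r in result.rows if (gene, r.sample_id, r.key) not in ledger]
        for row in fresh:
            ledger.add(gene, row.sample_id, row.key, stamp)
        out[gene] = replace(result, rows=fresh)
    return out
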