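"""Gene-alert records: the structured output of literature monitoring.

Each alert captures one publication-to-gene event worth re-querying the
exome store for: the gene symbol, when it was published, whether it is a
novel disorder gene / a phenotype expansion / a second disorder for a known
gene, its OMIM status at alert time (a snapshot — newly published genes lag
OMIM indexing, which is the point of monitoring the literature directly),
the reported inheritance modes, the reported variant classes, and optional
protein-domain intervals for domain-restricted missense matching.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from pathlib import Path

from .exceptions import AlertValidationError


class AssociationCategory(str, Enum):
    NOVEL_DISORDER = "novel_disorder"
    PHENOTYPE_UPDATE = "phenotype_update"
    DISTINCT_DISORDER_KNOWN_GENE = "distinct_disorder_known_gene"


class OmimStatus(str, Enum):
    MORBID = "morbid"
    NON_MORBID = "non_morbid"
    ABSENT = "absent"


class InheritanceMode(str, Enum):
    DE_NOVO_DOMINANT = "de_novo_dominant"
    AUTOSOMAL_DOMINANT_INHERITED = "autosomal_dominant_inherited"
    AUTOSOMAL_RECESSIVE = "autosomal_recessive"
    X_LINKED = "x_linked"


class VariantClass(str, Enum):
    PROTEIN_TRUNCATING = "protein_truncating"
    MISSENSE_IN_DOMAIN = "missense_in_domain"
    MISSENSE_ANY = "missense_any"
    SPLICE = "splice"


@dataclass(frozen=True)
class DomainInterval:
    """1-based, closed amino-acid interval of a protein domain."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise AlertValidationError(
                f"domain interval [{self.start}, {self.end}] must satisfy 1 <= start <= end"
            )

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class GeneAlert:
    gene: str
    publication_date: date
    association_category: AssociationCategory
    omim_status: OmimStatus
    inheritance_modes: frozenset[InheritanceMode]
    reported_variant_classes: frozenset[VariantClass]
    domains: tuple[DomainInterval, ...] = ()
    source_ref: str = ""

    def __post_init__(self) -> None:
        if not self.gene:
            raise AlertValidationError("alert gene symbol must be non-empty")
        if not self.inheritance_modes:
            raise AlertValidationError(f"alert {self.gene}: at least one inheritance mode required")
        if not self.reported_variant_classes:
            raise AlertValidationError(f"alert {self.gene}: at least one variant class required")


@dataclass
class AlertSet:
    alerts: list[GeneAlert]
    period: tuple[date, date] | None = None

    def __post_init__(self) -> None:
        seen = set()
        for a in self.alerts:
            ident = (a.gene, a.source_ref)
            if ident in seen:
                raise AlertValidationError(
                    f"duplicate alert for gene {a.gene!r} with source {a.source_ref!r}"
                )
            seen.add(ident)

    def genes(self) -> list[str]:
        out, seen = [], set()
        for a in self.alerts:
            if a.gene not in seen:
                seen.add(a.gene)
                out.append(a.gene)
        return out

    def category_counts(self) -> dict[AssociationCategory, int]:
        counts = {c: 0 for c in AssociationCategory}
        for a in self.alerts:
            counts[a.association_category] += 1
        return counts


# ---------------------------------------------------------------------------
# File format: one record per line, TSV, JSON column for domains
# ---------------------------------------------------------------------------

ALERT_COLUMNS = (
    "gene", "publication_date", "association_category", "omim_status",
    "inheritance_modes", "reported_variant_classes", "domains", "source_ref",
)


def _enum_value(enum_cls, token: str, record: str):
    try:
        return enum_cls(token)
    except ValueError:
        raise AlertValidationError(
            f"record {record}: unknown {enum_cls.__name__} token {token!r} "
            f"(allowed: {[e.value for e in enum_cls]})"
        ) from None


def _record_from_fields(fields: dict[str, str], record: str) -> GeneAlert:
    gene = fields.get("gene", "").strip()
    if not gene:
        raise AlertValidationError(f"record {record}: empty gene symbol")
    modes = frozenset(
        _enum_value(InheritanceMode, tok.strip(), record)
        for tok in fields["inheritance_modes"].split(",") if tok.strip()
    )
    classes = frozenset(
        _enum_value(VariantClass, tok.strip(), record)
        for tok in fields["reported_variant_classes"].split(",") if tok.strip()
    )
    raw_domains = fields.get("domains", "").strip()
    domains: tuple[DomainInterval, ...] = ()
    if raw_domains and raw_domains != ".":
        parsed = json.loads(raw_domains)
        domains = tuple(DomainInterval(int(s), int(e)) for s, e in parsed)
    return GeneAlert(
        gene=gene,
        publication_date=date.fromisoformat(fields["publication_date"]),
        association_category=_enum_value(AssociationCategory, fields["association_category"], record),
        omim_status=_enum_value(OmimStatus, fields["omim_status"], record),
        inheritance_modes=modes,
        reported_variant_classes=classes,
        domains=domains,
        source_ref=fields.get("source_ref", "").strip(),
    )


def parse_alert_file(path) -> AlertSet:
    """Load an alert TSV (or the equivalent ``.json`` form) into an AlertSet.

    TSV dialect: ``#`` comment lines, a header naming :data:`ALERT_COLUMNS`,
    one record per line, comma-separated vocabulary tokens, a JSON column for
    domain intervals ("." when none).
    """
    path = Path(path)
    if path.suffix == ".json":
        doc = json.loads(path.read_text(encoding="utf-8"))
        alerts = []
        for i, rec in enumerate(doc.get("alerts", [])):
            record = f"{path}#{i}"
            gene = rec.get("gene", "").strip()
            if not gene:
                raise AlertValidationError(f"record {record}: empty gene symbol")
            alerts.append(GeneAlert(
                gene=gene,
                publication_date=date.fromisoformat(rec["publication_date"]),
                association_category=_enum_value(
                    AssociationCategory, rec["association_category"], record),
                omim_status=_enum_value(OmimStatus, rec["omim_status"], record),
                inheritance_modes=frozenset(
                    _enum_value(InheritanceMode, t, record)
                    for t in rec["inheritance_modes"]),
                reported_variant_classes=frozenset(
                    _enum_value(VariantClass, t, record)
                    for t in rec["reported_variant_classes"]),
                domains=tuple(DomainInterval(int(s), int(e)) for s, e in rec.get("domains", [])),
                source_ref=rec.get("source_ref", ""),
            ))
        period = None
        if doc.get("period"):
            period = (date.fromisoformat(doc["period"][0]), date.fromisoformat(doc["period"][1]))
        return AlertSet(alerts=alerts, period=period)

    lines = [
        ln for ln in path.read_text(encoding="utf-8").splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines:
        return AlertSet(alerts=[])
    header = lines[0].split("\t")
    alerts = []
    for i, ln in enumerate(lines[1:], start=2):
        fields = dict(zip(header, ln.split("\t")))
        alerts.append(_record_from_fields(fields, record=f"{path}:{i}"))
    return AlertSet(alerts=alerts)


def serialize_alert_file(alert_set: AlertSet, path) -> Path:
    """Write an AlertSet back to the TSV dialect (inverse of parsing)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(ALERT_COLUMNS) + "\n")
        for a in alert_set.alerts:
            domains = (
                json.dumps([[d.start, d.end] for d in a.domains]) if a.domains else "."
            )
            fh.write("\t".join([
                a.gene,
                a.publication_date.isoformat(),
                a.association_category.value,
                a.omim_status.value,
                ",".join(sorted(m.value for m in a.inheritance_modes)),
                ",".join(sorted(c.value for c in a.reported_variant_classes)),
                domains,
                a.source_ref,
            ]) + "\n")
    return path
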