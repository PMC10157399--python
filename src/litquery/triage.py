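"""Rare-variant filtration and alert-driven candidate matching.

A query hit becomes a *candidate* only when it survives the rarity gate
(maximum population allele frequency strictly below the threshold, 1% by
default) and matches the driving alert on both the reported variant class
(protein-truncating / missense, optionally domain-restricted / splice) and
the reported inheritance pattern, judged from stated family segregation.

One deliberate asymmetry mirrors diagnostic practice: under a de-novo-only
alert, a class-matching variant inherited from an asymptomatic parent is
*not* discarded — it is emitted tagged ``inherited-from-asymptomatic-parent``
so the classification layer can hold it at VUS rather than losing it.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from .alerts import GeneAlert, InheritanceMode, VariantClass
from .exceptions import ConfigError, ParseWarning
from .store_io import AF_COLUMNS, AnnotatedVariantRow


class EffectClass(str, Enum):
    PROTEIN_TRUNCATING = "protein_truncating"
    MISSENSE = "missense"
    INFRAME_INDEL = "inframe_indel"
    UNKNOWN_SPLICE = "unknown_splice"


class SegregationStatus(str, Enum):
    DE_NOVO = "de_novo"
    MATERNALLY_INHERITED = "maternally_inherited"
    PATERNALLY_INHERITED = "paternally_inherited"
    BIPARENTAL = "biparental"
    NOT_MATERNAL = "not_maternal"
    NOT_PATERNAL = "not_paternal"
    UNKNOWN = "unknown"


#: Table-vocabulary spellings accepted (case-insensitively) in segregation
#: files; "ND" (not determined) maps to unknown.
_SEGREGATION_TOKENS = {
    "de novo": SegregationStatus.DE_NOVO,
    "maternally inherited": SegregationStatus.MATERNALLY_INHERITED,
    "paternally inherited": SegregationStatus.PATERNALLY_INHERITED,
    "probable paternal inheritance": SegregationStatus.PATERNALLY_INHERITED,
    "probable maternal inheritance": SegregationStatus.MATERNALLY_INHERITED,
    "paternally and maternally inherited": SegregationStatus.BIPARENTAL,
    "maternally and paternally inherited": SegregationStatus.BIPARENTAL,
    "not maternally inherited": SegregationStatus.NOT_MATERNAL,
    "not paternally inherited": SegregationStatus.NOT_PATERNAL,
    "nd": SegregationStatus.UNKNOWN,
    "unknown": SegregationStatus.UNKNOWN,
}

_INHERITED = frozenset({
    SegregationStatus.MATERNALLY_INHERITED,
    SegregationStatus.PATERNALLY_INHERITED,
})

#: Which stated segregations are compatible with each reported mode.
#: "Not maternal"/"not paternal" leave de novo open, so they stay compatible
#: with de-novo-dominant reports (one Table-vocabulary case in point: a
#: not-maternally-inherited truncating variant can still be causative).
_MODE_COMPAT: dict[InheritanceMode, frozenset[SegregationStatus]] = {
    InheritanceMode.DE_NOVO_DOMINANT: frozenset({
        SegregationStatus.DE_NOVO,
        SegregationStatus.NOT_MATERNAL,
        SegregationStatus.NOT_PATERNAL,
    }),
    InheritanceMode.AUTOSOMAL_DOMINANT_INHERITED: frozenset({
        SegregationStatus.DE_NOVO,
        SegregationStatus.MATERNALLY_INHERITED,
        SegregationStatus.PATERNALLY_INHERITED,
        SegregationStatus.NOT_MATERNAL,
        SegregationStatus.NOT_PATERNAL,
    }),
    InheritanceMode.AUTOSOMAL_RECESSIVE: frozenset({
        SegregationStatus.BIPARENTAL,
    }),
    InheritanceMode.X_LINKED: frozenset({
        SegregationStatus.DE_NOVO,
        SegregationStatus.MATERNALLY_INHERITED,
        SegregationStatus.NOT_PATERNAL,
    }),
}


def parse_segregation_token(token: str) -> SegregationStatus:
    try:
        return _SEGREGATION_TOKENS[token.strip().lower()]
    except KeyError:
        raise ValueError(f"unknown segregation token {token!r}") from None


def parse_segregation_file(path) -> dict:
    """Stated segregations from a TSV (tokens parsed case-insensitively).

    Two columns give a sample-wide status (``sample<TAB>status``); an
    optional middle column ``chrom:pos:ref:alt`` scopes the status to one
    variant, which is how opposite parental origins of a compound-
    heterozygote pair are stated.
    """
    from .store_io import VariantKey  # local: avoid cycle at import time

    out: dict = {}
    for i, ln in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), start=1):
        if not ln.strip() or ln.startswith("#"):
            continue
        parts = ln.split("\t")
        if len(parts) == 2:
            out[parts[0].strip()] = parse_segregation_token(parts[1])
        elif len(parts) == 3:
            chrom, pos, ref, alt = parts[1].strip().split(":")
            out[(parts[0].strip(), VariantKey(chrom, int(pos), ref, alt))] = (
                parse_segregation_token(parts[2])
            )
        else:
            raise ValueError(f"{path}:{i}: expected 'sample[<TAB>variant]<TAB>status'")
    return out


def segregation_for(row: AnnotatedVariantRow, segregations: dict) -> SegregationStatus:
    """Row-level lookup: a (sample, variant) entry overrides the sample-wide one."""
    return segregations.get(
        (row.sample_id, row.key),
        segregations.get(row.sample_id, SegregationStatus.UNKNOWN),
    )


# ---------------------------------------------------------------------------
# HGVS-p effect classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantEffect:
    effect_class: EffectClass
    protein_position: int | None = None


_AA3 = r"(?:[A-Z][a-z]{2})"
_P_PREFIX = re.compile(r"^p\.\(?|\)$")
_SUBSTITUTION = re.compile(rf"^({_AA3})(\d+)({_AA3}|\*)$")
_LEAD_POSITION = re.compile(rf"^{_AA3}(\d+)")


def classify_variant_effect(protein_change: str) -> VariantEffect:
    """Classify an HGVS-p string into the triage effect vocabulary.

    Frameshifts, stop gains (``*``/``Ter``) -> protein-truncating;
    single-residue substitutions -> missense with parsed position;
    in-frame ``del``/``dup`` without frameshift -> in-frame indel;
    ``p.?`` (and any unparseable string, with a warning) -> unknown splice
    effect, the notation used for intronic/splice-site changes whose protein
    consequence is unassessed.
    """
    if not protein_change:
        raise ValueError("protein change string must be non-empty")
    body = _P_PREFIX.sub("", protein_change.strip())
    if body == "?":
        return VariantEffect(EffectClass.UNKNOWN_SPLICE)

    lead = _LEAD_POSITION.match(body)
    position = int(lead.group(1)) if lead else None

    if "fs" in body:
        return VariantEffect(EffectClass.PROTEIN_TRUNCATING, position)
    m = _SUBSTITUTION.match(body)
    if m:
        if m.group(3) in ("*", "Ter"):
            return VariantEffect(EffectClass.PROTEIN_TRUNCATING, position)
        return VariantEffect(EffectClass.MISSENSE, position)
    if body.endswith("*") or body.endswith("Ter"):
        return VariantEffect(EffectClass.PROTEIN_TRUNCATING, position)
    if position is not None and (body.endswith("del") or body.endswith("dup")):
        return VariantEffect(EffectClass.INFRAME_INDEL, position)
    warnings.warn(
        f"unparseable protein change {protein_change!r}; treated as unknown splice effect",
        ParseWarning,
        stacklevel=2,
    )
    return VariantEffect(EffectClass.UNKNOWN_SPLICE)


# ---------------------------------------------------------------------------
# Rarity filter
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TriageConfig:
    """Tunable triage thresholds.

    ``af_threshold`` is a fraction (default 0.01, i.e. rare means every
    population allele frequency strictly below 1%); ``af_sources`` the
    ordered frequency fields aggregated by maximum (most conservative);
    missing frequencies count as rare by default (a variant absent from all
    population panels is the typical novel-disease situation).  The LoF
    constraint flags mark truncating candidates in intolerant genes
    (pLI > 0.9 or o/e < 0.3).
    """

    af_threshold: float = 0.01
    af_sources: tuple[str, ...] = AF_COLUMNS
    lof_pli_threshold: float = 0.9
    lof_oe_threshold: float = 0.3
    treat_missing_af_as_rare: bool = True
    splice_requires_alert_class: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.af_threshold <= 1.0):
            raise ConfigError(f"af_threshold must be in (0, 1], got {self.af_threshold}")
        unknown = [s for s in self.af_sources if s not in AF_COLUMNS]
        if unknown:
            raise ConfigError(
                f"unknown AF source(s) {unknown}; known sources: {list(AF_COLUMNS)}"
            )
        if not self.af_sources:
            raise ConfigError("at least one AF source required")


def filter_rare(
    rows: list[AnnotatedVariantRow], cfg: TriageConfig = TriageConfig()
) -> list[AnnotatedVariantRow]:
    """Keep rows whose maximum population AF is strictly below the threshold."""
    kept = []
    for row in rows:
        values = [row.af_fields.get(s) for s in cfg.af_sources]
        present = [v for v in values if v is not None]
        if not present:
            if cfg.treat_missing_af_as_rare:
                kept.append(row)
        elif max(present) < cfg.af_threshold:
            kept.append(row)
    return kept


def is_lof_constrained(row: AnnotatedVariantRow, cfg: TriageConfig = TriageConfig()) -> bool:
    """True when the gene's constraint metrics mark it LoF-intolerant."""
    pli = row.score_fields.get("PLI")
    oe = row.score_fields.get("OE")
    return (pli is not None and pli > cfg.lof_pli_threshold) or (
        oe is not None and oe < cfg.lof_oe_threshold
    )


# ---------------------------------------------------------------------------
# Candidate matching
# ---------------------------------------------------------------------------


@dataclass
class CandidateVariant:
    """A triaged hit: one row matched against one alert."""

    row: AnnotatedVariantRow
    alert: GeneAlert
    effect: VariantEffect
    segregation: SegregationStatus
    match_reasons: list[str]
    criteria: set[str] = field(default_factory=set)
    classification: "object | None" = None  # acmg.Classification, set downstream
    flags: list[str] = field(default_factory=list)
    reclassification_log: list[dict] = field(default_factory=list)
    lof_constrained: bool = False


def _class_match_reasons(effect: VariantEffect, alert: GeneAlert) -> list[str]:
    reasons = []
    classes = alert.reported_variant_classes
    if effect.effect_class is EffectClass.PROTEIN_TRUNCATING:
        if VariantClass.PROTEIN_TRUNCATING in classes:
            reasons.append("class:protein-truncating")
    elif effect.effect_class in (EffectClass.MISSENSE, EffectClass.INFRAME_INDEL):
        # in-frame single-residue indels are matched under the missense
        # classes: a residue-level change, domain rule applies when the
        # position parses
        label = "missense" if effect.effect_class is EffectClass.MISSENSE else "inframe"
        if VariantClass.MISSENSE_ANY in classes:
            reasons.append(f"class:{label}-any")
        if (
            VariantClass.MISSENSE_IN_DOMAIN in classes
            and effect.protein_position is not None
            and any(effect.protein_position in d for d in alert.domains)
        ):
            reasons.append(f"class:{label}-in-domain")
    elif effect.effect_class is EffectClass.UNKNOWN_SPLICE:
        if VariantClass.SPLICE in classes:
            reasons.append("class:splice")
    return reasons


_PENDING = "recessive-carrier-pending"


def _inheritance_reasons(
    segregation: SegregationStatus, alert: GeneAlert
) -> tuple[list[str], bool]:
    """(reasons, keep) under the alert's inheritance modes.

    A singly-inherited variant under a recessive alert is kept provisionally
    (tag ``recessive-carrier-pending``): it only survives matching if the
    compound-heterozygote pairing pass finds a trans partner.
    """
    if segregation is SegregationStatus.UNKNOWN:
        return ["inheritance:unknown"], True
    compatible = [
        m for m in sorted(alert.inheritance_modes, key=lambda m: m.value)
        if segregation in _MODE_COMPAT[m]
    ]
    if compatible:
        return [f"inheritance:{m.value}" for m in compatible], True
    reasons = []
    if InheritanceMode.DE_NOVO_DOMINANT in alert.inheritance_modes and segregation in _INHERITED:
        # retained, not discarded: the classifier holds these at VUS
        reasons.append("inherited-from-asymptomatic-parent")
    if InheritanceMode.AUTOSOMAL_RECESSIVE in alert.inheritance_modes and segregation in _INHERITED:
        reasons.append(_PENDING)
    return reasons, bool(reasons)


def match_candidates(
    rows: list[AnnotatedVariantRow],
    alert: GeneAlert,
    segregations: dict[str, SegregationStatus],
    cfg: TriageConfig = TriageConfig(),
) -> list[CandidateVariant]:
    """Match rare-filtered rows of the alert's gene against the alert.

    A row becomes a candidate iff its effect class is among the alert's
    reported classes (missense-in-domain additionally requires the parsed
    protein position to fall inside an alert domain interval; an unknown
    splice effect matches only when the alert reports splice variants) and
    its stated segregation is compatible with an alert inheritance mode, or
    unknown.  Rows are re-checked against the rarity gate so the pipeline
    ordering cannot be violated by a caller.
    """
    if not alert.reported_variant_classes:
        raise ConfigError(f"alert {alert.gene}: no reported variant classes")
    for row in rows:
        if alert.gene not in row.gene.split(";") and row.gene != alert.gene:
            raise ValueError(
                f"row gene {row.gene!r} does not match alert gene {alert.gene!r}; "
                "restrict rows to the alert gene before matching"
            )
    rows = filter_rare(rows, cfg)

    candidates: list[CandidateVariant] = []
    for row in rows:
        if row.protein_change is None:
            continue
        effect = classify_variant_effect(row.protein_change)
        if (
            effect.effect_class is EffectClass.UNKNOWN_SPLICE
            and not cfg.splice_requires_alert_class
        ):
            class_reasons = ["class:splice-permissive"]
        else:
            class_reasons = _class_match_reasons(effect, alert)
        if not class_reasons:
            continue
        segregation = segregation_for(row, segregations)
        inh_reasons, keep = _inheritance_reasons(segregation, alert)
        if not keep:
            continue
        candidates.append(CandidateVariant(
            row=row, alert=alert, effect=effect, segregation=segregation,
            match_reasons=class_reasons + inh_reasons,
            lof_constrained=(
                effect.effect_class is EffectClass.PROTEIN_TRUNCATING
                and is_lof_constrained(row, cfg)
            ),
        ))

    if InheritanceMode.AUTOSOMAL_RECESSIVE in alert.inheritance_modes:
        _tag_compound_heterozygotes(candidates)
    # unpaired recessive carriers (pending tag never upgraded) are dropped
    def _has_inheritance_reason(c: CandidateVariant) -> bool:
        return any(
            r.startswith("inheritance:")
            or r in ("inherited-from-asymptomatic-parent", "recessive-biparental")
            for r in c.match_reasons
        )

    resolved = []
    for c in candidates:
        if _PENDING in c.match_reasons:
            c.match_reasons.remove(_PENDING)
            if not _has_inheritance_reason(c):
                continue
        resolved.append(c)
    resolved.sort(key=lambda c: (c.row.sample_id, c.row.key))
    return resolved


def _tag_compound_heterozygotes(candidates: list[CandidateVariant]) -> None:
    """Tag same-sample candidate pairs with opposite parental origins.

    Phase is taken from stated segregation only: one maternally and one
    paternally inherited candidate in the same gene and sample are treated
    as a trans pair satisfying the recessive model, as is any single
    biparental (homozygous) candidate.
    """
    by_sample: dict[str, list[CandidateVariant]] = {}
    for c in candidates:
        by_sample.setdefault(c.row.sample_id, []).append(c)
    for group in by_sample.values():
        origins = {c.segregation for c in group}
        if (
            SegregationStatus.MATERNALLY_INHERITED in origins
            and SegregationStatus.PATERNALLY_INHERITED in origins
        ):
            for c in group:
                if c.segregation in _INHERITED and "recessive-biparental" not in c.match_reasons:
                    c.match_reasons.append("recessive-biparental")
        for c in group:
            if (
                c.segregation is SegregationStatus.BIPARENTAL
                and "recessive-biparental" not in c.match_reasons
            ):
                c.match_reasons.append("recessive-biparental")
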