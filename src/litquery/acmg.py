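"""ACMG-AMP evidence combination and segregation-driven reclassification.

Evidence codes (PVS1, PS1-4, PM1-6, PP1-5 on the pathogenic side; BA1,
BS1-4, BP1-7 on the benign side) carry fixed strengths and are combined by
the standard rule table into a five-tier classification.  No
laboratory-specific strength modifications are applied: strength is a pure
function of the code.  Codes are supplied by the analyst or by the triage
layer's explicit mappings; this module never derives evidence from raw
annotations itself.

Classification semantics: the pathogenic-side rules (pathogenic first, then
likely pathogenic) and the benign-side rules are evaluated independently;
satisfying rules on both sides yields VUS with rationale ``conflicting``,
satisfying neither yields VUS ``insufficient``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from enum import Enum

from .alerts import GeneAlert, InheritanceMode
from .exceptions import UnknownCriterionError
from .triage import CandidateVariant, SegregationStatus


class Strength(str, Enum):
    VERY_STRONG = "very_strong"
    STRONG = "strong"
    MODERATE = "moderate"
    SUPPORTING = "supporting"
    STAND_ALONE_BENIGN = "stand_alone_benign"
    STRONG_BENIGN = "strong_benign"
    SUPPORTING_BENIGN = "supporting_benign"


#: strength is a pure function of the code
CRITERIA: dict[str, Strength] = {
    "PVS1": Strength.VERY_STRONG,
    **{f"PS{i}": Strength.STRONG for i in range(1, 5)},
    **{f"PM{i}": Strength.MODERATE for i in range(1, 7)},
    **{f"PP{i}": Strength.SUPPORTING for i in range(1, 6)},
    "BA1": Strength.STAND_ALONE_BENIGN,
    **{f"BS{i}": Strength.STRONG_BENIGN for i in range(1, 5)},
    **{f"BP{i}": Strength.SUPPORTING_BENIGN for i in range(1, 8)},
}


class Tier(str, Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    VUS = "VUS"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"


#: order used by the monotonicity contract (pathogenic end first)
TIER_ORDER = (
    Tier.PATHOGENIC, Tier.LIKELY_PATHOGENIC, Tier.VUS, Tier.LIKELY_BENIGN, Tier.BENIGN,
)


@dataclass(frozen=True)
class Classification:
    value: Tier
    rationale: str


_CODE_TOKEN = re.compile(r"\b(PVS1|PS[1-4]|PM[1-6]|PP[1-5]|BA1|BS[1-4]|BP[1-7])\b")


def parse_criteria_string(text: str) -> set[str]:
    """Extract evidence codes from free text like ``"PM1, PM2, and PP5"``."""
    return set(_CODE_TOKEN.findall(text))


def _validate(codes) -> set[str]:
    codes = set(codes)
    unknown = sorted(c for c in codes if c not in CRITERIA)
    if unknown:
        raise UnknownCriterionError(f"unknown evidence code(s): {unknown}")
    return codes


def combine_criteria(codes) -> Classification:
    """Combine a set of evidence codes into a five-tier classification."""
    codes = _validate(codes)
    n = {s: 0 for s in Strength}
    for c in codes:
        n[CRITERIA[c]] += 1
    pvs, ps, pm, pp = (
        n[Strength.VERY_STRONG], n[Strength.STRONG],
        n[Strength.MODERATE], n[Strength.SUPPORTING],
    )
    ba, bs, bp = (
        n[Strength.STAND_ALONE_BENIGN], n[Strength.STRONG_BENIGN],
        n[Strength.SUPPORTING_BENIGN],
    )

    path: tuple[Tier, str] | None = None
    if pvs >= 1 and (ps >= 1 or pm >= 2 or (pm == 1 and pp == 1) or pp >= 2):
        path = (Tier.PATHOGENIC, "PVS1+support")
    elif ps >= 2:
        path = (Tier.PATHOGENIC, ">=2 strong")
    elif ps == 1 and (pm >= 3 or (pm == 2 and pp >= 2) or (pm == 1 and pp >= 4)):
        path = (Tier.PATHOGENIC, "strong+moderate/supporting")
    elif pvs >= 1 and pm >= 1:
        path = (Tier.LIKELY_PATHOGENIC, "PVS1+moderate")
    elif ps == 1 and pm >= 1:
        path = (Tier.LIKELY_PATHOGENIC, "strong+1-2 moderate")
    elif ps == 1 and pp >= 2:
        path = (Tier.LIKELY_PATHOGENIC, "strong+>=2 supporting")
    elif pm >= 3:
        path = (Tier.LIKELY_PATHOGENIC, ">=3 moderate")
    elif pm == 2 and pp >= 2:
        path = (Tier.LIKELY_PATHOGENIC, "2 moderate+>=2 supporting")
    elif pm == 1 and pp >= 4:
        path = (Tier.LIKELY_PATHOGENIC, "1 moderate+>=4 supporting")

    benign: tuple[Tier, str] | None = None
    if ba >= 1:
        benign = (Tier.BENIGN, "BA1")
    elif bs >= 2:
        benign = (Tier.BENIGN, ">=2 strong benign")
    elif bs == 1 and bp >= 1:
        benign = (Tier.LIKELY_BENIGN, "strong+supporting benign")
    elif bp >= 2:
        benign = (Tier.LIKELY_BENIGN, ">=2 supporting benign")

    if path and benign:
        return Classification(Tier.VUS, "conflicting")
    if path:
        return Classification(*path)
    if benign:
        return Classification(*benign)
    return Classification(Tier.VUS, "insufficient")


def classify_candidate(candidate: CandidateVariant) -> CandidateVariant:
    """Fill a candidate's classification from its evidence-code set."""
    candidate.classification = combine_criteria(candidate.criteria)
    return candidate


def apply_segregation_evidence(
    candidate: CandidateVariant,
    alert: GeneAlert | None = None,
    *,
    trio_confirmed: bool = False,
) -> CandidateVariant:
    """Reconcile a provisional classification with stated family segregation.

    Under an alert reporting only de novo occurrences, a variant inherited
    from an asymptomatic parent cannot keep a pathogenic call: any P/LP is
    downgraded to VUS with rationale ``inherited-unreported`` and the event
    is logged with before/after.  A confirmed de novo occurrence under a
    de novo alert adds PS2 (trio confirmation required).  Unknown
    segregation leaves the classification untouched and flags the candidate
    ``segregation-pending``.  The operation is idempotent.
    """
    if alert is None:
        alert = candidate.alert
    if candidate.classification is None:
        candidate = classify_candidate(candidate)

    if candidate.segregation is SegregationStatus.UNKNOWN:
        if "segregation-pending" not in candidate.flags:
            candidate.flags.append("segregation-pending")
        return candidate

    de_novo_only = alert.inheritance_modes == frozenset({InheritanceMode.DE_NOVO_DOMINANT})
    inherited = candidate.segregation in (
        SegregationStatus.MATERNALLY_INHERITED, SegregationStatus.PATERNALLY_INHERITED,
    )
    if de_novo_only and inherited:
        if candidate.classification.value in (Tier.PATHOGENIC, Tier.LIKELY_PATHOGENIC):
            before = candidate.classification
            candidate.classification = Classification(Tier.VUS, "inherited-unreported")
            candidate.reclassification_log.append({
                "before": before.value.value,
                "after": Tier.VUS.value,
                "reason": "inherited-unreported",
            })
        return candidate

    if (
        candidate.segregation is SegregationStatus.DE_NOVO
        and InheritanceMode.DE_NOVO_DOMINANT in alert.inheritance_modes
        and trio_confirmed
        and "PS2" not in candidate.criteria
    ):
        before = candidate.classification
        candidate.criteria.add("PS2")
        candidate.classification = combine_criteria(candidate.criteria)
        if candidate.classification != before:
            candidate.reclassification_log.append({
                "before": before.value.value,
                "after": candidate.classification.value.value,
                "reason": "de-novo-confirmed-PS2",
            })
    return candidate


def supersede_alert(candidate: CandidateVariant, new_alert: GeneAlert) -> CandidateVariant:
    """Re-evaluate a candidate under a newer alert record for the same gene.

    Later publications can change the reported inheritance or add evidence;
    history is never mutated — a fresh candidate is returned carrying the new
    alert, with the prior classification preserved in the log.
    """
    if new_alert.gene != candidate.alert.gene:
        raise ValueError(
            f"superseding alert is for {new_alert.gene!r}, candidate is {candidate.alert.gene!r}"
        )
    fresh = replace(
        candidate,
        alert=new_alert,
        criteria=set(candidate.criteria),
        flags=list(candidate.flags),
        match_reasons=list(candidate.match_reasons),
        reclassification_log=list(candidate.reclassification_log),
    )
    fresh.classification = None
    return apply_segregation_evidence(classify_candidate(fresh), new_alert)
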