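"""Packaged in-repo fixtures: the published candidate-variant table and the
128-gene alert panel, plus summary helpers over them.

``data/candidate_table.tsv`` transcribes the published table of 56 candidate variants
(36 genes, 53 individuals) with per-row delay, stated segregation, genomic
and protein-level descriptions, the final classification and, where given,
the retrospective ACMG-AMP evidence-code cell.  ``data/alerts_128_synthetic.tsv``
reproduces the reported alert-panel composition (128 genes: 100 novel-disorder
/ 9 distinct-disorder / 19 phenotype-update; 37 non-morbid and one
OMIM-absent among the novel) with synthetic gene symbols standing in for the
genes outside the candidate table, whose identities were not published.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .acmg import Tier, combine_criteria
from .alerts import AlertSet, parse_alert_file
from .store_io import VariantKey, parse_hgvs_g
from .triage import SegregationStatus, parse_segregation_token

#: printed-table class marks -> five-tier vocabulary
_CLASS_MARKS = {
    "P": Tier.PATHOGENIC,
    "LP": Tier.LIKELY_PATHOGENIC,
    "VUS": Tier.VUS,
    "LB": Tier.LIKELY_BENIGN,
    "B": Tier.BENIGN,
}


@dataclass(frozen=True)
class CandidateTableRow:
    gene: str
    delay_months: float | None
    segregation: SegregationStatus
    key: VariantKey
    protein_change: str
    n_patients: int | None
    classification: Tier
    retro_label: Tier | None
    retro_criteria: frozenset[str]


def _data_path(name: str):
    return resources.files("litquery").joinpath("data", name)


def load_candidate_table() -> list[CandidateTableRow]:
    """Load the packaged candidate-variant table (56 rows)."""
    text = _data_path("candidate_table.tsv").read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    header = lines[0].split("\t")
    rows = []
    for ln in lines[1:]:
        f = dict(zip(header, ln.split("\t")))
        rows.append(CandidateTableRow(
            gene=f["gene"],
            delay_months=None if f["delay_months"] == "." else float(f["delay_months"]),
            segregation=parse_segregation_token(f["segregation"]),
            key=parse_hgvs_g(f["genomic_position"]),
            protein_change=f["protein_change"],
            n_patients=None if f["n_patients"] == "." else int(f["n_patients"]),
            classification=_CLASS_MARKS[f["classification"]],
            retro_label=None if f["retro_label"] == "." else _CLASS_MARKS[f["retro_label"]],
            retro_criteria=frozenset(
                () if f["retro_criteria"] == "." else f["retro_criteria"].split(",")
            ),
        ))
    return rows


def load_alert_fixture() -> AlertSet:
    """Load the packaged 128-record alert panel."""
    with resources.as_file(_data_path("alerts_128_synthetic.tsv")) as p:
        return parse_alert_file(p)


def candidate_table_summary(rows: list[CandidateTableRow]) -> dict:
    """Variant/gene/individual tallies and class counts over the table.

    Individuals are counted from the stated per-group patient counts (given
    once per patient group, ``None`` on continuation rows).
    """
    by_class: dict[str, int] = {t.value: 0 for t in Tier}
    for r in rows:
        by_class[r.classification.value] += 1
    return {
        "n_variants": len(rows),
        "n_genes": len({r.gene for r in rows}),
        "n_individuals": sum(r.n_patients or 0 for r in rows),
        "by_class": by_class,
    }


def replay_retro_criteria(rows: list[CandidateTableRow]) -> dict:
    """Re-combine every populated retrospective evidence cell.

    Returns the number of populated cells, the number whose recombined tier
    equals the printed label, and the disagreeing rows (empty when the
    combiner reproduces the table).
    """
    populated = [r for r in rows if r.retro_label is not None]
    disagreements = []
    for r in populated:
        got = combine_criteria(r.retro_criteria).value
        if got is not r.retro_label:
            disagreements.append((r.gene, str(r.key), r.retro_label.value, got.value))
    return {
        "n_cells": len(populated),
        "n_agree": len(populated) - len(disagreements),
        "disagreements": disagreements,
    }
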