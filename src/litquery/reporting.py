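"""Summary metrics and the diagnostic report.

Covers the study-level accounting around the query engine: per-mode line
counts and the v1-to-v2 fold reduction, positive/negative query tallies,
classification counts, diagnostic yields against the cohort denominators,
and alert-to-report delay statistics.  Percentages mirror diagnostic-report
conventions: per-gene line means truncate toward zero, yields round half-up
to the printed precision, and every formatted number keeps its raw value in
the machine-readable report.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from datetime import date

from .acmg import Tier
from .exceptions import MetricError
from .query_engine import QueryResult
from .store_io import format_hgvs_g
from .triage import CandidateVariant


@dataclass(frozen=True)
class CohortSummary:
    """Fixed denominators of the exome cohort the store covers."""

    total_exomes: int = 5459
    probands: int = 4170
    dd_id_probands: int = 3771
    diagnosed_probands: int = 896
    undiagnosed_probands: int = 2875
    relatives: int = 1289

    def __post_init__(self) -> None:
        if self.diagnosed_probands + self.undiagnosed_probands != self.dd_id_probands:
            raise ValueError("diagnosed + undiagnosed must equal DD/ID probands")
        if self.probands + self.relatives != self.total_exomes:
            raise ValueError("probands + relatives must equal total exomes")


@dataclass(frozen=True)
class QueryMetrics:
    mode: str
    genes: int
    total_lines: int

    def __post_init__(self) -> None:
        if self.genes == 0:
            raise MetricError(f"mode {self.mode!r}: per-gene mean undefined for zero genes")

    @property
    def mean_lines_per_gene(self) -> int:
        # truncated toward zero, the convention of the per-gene line mean
        return self.total_lines // self.genes


def _round_half_up(x: float, ndigits: int = 0) -> float:
    scale = 10 ** ndigits
    return math.floor(x * scale + 0.5) / scale


def query_metrics(results: list[QueryResult]) -> dict[str, QueryMetrics]:
    """Aggregate query results into per-mode gene and line totals."""
    per_mode: dict[str, dict[str, int]] = {}
    for r in results:
        agg = per_mode.setdefault(r.mode, {"genes": 0, "lines": 0})
        agg["genes"] += 1
        agg["lines"] += r.line_count
    return {
        mode: QueryMetrics(mode=mode, genes=agg["genes"], total_lines=agg["lines"])
        for mode, agg in sorted(per_mode.items())
    }


def fold_reduction(v1: QueryMetrics, v2: QueryMetrics) -> int:
    """Rounded ratio of mean output lines per gene, v1 over v2."""
    if v2.mean_lines_per_gene == 0:
        raise MetricError("v2 mean lines/gene is zero; fold reduction undefined")
    return int(_round_half_up(v1.mean_lines_per_gene / v2.mean_lines_per_gene))


# ---------------------------------------------------------------------------
# Classification summaries
# ---------------------------------------------------------------------------


def classification_summary(
    candidates: list[CandidateVariant], queried_genes: int | None = None
) -> dict:
    """Counts by tier, distinct genes/individuals, positive/negative tally.

    A *positive* query for a gene means at least one candidate survived
    triage for it; with ``queried_genes`` given, negative = queried -
    positive.  Class counts sum to the candidate count by construction.
    """
    by_class = {t.value: 0 for t in Tier}
    genes: set[str] = set()
    individuals: set[str] = set()
    for c in candidates:
        tier = c.classification.value.value if c.classification is not None else Tier.VUS.value
        by_class[tier] += 1
        genes.add(c.alert.gene)
        individuals.add(c.row.sample_id)
    out = {
        "n_variants": len(candidates),
        "by_class": by_class,
        "n_genes": len(genes),
        "genes": sorted(genes),
        "n_individuals": len(individuals),
        "positive_genes": len(genes),
    }
    if queried_genes is not None:
        if queried_genes < len(genes):
            raise MetricError(
                f"{queried_genes} queried genes < {len(genes)} positive genes"
            )
        out["queried_genes"] = queried_genes
        out["negative_genes"] = queried_genes - len(genes)
    return out


def cohort_yields(
    *,
    causal_individuals: int,
    flagged_individuals: int,
    causal_or_vus_individuals: int,
    causal_genes: int,
    interest_genes: int,
    queried_genes: int,
    cohort: CohortSummary = CohortSummary(),
) -> dict:
    """Diagnostic-yield percentages at report precision, with raw values.

    * causal yield: causal individuals / undiagnosed probands (1 decimal)
    * flagged fraction: flagged individuals / DD-ID probands (1 decimal)
    * causative among flagged (1 decimal) and causative+VUS among flagged
      (integer percent)
    * per-gene diagnosis and variant-of-interest fractions over the queried
      gene panel (integer percent)
    """
    for name, denom in (
        ("undiagnosed probands", cohort.undiagnosed_probands),
        ("DD/ID probands", cohort.dd_id_probands),
        ("queried genes", queried_genes),
    ):
        if denom == 0:
            raise MetricError(f"zero denominator: {name}")
    if flagged_individuals == 0 and (causal_individuals or causal_or_vus_individuals):
        raise MetricError("flagged individuals is zero but numerators are not")

    def pct(num: int, denom: int, ndigits: int):
        raw = 100.0 * num / denom if denom else 0.0
        value = _round_half_up(raw, ndigits)
        return {"value": value if ndigits else int(value), "raw": raw,
                "numerator": num, "denominator": denom}

    return {
        "causal_yield_undiagnosed": pct(causal_individuals, cohort.undiagnosed_probands, 1),
        "flagged_fraction_dd_id": pct(flagged_individuals, cohort.dd_id_probands, 1),
        "causal_fraction_flagged": pct(causal_individuals, flagged_individuals, 1)
        if flagged_individuals else {"value": 0.0, "raw": 0.0, "numerator": 0, "denominator": 0},
        "causal_or_vus_fraction_flagged": pct(causal_or_vus_individuals, flagged_individuals, 0)
        if flagged_individuals else {"value": 0, "raw": 0.0, "numerator": 0, "denominator": 0},
        "causal_gene_fraction": pct(causal_genes, queried_genes, 0),
        "interest_gene_fraction": pct(interest_genes, queried_genes, 0),
    }


# ---------------------------------------------------------------------------
# Delay statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReportEntry:
    """Bookkeeping of one candidate's path from alert to diagnostic report."""

    individual_id: str
    alert_date: date | None = None
    report_date: date | None = None
    delay_months: float | None = None
    phase: str = "daily"  # daily | endpoint

    def __post_init__(self) -> None:
        if self.delay_months is not None and self.delay_months < 0:
            raise ValueError("delay must be non-negative")


def delay_stats(delays) -> dict:
    """Mean / sample SD (n-1) / min / max of known delays; unknowns counted.

    Accepts either floats (None = unknown) or :class:`ReportEntry` items.
    With a single known delay the SD is reported as 0.0 by convention.
    """
    values = []
    excluded = 0
    for d in delays:
        if isinstance(d, ReportEntry):
            d = d.delay_months
        if d is None:
            excluded += 1
        else:
            values.append(float(d))
    if not values:
        raise MetricError("all delays unknown; statistics undefined")
    n = len(values)
    mean = sum(values) / n
    sd = 0.0 if n == 1 else math.sqrt(sum((v - mean) ** 2 for v in values) / (n - 1))
    return {
        "mean": mean, "sd": sd, "min": min(values), "max": max(values),
        "n": n, "n_excluded": excluded,
    }


def delay_stats_by_phase(entries: list[ReportEntry]) -> dict[str, dict]:
    out = {"overall": delay_stats(entries)}
    for phase in sorted({e.phase for e in entries}):
        subset = [e for e in entries if e.phase == phase]
        if any(e.delay_months is not None for e in subset):
            out[phase] = delay_stats(subset)
    return out


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

_REPORT_COLUMNS = (
    "gene", "individual", "segregation", "genomic_position", "protein",
    "effect", "classification", "rationale", "criteria", "match_reasons",
)


def render_report(
    candidates: list[CandidateVariant],
    metrics: dict[str, QueryMetrics] | None = None,
    yields: dict | None = None,
    delays: dict | None = None,
) -> str:
    """Render the candidate table plus a JSON metrics block, deterministically.

    Identical inputs produce byte-identical output: candidates are sorted by
    (gene, individual, position), floats are formatted to fixed precision and
    JSON keys are sorted.
    """
    lines = ["\t".join(_REPORT_COLUMNS)]
    ordered = sorted(candidates, key=lambda c: (c.alert.gene, c.row.sample_id, c.row.key))
    for c in ordered:
        cls = c.classification
        lines.append("\t".join([
            c.alert.gene,
            c.row.sample_id,
            c.segregation.value,
            format_hgvs_g(c.row.key),
            c.row.protein_change or ".",
            c.effect.effect_class.value,
            cls.value.value if cls else ".",
            cls.rationale if cls else ".",
            ",".join(sorted(c.criteria)) or ".",
            ";".join(c.match_reasons),
        ]))
    summary: dict = {"summary": classification_summary(candidates)}
    if metrics is not None:
        summary["query_metrics"] = {
            mode: {
                "genes": m.genes, "total_lines": m.total_lines,
                "mean_lines_per_gene": m.mean_lines_per_gene,
            }
            for mode, m in metrics.items()
        }
    if yields is not None:
        summary["yields"] = yields
    if delays is not None:
        summary["delays"] = delays
    blob = json.dumps(summary, sort_keys=True, indent=2, default=float)
    return "\n".join(lines) + "\n\n" + blob + "\n"
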