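"""Synthetic variant stores with known ground truth.

The generator emulates the store the query engine was built for: one
directory of per-sample annotated variant tables, where each sample may have
been analyzed one to three times under successive pipeline versions (older
analyses carry fewer annotation columns), every re-analysis duplicates the
sample's variants into another file, and a manifest records provenance.
Background variants are independent draws over a configurable gene universe
whose symbols deliberately include superstring pairs (GENE1 / GENE10 / ...),
the classic whole-word-matching trap.  *Planted* variants with chosen gene,
frequency, effect and segregation carry an ``expected_candidate`` flag, so
pipeline recall and precision are measurable exactly.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np

from .alerts import AlertSet, GeneAlert
from .store_io import (
    SCHEMAS,
    AnnotatedVariantRow,
    VariantKey,
    VariantStore,
    scan_store,
    write_variant_table,
)
from .triage import SegregationStatus

_AA = (
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
)
_BASES = "ACGT"


@dataclass(frozen=True)
class PlantedVariant:
    """One deliberately inserted variant with its expected pipeline outcome."""

    gene: str
    sample_id: str
    key: VariantKey
    protein_change: str
    segregation: SegregationStatus
    af: float | None  # None = absent from every population panel
    expected_candidate: bool
    alert: GeneAlert | None = None


@dataclass(frozen=True)
class SimConfig:
    """Study-condition defaults: a desk-scale image of a clinical exome store.

    30 samples with 1-3 analyses each (re-analysis is the norm, matching the
    duplicate-line problem the v2 script exists for), ~60 background coding
    variants per sample in a 40-gene universe, and 70% of background
    variants rare (population AF < 1%).
    """

    n_samples: int = 30
    analyses_per_sample: tuple[tuple[int, float], ...] = ((1, 0.3), (2, 0.5), (3, 0.2))
    schema_versions: tuple[str, ...] = ("v1", "v2")
    background_variants_per_sample: int = 60
    rare_fraction: float = 0.7
    n_genes: int = 40
    planted: tuple[PlantedVariant, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isclose(sum(p for _, p in self.analyses_per_sample), 1.0):
            raise ValueError("analyses_per_sample probabilities must sum to 1")
        if not (0.0 <= self.rare_fraction <= 1.0):
            raise ValueError("rare_fraction must be in [0, 1]")
        universe = set(self.gene_universe())
        missing = sorted({p.gene for p in self.planted} - universe)
        if missing:
            raise ValueError(f"planted genes outside the simulated universe: {missing}")

    def gene_universe(self) -> list[str]:
        base = [f"GENE{i}" for i in range(1, self.n_genes + 1)]
        extra = [p.gene for p in self.planted if p.gene not in base]
        # planted genes named outside the GENE* scheme extend the universe
        return base + sorted(set(extra))


@dataclass
class GroundTruth:
    """Manifest of planted records plus generator-side background tallies."""

    planted: tuple[PlantedVariant, ...]
    n_background: int
    n_background_rare: int
    seed: int = 0

    def expected_candidates(self) -> set[tuple[str, str, VariantKey]]:
        return {
            (p.gene, p.sample_id, p.key) for p in self.planted if p.expected_candidate
        }

    def segregations(self) -> dict[str, SegregationStatus]:
        return {p.sample_id: p.segregation for p in self.planted}

    def alerts(self) -> AlertSet:
        """One alert per planted gene (first record wins)."""
        seen: dict[str, GeneAlert] = {}
        for p in self.planted:
            if p.alert is not None and p.gene not in seen:
                seen[p.gene] = p.alert
        return AlertSet(alerts=[seen[g] for g in sorted(seen)])

    def to_json(self, path) -> None:
        doc = {
            "seed": self.seed,
            "n_background": self.n_background,
            "n_background_rare": self.n_background_rare,
            "planted": [
                {
                    "gene": p.gene, "sample_id": p.sample_id,
                    "chrom": p.key.chrom, "pos": p.key.pos,
                    "ref": p.key.ref, "alt": p.key.alt,
                    "protein_change": p.protein_change,
                    "segregation": p.segregation.value,
                    "af": p.af,
                    "expected_candidate": p.expected_candidate,
                }
                for p in self.planted
            ],
        }
        Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def _gene_chrom(gene: str, universe: list[str]) -> str:
    return f"chr{universe.index(gene) % 22 + 1}"


def _draw_protein_change(rng: np.random.Generator) -> str:
    pos = int(rng.integers(20, 1500))
    a, b = rng.choice(len(_AA), size=2, replace=False)
    kind = rng.random()
    if kind < 0.65:
        return f"p.({_AA[a]}{pos}{_AA[b]})"
    if kind < 0.80:
        return f"p.({_AA[a]}{pos}*)"
    if kind < 0.90:
        return f"p.({_AA[a]}{pos}{_AA[b]}fs*{int(rng.integers(2, 60))})"
    return "p.?"


def _draw_background_row(
    rng: np.random.Generator, sample_id: str, universe: list[str], rare_fraction: float
) -> tuple[AnnotatedVariantRow, bool]:
    gene = universe[int(rng.integers(0, len(universe)))]
    pos = int(rng.integers(1_000_000, 50_000_000))
    ref_i = int(rng.integers(0, 4))
    alt_i = (ref_i + 1 + int(rng.integers(0, 3))) % 4
    is_rare = bool(rng.random() < rare_fraction)
    if is_rare:
        af = float(10 ** rng.uniform(-6, np.log10(0.0099)))
    else:
        af = float(rng.uniform(0.01, 0.5))
    row = AnnotatedVariantRow(
        key=VariantKey(_gene_chrom(gene, universe), pos, _BASES[ref_i], _BASES[alt_i]),
        sample_id=sample_id,
        gene=gene,
        protein_change=_draw_protein_change(rng),
        af_fields={"GNOMAD_EXOME_AF": af},
        score_fields={
            "CADD": round(float(rng.uniform(0, 40)), 2),
            "PLI": round(float(rng.uniform(0, 1)), 3),
            "OE": round(float(rng.uniform(0.05, 1.5)), 3),
        },
    )
    return row, is_rare


def _version_view(row: AnnotatedVariantRow, schema) -> AnnotatedVariantRow:
    """Restrict a row to the columns a pipeline version knew about."""
    cols = set(schema.columns)
    return replace(
        row,
        af_fields={k: v for k, v in row.af_fields.items() if k in cols},
        score_fields={k: v for k, v in row.score_fields.items() if k in cols},
        omim_fields={k: v for k, v in row.omim_fields.items() if k in cols},
        extra_fields={k: v for k, v in row.extra_fields.items() if k in cols},
    )


def simulate_store(cfg: SimConfig, out_dir) -> tuple[VariantStore, GroundTruth]:
    """Write a synthetic store to ``out_dir``; return it scanned, with truth.

    The seed fully determines the output: two runs with one config produce
    byte-identical files.  A planted variant colliding with a background
    variant evicts the background draw with a warning.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    universe = cfg.gene_universe()

    sample_ids = [f"S{i:03d}" for i in range(1, cfg.n_samples + 1)]
    for p in cfg.planted:
        if p.sample_id not in sample_ids:
            sample_ids.append(p.sample_id)

    ks, probs = zip(*cfg.analyses_per_sample)
    n_background = 0
    n_background_rare = 0
    manifest_entries = []
    base_date = datetime(2019, 4, 1)

    for s_index, sample_id in enumerate(sample_ids):
        k = int(rng.choice(ks, p=probs))
        rows: dict[VariantKey, AnnotatedVariantRow] = {}
        rare_flags: dict[VariantKey, bool] = {}
        while len(rows) < cfg.background_variants_per_sample:
            row, is_rare = _draw_background_row(rng, sample_id, universe, cfg.rare_fraction)
            if row.key in rows:
                continue
            rows[row.key] = row
            rare_flags[row.key] = is_rare
        for p in cfg.planted:
            if p.sample_id != sample_id:
                continue
            if p.key in rows:
                warnings.warn(
                    f"planted variant {p.key} collided with a background draw "
                    f"in {sample_id}; background variant evicted",
                    UserWarning,
                    stacklevel=2,
                )
                del rows[p.key]
                del rare_flags[p.key]
            af = {} if p.af is None else {"GNOMAD_EXOME_AF": p.af}
            rows[p.key] = AnnotatedVariantRow(
                key=p.key, sample_id=sample_id, gene=p.gene,
                protein_change=p.protein_change, af_fields=af,
                score_fields={"CADD": 25.0, "PLI": 0.98, "OE": 0.12},
            )
        n_background += len(rare_flags)
        n_background_rare += sum(rare_flags.values())

        ordered = [rows[key] for key in sorted(rows)]
        for a_index in range(k):
            version = cfg.schema_versions[min(a_index, len(cfg.schema_versions) - 1)]
            schema = SCHEMAS[version]
            stamp = base_date + timedelta(days=s_index + 200 * a_index)
            path = f"{sample_id}_a{a_index + 1}_{version}.tsv"
            write_variant_table(
                [_version_view(r, schema) for r in ordered], schema, out_dir / path
            )
            manifest_entries.append({
                "path": path,
                "sample_id": sample_id,
                "analysis_timestamp": stamp.isoformat(),
                "version_tag": version,
            })

    manifest_entries.sort(key=lambda e: (e["sample_id"], e["analysis_timestamp"], e["path"]))
    (out_dir / "manifest.json").write_text(
        json.dumps({"files": manifest_entries}, indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    truth = GroundTruth(
        planted=cfg.planted,
        n_background=n_background,
        n_background_rare=n_background_rare,
        seed=cfg.seed,
    )
    truth.to_json(out_dir / "ground_truth.json")
    return scan_store(out_dir), truth
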