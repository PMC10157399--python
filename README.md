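# litquery

Literature-alert-driven re-querying of clinical exome stores: whole-word gene
queries over heterogeneous annotated variant tables, rare-variant triage
against the reported variant class and inheritance, ACMG–AMP classification,
and diagnostic-yield reporting.

## The problem

Exome sequencing leaves most developmental-disorder / intellectual-disability
(DD/ID) probands undiagnosed at first analysis, largely because the causal
gene has not yet been tied to a human disorder when the pipeline runs.  New
gene–disease associations appear in the literature daily, months before they
reach OMIM or ClinVar — so periodic full reanalysis lags, and the variants
are already sitting in the laboratory's accumulated per-sample variant
tables.  A far cheaper loop is: monitor the literature, and for each newly
implicated gene run a *targeted whole-word query* over every stored table,
then triage the hits.

Doing that reproducibly is harder than it sounds.  The store is
heterogeneous: the same individual may have been analyzed several times under
different pipeline versions, so a naive `grep -w GENE *.tsv` returns
duplicated lines with inconsistent column sets.  `litquery` models the whole
loop as a library:

- **store_io** — read/write/scan the store: TSV variant tables (eight VCF
  core columns + versioned custom annotations, `.` for gaps), a JSON/YAML
  manifest carrying sample, analysis timestamp and pipeline version, and an
  optional VCF ingestion path.
- **query_engine** — the *v1* query (raw whole-word matches, duplicates and
  all), the *v2* query (keep only each sample's most recent analysis, then
  harmonize all rows onto the master schema), and the *end-point* re-query
  that reruns every previously searched gene against the grown store and
  reports only unseen observations via an append-only ledger.
- **alerts** — structured gene-alert records: gene, publication date,
  association category, OMIM status snapshot, reported inheritance modes and
  variant classes, optional protein-domain intervals.
- **triage** — rarity gate (max population AF strictly < 1% by default,
  missing AF counts as rare) and alert-concordance matching: effect class
  parsed from HGVS-p, segregation compatibility, compound-heterozygote
  pairing, LoF-constraint flags (pLI > 0.9 or o/e < 0.3).
- **acmg** — ACMG–AMP evidence combination (PVS/PS/PM/PP vs BA/BS/BP, fixed
  strengths, standard combining rules) and segregation-driven
  reclassification: a "de novo only" report plus inheritance from an
  asymptomatic parent holds the call at VUS.
- **reporting** — per-mode line counts and fold reduction, positive/negative
  query tallies, classification counts, diagnostic yields against the cohort
  denominators (5,459 exomes; 3,771 DD/ID probands; 2,875 undiagnosed), and
  a deterministic report renderer.
- **synthetic** — a seeded store generator with planted ground-truth
  variants, plus packaged fixtures: the published 56-variant candidate table
  and a 128-gene alert panel.

## Worked example

Simulate a 20-sample store with one planted de novo truncating variant in an
alert gene, query it both ways, triage and classify:

```python
from datetime import date
from litquery import (
    GeneAlert, AssociationCategory, OmimStatus, InheritanceMode, VariantClass,
    VariantKey, SegregationStatus, SimConfig, simulate_store,
    grep_word_v1, query_gene_v2, match_candidates, render_report,
)
from litquery.synthetic import PlantedVariant
from litquery.acmg import classify_candidate, apply_segregation_evidence

alert = GeneAlert(
    gene="GENE7", publication_date=date(2020, 3, 9),
    association_category=AssociationCategory.NOVEL_DISORDER,
    omim_status=OmimStatus.NON_MORBID,
    inheritance_modes=frozenset({InheritanceMode.DE_NOVO_DOMINANT}),
    reported_variant_classes=frozenset({VariantClass.PROTEIN_TRUNCATING}),
    source_ref="doi:example")

planted = PlantedVariant(
    gene="GENE7", sample_id="S004", key=VariantKey("chr7", 5_500_123, "C", "T"),
    protein_change="p.(Arg712*)", segregation=SegregationStatus.DE_NOVO,
    af=None, expected_candidate=True, alert=alert)

store, truth = simulate_store(SimConfig(n_samples=20, seed=7, planted=(planted,)), "store/")
v1 = grep_word_v1("GENE7", store)
v2 = query_gene_v2("GENE7", store)
print(f"v1 query: {v1.line_count} lines   v2 query: {v2.line_count} lines")

rows = [r for r in v2.rows if r.gene == "GENE7"]
candidates = match_candidates(rows, alert, truth.segregations())
for c in candidates:
    c.criteria = {"PVS1", "PM2"} if c.row.key == planted.key else set()
    apply_segregation_evidence(classify_candidate(c))
print(render_report(candidates).split("\n\n")[0])
```

prints

```
v1 query: 59 lines   v2 query: 31 lines
gene	individual	segregation	genomic_position	protein	effect	classification	rationale	criteria	match_reasons
GENE7	S001	unknown	chr7:g.2181087C>A	p.(Asn1192Hisfs*26)	protein_truncating	VUS	insufficient	.	class:protein-truncating;inheritance:unknown
GENE7	S002	unknown	chr7:g.35222878A>G	p.(Cys850*)	protein_truncating	VUS	insufficient	.	class:protein-truncating;inheritance:unknown
GENE7	S004	de_novo	chr7:g.5500123C>T	p.(Arg712*)	protein_truncating	likely_pathogenic	PVS1+moderate	PM2,PVS1	class:protein-truncating;inheritance:de_novo_dominant
GENE7	S006	unknown	chr7:g.13786928G>A	p.(Asp942*)	protein_truncating	VUS	insufficient	.	class:protein-truncating;inheritance:unknown
GENE7	S015	unknown	chr7:g.22708979C>G	p.(Phe1407*)	protein_truncating	VUS	insufficient	.	class:protein-truncating;inheritance:unknown
GENE7	S020	unknown	chr7:g.6357643T>G	p.(Arg79*)	protein_truncating	VUS	insufficient	.	class:protein-truncating;inheritance:unknown
```

The v1 query returns 59 lines because every re-analysis of a sample repeats
its variants; the v2 query collapses them to 31 harmonized rows.  The planted
de novo stop-gain in S004 is the only hit with segregation support and
supplied evidence codes, so it alone reaches likely pathogenic; other rare
truncating hits without segregation data stay VUS ("insufficient").

The same operations are available from the shell:

```bash
litquery simulate --out store/ --seed 7
litquery grep GENE7 --store store/ --mode v2 --out GENE7.tsv
litquery endpoint --alerts alerts.tsv --store store/ --ledger seen.jsonl
litquery report --store store/ --alerts alerts.tsv --segregations seg.tsv
```

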