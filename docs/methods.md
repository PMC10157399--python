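# Methods

## The reanalysis model

`litquery` implements a targeted reanalysis loop for exome stores.  The unit
of input is a *gene alert*: a structured record of one publication
implicating a gene in a DD/ID phenotype, carrying the reported inheritance
mode(s) and variant class(es).  Each alert drives one query over the store of
per-sample annotated variant tables; hits are filtered to rare variants and
matched against the alert; surviving candidates are classified under
ACMG–AMP combining rules, with stated family segregation able to demote a
provisional call.  A query is *positive* when at least one candidate
survives triage, *negative* otherwise, and yields are fractions of
positive-gene and diagnosed-individual counts over the cohort denominators.

## The variant store

Each analysis file is tab-separated text derived from a VCF: the eight VCF
core columns first (CHROM, POS, ID, REF, ALT, QUAL, FILTER, INFO; hg19,
1-based), then pipeline-version-dependent annotation columns — population
allele frequencies (ESP, ExAC, gnomAD exome/genome), occurrence counts,
in-silico scores (PolyPhen, GERP, Grantham, CADD, misZ, pLI), OMIM fields
and the ClinVar class.  The second-generation schema adds the gnomAD o/e LoF
ratio with its CI bounds, the SPiP splice score and the CCR percentile.
Missing cells are a single gap token, `.`, and missingness is a first-class
state: a gap is `None` in memory and `.` again on write, never zero.

Analysis provenance (sample, timestamp, pipeline version) comes from a
JSON/YAML manifest at the store root rather than from file modification
times, so store listings — and therefore query outputs — are reproducible
and independent of filesystem enumeration order.  "Most recently analyzed"
is defined as the manifest timestamp, with ties broken by version tag
descending then path; an exact tie is an error rather than a silent pick.
Chromosome label style (`chr6` vs `6`) is preserved as given and never
normalized; mixing styles is rejected, since a whole-word text query cannot
be style-agnostic without silently missing rows.

Genomic HGVS strings are parsed into variant keys: substitutions keep
literal ref/alt; `del`/`dup` become symbolic alts `DEL`/`DUP` with the
affected span encoded as an `N`-run ref.  No normalization, left-alignment
or liftover is attempted — the store is taken exactly as produced upstream.

## Query semantics

Whole-word matching treats `[A-Za-z0-9_-]` as word characters and is
case-sensitive.  The hyphen is deliberately a word character: symbols such
as `NKX2-5` must be single tokens, while `GENE1` must never match `GENE10`.
By default only the gene-symbol column is searched (precision); a
`full_line` mode tokenizes every text field of the line, reproducing the
behaviour of a plain `grep -w` over the files.

The v1 query returns every matching line of every analysis file, duplicates
included.  The v2 query composes three steps: whole-word match, then
duplicate removal keeping each (sample, variant) observation only from the
sample's most recent analysis, then harmonization of all rows onto the
master schema (the union of the version schemas) with gaps marked — one
rectangular table per gene.  v2's line count is therefore never larger than
v1's, and with every sample analyzed k times it is exactly k-fold smaller.

The end-point re-query runs all previously searched genes against the grown
store and reports only (gene, sample, variant) observations absent from an
append-only seen-ledger (JSON lines).  This makes incremental daily querying
and one final batch query provably equivalent: the union of the deltas over
a growing store equals a single query on the final store.

## Triage

Rarity: a row is rare when the maximum over the configured population-AF
fields is strictly below the threshold (default 0.01).  The maximum is the
most conservative aggregate; a variant absent from every panel counts as
rare by default, because absence from population panels is the expected
signature of an ultra-rare disease allele.  Internal cohort counts are
carried but not thresholded.

Effect classes are parsed from HGVS-p: frameshift or stop-gain →
protein-truncating; single-residue substitution → missense with position;
in-frame single-residue del/dup → in-frame indel; `p.?` and anything
unparseable (with a warning, never a crash) → unknown splice effect.

A row matches its alert when the effect class is among the reported classes
— `missense_in_domain` additionally requires the parsed position to fall in
a reported domain interval; an unknown splice effect matches only when the
alert reports splice variants (configurable) — *and* the stated segregation
is compatible with a reported inheritance mode, or unknown.  Two deliberate
asymmetries:

- Under a de-novo-only alert, a class-matching variant inherited from an
  asymptomatic parent is kept and tagged rather than discarded; discarding
  it would lose exactly the stratum that diagnostic practice holds at VUS.
- In-frame single-residue indels are matched under the missense classes: a
  residue-level change with the domain rule applied when the position
  parses.  The alert vocabulary has no separate in-frame class, and such
  variants are reported and retained in practice.

Compound heterozygotes: under a recessive alert, two candidates in the same
gene and sample with *opposite stated parental origins* form a trans pair
(phase from stated segregation only; no read-backed phasing), as does a
single biparental/homozygous candidate.  A lone inherited carrier under a
recessive-only alert is dropped after the pairing pass.  Because a sample
can carry two variants with different origins, the segregation mapping
accepts per-variant entries `(sample, variant) -> status` alongside
sample-wide ones.

Truncating candidates in LoF-intolerant genes (pLI > 0.9 or o/e < 0.3) are
flagged; the flag is reported, not used as a filter.

## Classification

Evidence codes carry fixed strengths (PVS1 very strong; PS strong; PM
moderate; PP supporting; BA1 stand-alone benign; BS strong benign; BP
supporting benign) and are combined by the standard rule table with no
laboratory-specific modifications — the packaged candidate table's
evidence cells are all consistent with the unmodified table, which the test
suite verifies by replaying every populated cell.  Pathogenic-side and
benign-side rules are evaluated independently; both satisfied → VUS
("conflicting"), neither → VUS ("insufficient").

Segregation reconciliation: under a de-novo-only alert, an inherited P/LP
call is downgraded to VUS ("inherited-unreported") and the event logged
with before/after; a trio-confirmed de novo adds PS2 and recombines.  The
operation is idempotent, and later alerts for the same gene supersede
earlier ones as new records — history is never mutated.

## Reporting conventions

Per-gene line-count means truncate toward zero (82,156 lines over 52 genes
reports 1,579/gene), matching query-log reporting practice; the v1→v2 fold
is the rounded ratio of the two means.  Yields round half-up — one decimal
for cohort yields, integer percent for gene-panel fractions — and every
formatted number carries its raw value in the machine-readable report.
Delay statistics use the sample SD (n−1), report SD 0.0 for a single value,
and count unknown ("ND") delays as excluded rather than dropping them
silently.  The report renderer sorts candidates by (gene, individual,
position) and fixes number formatting, so identical inputs give
byte-identical bytes.

The cohort denominators are packaged constants (5,459 exomes = 4,170
probands + 1,289 relatives; 3,771 DD/ID probands = 896 diagnosed + 2,875
undiagnosed) with both identities enforced at construction.

## Synthetic stores and what they do (not) show

The generator emulates the structural features the engine exists to handle:
per-sample tables duplicated across 1–3 analyses under successive schema
versions, a manifest, a gene universe containing superstring symbol pairs
(GENE1/GENE10), and a background AF mixture with a configurable rare
fraction.  Defaults — 30 samples, 60 background variants each, 70% rare,
40 genes — are desk-scale: large enough that duplication, harmonization
gaps and common-variant contamination all occur, small enough that the full
suite runs in seconds.  Planted variants carry chosen gene, site, effect,
frequency and segregation plus an `expected_candidate` flag, so recall and
precision are exact.  A fixed seed yields byte-identical stores.

Background variants are independent draws: no LD, no haplotypes, no
realistic site-frequency spectrum, no genotype errors, and annotations are
sampled independently of effect.  Passing tests therefore demonstrate the
engine's contracts (matching, dedup, harmonization, filtration, combination,
accounting) — not calling accuracy on real exomes, which depends on the
upstream pipeline the store is taken from.

## Packaged fixtures

`data/candidate_table.tsv` transcribes the published candidate-variant table: 56
variants in 36 genes from 53 individuals, with delays, stated segregations,
genomic and protein descriptions, final classes and 19 populated
retrospective evidence cells.  Rows marked NA for criteria are excluded
from the replay check, as nothing is stated to replay.
`data/alerts_128_synthetic.tsv` reproduces the reported composition of the
18-month alert panel (128 genes: 100 novel-disorder, of which 37 not yet
OMIM-morbid and 1 absent from OMIM; 9 distinct-disorder; 19 updates); the
92 gene symbols beyond the candidate table were not published, so synthetic
placeholders (`SYNG*`) stand in, and the file is labelled synthetic.

## Problem sizes

The test suite uses stores of 2–100 samples (10,000 background draws for
the mixture-calibration check, 3 SE tolerance) and 20 seeded simulator
configurations for the recall property.  The acceptance script uses 10
seeded configurations of 6 samples × 25 background variants for recall,
and computes every table- and count-derived quantity directly from the
packaged fixtures.

## Known limitations

- No CNV, mitochondrial, or non-coding logic; the engine searches rare
  nuclear SNVs/indels as stored.
- Gene symbols are matched literally; no alias or HGNC resolution (a
  warning is emitted when a queried symbol is absent from the store).
- Evidence codes are supplied, not derived: the package does not compute
  PM2 from gnomAD or PP3 from scores itself.
- The splice-matching rule for `p.?` variants is a configuration choice;
  published practice is ambiguous (several such variants were retained as
  LP where only truncating variants had been reported).
- Delay unit conventions in the transcribed table are ambiguous between
  sources; delay statistics are recomputed from the transcription and not
  asserted against any printed mean.
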