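# Methods

## The data model

`varcdm` stores one cohort per database: nine tables in a single-file
SQLite store with foreign keys enforced, created from a versioned DDL
asset (`src/varcdm/assets/schema.sql`, schema version 1.0). The five
clinical tables follow the OMOP table split (person, condition,
procedure, specimen, care site) but carry only the columns this package
reads; the four genomic tables describe the test (metadata and targeted
gene list), each observed alteration, and its interpretation.

Design points that matter downstream:

- **Two specimen links per variant.** `variant_occurrence` references a
  target (tumor) specimen and, optionally, a reference (normal) specimen;
  the reference link is nullable so single-specimen (e.g. congenital)
  testing is representable. Validation checks that the target link
  really points at a specimen with role `target`.
- **Annotation is a separate table.** Interpretations
  (database/version, somatic vs germline origin, pathogenicity, allele
  fraction, medication) attach to an occurrence many-to-one, so they can
  be re-issued when annotation databases move without rewriting
  observations.
- **String-coded vocabularies.** Controlled terms (gender, stage,
  specimen role, the two variant-type levels, variant origin) are stored
  as strings validated against fixed vocabularies. Real OMOP
  `concept_id` resolution is out of scope; the string codes are the
  mapping hook.
- **Coordinates are 1-based inclusive** (the MAF convention). VCF input
  is converted at load: the shared leading base is stripped; a deletion
  spans the deleted bases; an insertion gets start = base before and
  end = base after the inserted run.
- **Age is integer years at diagnosis**, which is all the demographic
  binning needs.

`validate_database` re-derives every invariant from the stored bytes
(keys, vocabularies, ranges, specimen roles, and a re-parse of every
stored protein HGVS) and returns violations as data in deterministic
order, so a load can be audited after the fact. Everything inserted
through `insert_records` is checked on the way in (all-or-nothing per
batch), giving the soundness property the tests assert: API-built
databases always validate clean.

## Nomenclature

Gene symbols resolve case-insensitively through an HGNC table mapping
symbols and aliases to (canonical symbol, accession). The bundled subset
covers the default 49-gene panel plus ~30 common aliases (HER2, P53,
LKB1, ...); a full HGNC TSV can be loaded with `HgncTable.from_tsv`.

Protein-level HGVS is handled by a purpose-built parser covering the
grammar clinical panel and MAF data actually use: substitution
(including stop-gain), synonymous (`=`), deletion, insertion,
duplication, delins, and frameshift with optional `Ter` offset, over
single positions and ranges. Extensions (mosaicism, phasing, uncertain
breakpoints) are rejected with the offset of the first offending
character. Two normalization rules are enforced at the model boundary:

- **Three-letter codes only.** One-letter input (`p.L858R`,
  `p.P72Rfs*5`) is expanded on the way in (`p.Leu858Arg`,
  `p.Pro72ArgfsTer5`); `*` becomes `Ter`. Expansion is idempotent and
  `format ∘ parse` is the identity on canonical text, so stored
  expressions are stable and comparable across sites.
- **`Xaa` is query-side only.** The wildcard matches any single-residue
  substitution at the stated codon — including a stop-gain, since that
  is still a substituted residue — but never an indel or frameshift at
  that codon, which are profiled as their own classes. Observations
  containing `Xaa` are rejected at insert.

Consequence vocabulary mapping (MAF `Variant_Classification`, VCF
Sequence Ontology terms → `variant_feature`; MAF `Variant_Type` and
structural panel terms → `sequence_alteration`) ships as an editable JSON
asset and is total: unmapped terms land on `other` with a logged
warning rather than failing a load.

## ETL

`read_maf` streams records with case-insensitive column matching and
`#`-comment handling; `hugo_symbol`, `variant_classification` and
`tumor_sample_barcode` are mandatory. `load_maf` restricts to the panel
(off-panel rows are counted, not errors), keeps **one sample per
patient** (earliest specimen collection date, then lexicographic
barcode — multi-sample patients would otherwise double-count in every
patient-level frequency), expands HGVS, and maps vocabularies.
`load_vcf` takes one patient per file, keeps ALT alleles whose FILTER is
PASS/'.', reads per-ALT annotation from a configurable INFO field and
sub-field order, and converts coordinates as above. `load_clinical`
loads the five clinical tables from the TSV dump dialect, skipping rows
that violate an invariant with reason `invariant_violation`. Every
loader returns a `LoadReport` whose reasons partition the skipped rows,
and panel restriction commutes with loading (filter-then-load equals
load-then-filter).

## Profiling

All frequencies are **patient-level with the full cohort as
denominator**: a patient counts at most once per gene (and once per
actionable pattern, and once per gene across patterns), and patients
with no variants stay in the denominator — this is what makes printed
percentages reproducible from counts. Variant-type proportions are the
exception by design: they are proportions of variant *rows*, at either
taxonomy level. Percentages print half-up to one decimal and ratios
half-up to two decimals, matching clinical-table convention; the
chi-squared is Pearson without continuity correction on the 2×2 table
`[[a, n1−a], [b, n2−b]]`, with the significance threshold fixed at 0.05
and no multiple-testing correction by default (a Bonferroni option
exists but is off, matching how such site comparisons are usually
reported).

The waterfall matrix needs two deterministic orders the underlying
convention leaves implicit, both fixed here as documented configuration:

- **Cell priority** (one feature per patient-gene cell),
  most-deleterious-first: nonsense > frameshift > splice > inframe >
  missense > synonymous > intron > other. Adding a lower-priority
  variant never changes a cell.
- **Column order**: patients sort by their presence/absence pattern
  across the gene rows (memo-sort), mutated-first, ties by `person_id`,
  producing the characteristic staircase reproducibly.

`export_aggregate` emits only counts, denominators, labels and versions —
no `person_id`, `specimen_id` or per-patient rows — and optional
k-suppression masks any count strictly between 0 and k as `"<k"`,
limiting responses that would target a near-unique individual. Noise
injection (differential privacy) is deliberately not implemented.
Exports from disjoint cohorts on the same panel are additive:
`merge_aggregates` sums them element-wise and equals the export of the
pooled database, which is what makes multi-site pooling of reports
legitimate. `compare_aggregates` refuses suppressed cells and mismatched
schema versions, and skips zero-denominator items with a note.

## The synthetic generator

The generator is the package's stand-in for the two non-public study
cohorts; it emulates their *marginal* statistics, not their sequences.

- **Clinical fixtures** reproduce the published cohort description
  exactly: N=114 (ages 7/26/41/35/5/0 across ≤49…≥80/unknown, gender
  64/50/0, pathology 92/22, stage 78/16/18/0/2) and N=1060 (ages
  44/163/310/317/56/170, gender 628/429/3, pathology 603/457, stage
  526/286/184/36/28). Each margin is assigned independently in blocks
  over deterministic person ids 1..N; only the margins are contractual,
  joint distributions are not modelled. Ages are stored as bin
  representatives (45/55/65/75/85/unknown).
- **Variant cohorts**: per patient, each panel gene mutates
  independently with its configured probability; a mutated patient-gene
  receives 1 + Poisson(λ=0.3) variants (λ exists to exercise
  per-patient-gene deduplication and waterfall priority; it is config).
  Features and structural classes are drawn from weight tables, with two
  consistency overrides: frameshift/inframe variants become
  insertion/deletion, and CNV/translocation draws carry no protein-level
  change and the feature `other`. Hotspot patterns are injected
  independently per patient with their own probabilities; an `Xaa`
  wildcard is instantiated uniformly over the 19 non-reference
  residues. Generated protein HGVS always re-parses, so generated
  databases validate clean. One `numpy` generator seeded from the spec
  drives everything; identical spec + seed gives byte-identical dumps.
- **The two-site conditions** (`two_site_fixture`): site A, n=114, panel
  cohort with all six structural classes; site B, n=1060, SNP/INDEL
  only; both on the bundled 49-gene panel (the panel list is this
  package's own curation — the 15 genes profiled in the source figures
  plus well-known cancer genes). Gene and hotspot probabilities encode
  the published contrasts: EGFR p.Leu858Arg 0.175 vs 0.0264 (ratio
  6.6), KRAS codon-12 0.085 vs 0.172 (ratio 2.0), gene-level EGFR
  0.895 vs 0.115. Because injected hotspots and CNV reclassification
  dilute the configured weight tables, backgrounds are calibrated so the
  *realized* compositions land at the published values: site A
  background intron+synonymous weight 0.88 → realized ≈ 0.83; site B
  background missense weight 0.70 → realized ≈ 0.73; EGFR/KRAS gene
  backgrounds likewise account for the union with their hotspot
  carriers. Site B's gene probabilities are chosen so the two top-10
  lists overlap in five genes (TP53, EGFR, MET, APC, ATM), giving the
  15-gene union profile, with a ≥4-standard-error gap at the 10th/11th
  boundary so the union size is stable under sampling noise.

What passing tests on synthetic data do **not** show: fidelity to real
mutational signatures, hotspot clustering beyond the configured
patterns, co-mutation/exclusivity structure, sequencing artefacts, or
real panels' gene lists. The generator demonstrates that the model,
ETL, and analytics are correct and that the published cross-site
contrasts are recoverable under the stated marginal conditions — not
that those conditions exhaust real data.

## Numerical and edge-case choices

- Rounding: ties-away-from-zero via `decimal` (banker's rounding would
  print 80.7% as 80.7 but 16.05 as 16.0 instead of 16.1).
- `chi_squared_2x2` raises on tables with an empty outcome margin
  (statistic undefined); comparisons record these as "degenerate table;
  no test" instead of failing the whole report.
- Empty cohorts raise `empty_cohort`; a profiled gene with no variants
  is a zero-frequency row, not an error.
- Tie-breaks are alphabetical (gene ordering at equal frequency) or by
  surrogate key (patient ordering), never insertion order.
- The acceptance study replicates the two-site draw 200 times
  (114+1060 patients each, a fraction of a second per draw) and
  averages per-site frequencies before forming ratios, which keeps the
  Monte-Carlo error of the headline ratios near two percent; problem
  sizes were chosen so the whole script runs in about a minute.

## Known limitations

- The HGVS parser intentionally covers the clinical-report subset of
  the standard; DNA-level (`c.`) strings are stored verbatim, not
  parsed, and there is no transcript-aware c.↔p. projection.
- Pattern matching is positional and literal: it cannot identify that
  two differently normalized HGVS strings denote the same physical
  event (no sequence-level normalization).
- The one-sample-per-patient rule uses collection dates when present
  and barcode order otherwise; with neither, the choice is arbitrary
  but deterministic.
- SQLite is single-writer; the model targets desk-scale cohorts
  (10²–10⁴ patients), not warehouse deployments.
- k-suppression bounds disclosure per report; it does not defend
  against adversarial repeated querying across many reports.
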