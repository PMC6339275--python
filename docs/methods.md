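# Methods

## Classification model

Each reportable alteration in a test is classified against a curated
knowledgebase of disease–biomarker–therapy associations:

1. **Same-tumor curated evidence.** Every level-1 (companion-diagnostic
   label) and level-2 (practice-guideline) association whose biomarker
   pattern matches the variant *and* whose tumor type equals the test's
   tumor type is collected; the strongest matched level is the variant's
   level. Matching is exhaustive — all matching rows are retained for
   reporting, including coexisting resistance (contraindication) rows.
2. **Level 3.** With no same-tumor curated match, the variant is level 3
   if either (a) *off-label route*: it matches a non-contraindication
   level-1 label row for a different tumor type — a resistance marker
   observed elsewhere is not a therapy opportunity, so contraindication
   rows never confer off-label evidence, and level-2 guideline rows are
   deliberately excluded from this route because the off-label notion is
   tied to drug labels; or (b) *gene-target route*: the gene is on the
   configured trial-inclusion/direct-target list (66 genes by default).
3. **VUTS** otherwise.

Pattern scopes mirror how labels and guidelines express biomarkers: a
named protein change (`V600E`), a codon set (RAS codons 12/13/61/117/146),
an exon set optionally restricted by variant class ("exon 19 deletion",
"exon 20 insertion"), any small variant in a gene, amplification,
homozygous deletion, fusion (optionally partner-specific), and exon
skipping. Matching keys are protein-level (HGVS-p short form); genomic
coordinates are not interpreted. Exon numbers are taken as annotated in
the input; transcript-numbering disputes are out of scope.

A variant with both a contraindication and a sensitizing match at the same
level (lung *EGFR* T790M: gefitinib resistance + osimertinib sensitivity)
takes that level with `contraindicated_only = False`, since an actionable
sensitizing option exists. Therapies are never ranked; reports list all.

## Gates preceding classification

* **Depth QC** — small variants (SNV/insertion/deletion/indel) require
  ≥ 457 reads (the panel's validated minimum; configurable). Copy-number
  and fusion calls are exempt; a missing depth passes with a warning.
* **Reportability** — small variants in hotspot (oncogene) genes are
  reportable as called; small variants in full-coding (tumor-suppressor)
  genes require SIFT = deleterious AND PolyPhen = damaging. Copy-number
  gain requires the gene on the gain panel and copy number ≥ 6 ("high-level
  amplification"); loss requires the loss panel and copy number ≤ 0.5
  ("homozygous deletion"); both thresholds are configurable choices, as the
  source assay publishes no numeric cutoffs. Fusions and exon skips require
  the gene on the RNA fusion panel.
* **ACMG flag** — a small variant in one of the configured ACMG
  secondary-findings genes is annotated for germline follow-up; the flag
  never alters the evidence level, and (by design) copy-number events are
  not flagged. Germline status itself is not modeled.

## Aggregation and agreement analysis

A test's **most actionable** level is the strongest level among its
reportable variants; a test with zero reportable variants falls in the
VUTS bucket with a zero-variant marker. A level-1 test is flagged
`level1_contraindicated_only` when *every* level-1 variant it carries is
contraindication-only (the *KRAS*/*NRAS* colorectal situation); the
headline targeted-therapy rate is reported both over all level-1 tests and
excluding the flagged ones — the exclusion drops tests, not their other
variants.

Recommendations are one of eight categories (targeted therapy, precision
trial, immunotherapy, hormonal, chemo/radiation, surgery, transplant,
non-therapeutic). Eligibility requires ≥ 60 days of post-test follow-up;
a recommendation dated beyond the 120-day capture window counts as
missing. One recommendation per test (the first in-window one) is
cross-tabulated against the four most-actionable buckets; empty buckets
yield undefined (NaN) rates, never zero. An **off-label hit** is a variant
with at least one off-label-qualifying match and no same-tumor curated
match; the off-label census is scoped to tests with no level-1/2 evidence
(most-actionable = level 3), and uptake is the number of off-label
variants in tests whose recommendation was targeted therapy, over all
off-label variants.

## Knowledgebase content choices

* One printed association row whose variant vocabulary spans several
  machine patterns becomes several entries sharing a `row_id`.
* "BRCA mutation" (ovarian, level 1) is two gene-level rows (BRCA1,
  BRCA2), matching how gene censuses report them downstream.
* The therapy-class token "EGFR tyrosine kinase inhibitor" expands to the
  unique agents enumerated alongside it (afatinib, erlotinib, gefitinib,
  osimertinib).
* "Gastric/GEJ" maps to the controlled-vocabulary term "Stomach"; the
  tumor vocabulary is the fixed 29-term list of the cohort, plus a
  wildcard `ANY` supported by the schema.
* The copy-number-gain panel list is completed with MET, MYC, MYCL and
  MDM2, which the association table (MET amplification in lung) and the
  level-3 census require but the printed gain list omits.
* The ACMG gene default is the subset of panel genes on the ACMG
  secondary-findings list; both it and the level-3 gene-target list are
  configurable fields of the knowledgebase file.

## The synthetic cohort

The **fixture** is a fully enumerated, seed-free cohort of 657 tests (646
patients; 11 repeat tests assigned to lung-cancer patients) designed so
that running the *real* pipeline over it reproduces the published
marginals: 2778 alterations (92 level 1 / 109 level 2 / 1532 level 3 /
1045 VUTS); most-actionable buckets 89 / 100 / 419 / 49; the level-3
per-gene census (TP53 310 variants in 280 tests, ATM 158/139, …); 111
off-label variants in 90 tests, 90 of them BRCA1/2; tumor-type, stage,
sex, age and prior-treatment marginals; and the recommendation
cross-tabulation (targeted therapy 26/89, 11/100, 15/419, 0/49; the
contraindication-excluded level-1 rate 26/54). Where the source tables
constrain only variant families, exemplar alleles are chosen in fixed
rotations (e.g. KRAS G12D/G13D/Q61H/A146T for "codon 12/13/61/146");
placements the tables leave unconstrained (which tumor types host which
level-3/VUTS variants beyond the published censuses) are arbitrary but
deterministic, allocated round-robin across tumor types under per-gene
tumor-exclusion rules that prevent a placement from accidentally matching
a same-tumor curated row. VUTS variants are drawn from panel genes with no
therapy association at any level and are reportable by construction
(hotspot genes with unknown/tolerated calls; a few deleterious
tumor-suppressor variants in non-target genes). Three source-internal
count conflicts (single/double level-1 variant split; level-2 rows that
cannot arise from the published level-1/2 association table; a level-3
test share whose printed percentage does not match its own printed counts)
are resolved in favor of the table-level censuses; the affected level-2
variants are reallocated to the dominant level-2 class (KRAS, lung) so
that every downstream total and rate is preserved.

The **random generator** samples a seeded cohort from a `CohortSpec`:
per-test most-actionable bucket from normalized per-level weights, tumor
type from the configured mix (redrawn from the bucket-compatible subset
when curated evidence requires specific tumor types), one anchor variant
realizing the bucket, Poisson-distributed filler variants at weaker
levels, and recommendations from a bucket × category rate matrix. The same
seed always yields identical tables; a missing seed is an error.

Neither generator models allele frequencies, mutational signatures,
clonality, tumor purity, or realistic variant co-occurrence beyond the
constraints above — passing tests demonstrate the pipeline's bookkeeping
and ordering logic on knowledgebase-faithful inputs, not performance on
real sequencing data.

## Numerical and reporting conventions

Percentages are rounded to the nearest integer percent; the mean
alterations per test to one decimal; the level-3 per-gene test fraction to
two decimals (denominator 657). Report rendering is deterministic (level
rank, then gene, then protein change). Problem sizes: the fixture analysis
is 657 tests × ~4.2 variants (sub-second); property suites use 1000 random
variant/tumor pairs for ordering oracles and a 10,000-test seeded cohort
for the convergence check (a few seconds).

## Known limitations

* The knowledgebase is a June-2017 snapshot; updates are manual file
  edits (no live querying of trial registries, labels or guidelines).
* Variant calling, annotation (SIFT/PolyPhen, population frequency) and
  transcript selection happen upstream; inputs must arrive annotated.
* Multi-exon indels rely on the exon annotation supplied in the input.
* Drug ranking, dosing, toxicity, germline confirmation workflows, and
  outcome/survival analysis are out of scope.
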