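# oncotier

Three-tier somatic variant actionability classification for tumor NGS
panels, with a treatment-recommendation agreement analysis and a synthetic
cohort generator.

## The problem

Comprehensive tumor sequencing panels report dozens of alterations per
specimen, but only a fraction carry evidence that should change therapy.
US regulatory guidance for NGS tumor profiling recognizes three evidence
levels for a disease–biomarker–drug association:

* **Level 1 (companion diagnostic)** — the biomarker is required on an
  approved drug label for that tumor type (e.g. *EGFR* L858R → EGFR TKIs in
  lung cancer);
* **Level 2 (practice guideline)** — the association is supported by
  professional guidelines (NCCN/ESMO) rather than a label, including
  resistance associations (e.g. *KRAS* mutation → EGFR-TKI non-response in
  lung cancer);
* **Level 3 (trial / off-label)** — the biomarker supports enrollment in a
  precision-medicine trial, or it is a label-listed biomarker observed in a
  tumor type outside its label ("off-label");
* **VUTS** — a reportable variant of unknown therapeutic significance.

A special case is the **resistance contraindication**: *KRAS*/*NRAS*
mutations in colorectal cancer are companion-diagnostic (level 1)
biomarkers, but they argue *against* anti-EGFR antibodies rather than for
any drug. Headline "actionability" rates are therefore reported both with
and without tests whose level-1 evidence is contraindication-only.

`oncotier` implements this classification engine end to end for a 144-gene
pan-cancer panel: a machine-readable knowledgebase of tiered associations
with pattern matching at nucleotide/codon/exon/gene/fusion granularity;
read-depth QC (minimum 457 reads for small variants) and the dual
reporting strategy (hotspot reporting for oncogenes; full-coding reporting
for tumor suppressors, gated on concordant deleterious SIFT + PolyPhen
calls); per-test aggregation to the *most actionable* level; ACMG
secondary-findings disclosure flags; and a cross-tabulation of per-test
evidence against eight physician treatment-recommendation categories
captured within a 120-day post-test window (≥ 60 days follow-up required).

Because the cohort this models is not publicly deposited, the package
ships a deterministic synthetic cohort generator whose 657 tests, when run
through the real pipeline, reproduce the study's published marginals
exactly (per-level variant and test censuses, level-3 per-gene census,
off-label structure, recommendation cross-tabulation), plus a seeded
random generator for property testing.

## Worked example

```python
from oncotier import (ObservedVariant, VariantClass, classify_variant,
                      summarize_test, write_report, load_knowledgebase)

kb = load_knowledgebase()                 # bundled June-2017 knowledgebase
variants = [
    ObservedVariant(gene="EGFR", variant_class=VariantClass.SNV,
                    protein_change="L858R", exon=21, read_depth=980),
    ObservedVariant(gene="EGFR", variant_class=VariantClass.SNV,
                    protein_change="T790M", exon=20, read_depth=912),
    ObservedVariant(gene="TP53", variant_class=VariantClass.SNV,
                    protein_change="R175H", read_depth=850,
                    sift_call="DELETERIOUS", polyphen_call="DAMAGING"),
]
tc = summarize_test([classify_variant(v, "Lung", kb) for v in variants],
                    test_id="T0001")
print(write_report(tc, kb))
```

prints:

```
# NGS test report — T0001

Most actionable evidence: **Level 1**

## Level 1
- EGFR L858R — therapies: afatinib, bevacizumab + erlotinib, erlotinib, gefitinib, osimertinib
- EGFR T790M — therapies: osimertinib — contraindicated: gefitinib

## Level 3
- TP53 R175H [ACMG]

ACMG disclosure: one or more variants occur in genes on the ACMG secondary-findings list and may be of germline origin; germline testing is advised if clinically applicable.
```

Both *EGFR* variants are companion-diagnostic level 1 in lung cancer —
T790M simultaneously contraindicates gefitinib and indicates osimertinib,
so the test is not flagged contraindication-only. *TP53* has no
label/guideline therapy but sits on the trial-target list (level 3) and on
the ACMG disclosure list.

### Command line

```
oncotier simulate --fixture --out cohort/        # deterministic 657-test cohort
oncotier classify --variants cohort/fixture_variants.tsv \
                  --cohort cohort/fixture_cohort.tsv --out results/
oncotier analyze  --variants cohort/fixture_variants.tsv \
                  --cohort cohort/fixture_cohort.tsv --out agreement.json
```

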