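"""Per-test aggregation, cohort censuses, and report rendering.

A test's headline is its *most actionable* level: the strongest evidence
level among its reportable variants (VUTS when nothing reaches level 3,
including the zero-reportable-variant case). A level-1 test whose level-1
evidence consists solely of resistance contraindication rows (the RAS /
anti-EGFR colorectal situation) is flagged, because downstream the headline
targeted-therapy agreement rate is also reported excluding those tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .classify import ClassifiedVariant, classify_variant
from .knowledgebase import Knowledgebase
from .levels import EvidenceLevel, strongest
from .variants import TestRecord, qc_filter, reportability_gate


@dataclass(frozen=True)
class TestClassification:
    """Aggregated classification of one test."""

    test_id: str
    classified: tuple[ClassifiedVariant, ...]
    most_actionable: EvidenceLevel
    level1_contraindicated_only: bool
    off_label_hits: tuple[ClassifiedVariant, ...]

    @property
    def n_reportable(self) -> int:
        return len(self.classified)

    @property
    def zero_variant(self) -> bool:
        """Marker distinguishing a test with no reportable variants from a
        test whose variants are all VUTS."""
        return not self.classified


@dataclass(frozen=True)
class CohortSummary:
    n_tests: int
    variant_level_counts: dict
    test_bucket_counts: dict
    mean_variants_per_test: float
    level3_gene_table: pd.DataFrame


def summarize_test(classified, test_id: str = "") -> TestClassification:
    """Reduce one test's classified variants to its most-actionable headline."""
    classified = tuple(classified)
    most = strongest(cv.best_level for cv in classified)
    l1 = [cv for cv in classified if cv.best_level is EvidenceLevel.LEVEL_1]
    l1_contra_only = bool(
        most is EvidenceLevel.LEVEL_1
        and l1
        and all(cv.contraindicated_only for cv in l1)
    )
    off_label = tuple(cv for cv in classified if cv.off_label)
    return TestClassification(
        test_id=test_id,
        classified=classified,
        most_actionable=most,
        level1_contraindicated_only=l1_contra_only,
        off_label_hits=off_label,
    )


def classify_test(record: TestRecord, kb: Knowledgebase) -> TestClassification:
    """Full per-test pipeline: depth QC, reportability gate, classification,
    aggregation. Variants failing either gate are dropped silently (they are
    not reportable alterations)."""
    kept = []
    for v in record.variants:
        if not qc_filter(v):
            continue
        if not reportability_gate(v, kb.panel):
            continue
        kept.append(classify_variant(v, record.tumor_type, kb))
    return summarize_test(kept, test_id=record.test_id)


def classify_cohort(records, kb: Knowledgebase) -> list[TestClassification]:
    return [classify_test(rec, kb) for rec in records]


def cohort_level_census(tests) -> CohortSummary:
    """Cohort-wide censuses: per-variant counts by assigned level, per-test
    counts by most-actionable level, mean reportable alterations per test,
    and the level-3 per-gene census (variants, tests, fraction of all tests
    to two decimals)."""
    tests = list(tests)
    if not tests:
        raise ValueError("empty cohort")
    n_tests = len(tests)

    variant_counts = {lv: 0 for lv in EvidenceLevel}
    bucket_counts = {lv: 0 for lv in EvidenceLevel}
    total_variants = 0
    gene_variants: dict[str, int] = {}
    gene_tests: dict[str, int] = {}

    for tc in tests:
        bucket_counts[tc.most_actionable] += 1
        genes_in_test = set()
        for cv in tc.classified:
            total_variants += 1
            variant_counts[cv.best_level] += 1
            if cv.best_level is EvidenceLevel.LEVEL_3:
                g = cv.variant.gene
                gene_variants[g] = gene_variants.get(g, 0) + 1
                genes_in_test.add(g)
        for g in genes_in_test:
            gene_tests[g] = gene_tests.get(g, 0) + 1

    rows = [
        {
            "gene": g,
            "n_variants": gene_variants[g],
            "n_tests": gene_tests[g],
            "fraction_of_tests": round(gene_tests[g] / n_tests, 2),
        }
        for g in gene_variants
    ]
    table = pd.DataFrame(rows, columns=["gene", "n_variants", "n_tests",
                                        "fraction_of_tests"])
    if len(table):
        table = table.sort_values(
            ["n_variants", "gene"], ascending=[False, True]
        ).reset_index(drop=True)

    return CohortSummary(
        n_tests=n_tests,
        variant_level_counts={lv.name: variant_counts[lv] for lv in EvidenceLevel},
        test_bucket_counts={lv.name: bucket_counts[lv] for lv in EvidenceLevel},
        mean_variants_per_test=total_variants / n_tests,
        level3_gene_table=table,
    )


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

def _variant_sort_key(cv: ClassifiedVariant):
    return (cv.best_level.rank, cv.variant.gene, cv.variant.protein_change or "")


def write_report(tc: TestClassification, kb: Knowledgebase,
                 fmt: str = "markdown") -> str:
    """Render a deterministic per-test report (markdown or JSON string).

    Variants are grouped by evidence level (strongest first), each with its
    matched therapies and contraindication markers; an ACMG disclosure
    paragraph is appended when any flagged gene is present.
    """
    ordered = sorted(tc.classified, key=_variant_sort_key)
    if fmt == "json":
        doc = {
            "test_id": tc.test_id,
            "most_actionable": tc.most_actionable.name,
            "level1_contraindicated_only": tc.level1_contraindicated_only,
            "variants": [
                {
                    "gene": cv.variant.gene,
                    "variant_class": cv.variant.variant_class.value,
                    "protein_change": cv.variant.protein_change,
                    "level": cv.best_level.name,
                    "contraindicated_only": cv.contraindicated_only,
                    "off_label": cv.off_label,
                    "therapies": list(cv.therapies),
                    "contraindicated_therapies": sorted({
                        t for m in cv.same_tumor_matches
                        if m.association.contraindication
                        for t in m.association.therapies
                    }),
                    "acmg_flag": cv.acmg_flag,
                }
                for cv in ordered
            ],
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    lines = [f"# NGS test report — {tc.test_id}", ""]
    if tc.zero_variant or tc.most_actionable is EvidenceLevel.VUTS:
        lines.append(
            "No variants were classified as having clinical significance "
            "for targeted therapy."
        )
        lines.append("")
    else:
        lines.append(f"Most actionable evidence: **{tc.most_actionable.label}**")
        if tc.level1_contraindicated_only:
            lines.append(
                "(all level 1 evidence indicates resistance to the associated "
                "targeted therapies)"
            )
        lines.append("")
    for level in EvidenceLevel:
        group = [cv for cv in ordered if cv.best_level is level]
        if not group:
            continue
        lines.append(f"## {level.label}")
        for cv in group:
            v = cv.variant
            desc = v.protein_change or v.variant_class.value
            entry = f"- {v.gene} {desc}"
            if cv.therapies:
                entry += f" — therapies: {', '.join(cv.therapies)}"
            contra = sorted({
                t for m in cv.same_tumor_matches
                if m.association.contraindication
                for t in m.association.therapies
            })
            if contra:
                entry += f" — contraindicated: {', '.join(contra)}"
            if cv.off_label:
                entry += " — off-label indication (other tumor type label)"
            if cv.acmg_flag:
                entry += " [ACMG]"
            lines.append(entry)
        lines.append("")
    if any(cv.acmg_flag for cv in ordered):
        lines.append(
            "ACMG disclosure: one or more variants occur in genes on the ACMG "
            "secondary-findings list and may be of germline origin; germline "
            "testing is advised if clinically applicable."
        )
        lines.append("")
    return "\n".join(lines)


def classification_to_frame(tests) -> pd.DataFrame:
    """Per-variant classification export (TSV-ready)."""
    rows = []
    for tc in tests:
        for cv in sorted(tc.classified, key=_variant_sort_key):
            rows.append({
                "test_id": tc.test_id,
                "gene": cv.variant.gene,
                "protein_change": cv.variant.protein_change or "",
                "variant_class": cv.variant.variant_class.value,
                "best_level": cv.best_level.name,
                "contraindicated_only": (
                    "" if cv.contraindicated_only is None
                    else str(cv.contraindicated_only).lower()
                ),
                "off_label": str(cv.off_label).lower(),
                "therapies": ";".join(cv.therapies),
                "acmg_flag": str(cv.acmg_flag).lower(),
            })
    return pd.DataFrame(rows, columns=[
        "test_id", "gene", "protein_change", "variant_class", "best_level",
        "contraindicated_only", "off_label", "therapies", "acmg_flag",
    ])
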