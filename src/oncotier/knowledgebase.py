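"""Therapeutic-association knowledgebase: schema, loading, pattern matching.

The knowledgebase encodes disease-biomarker-drug associations at two curated
evidence levels (companion-diagnostic label rows and practice-guideline
rows), a panel definition (which genes are covered by the hotspot,
full-coding, copy-number and fusion strategies), the gene list that confers
trial-level (level 3) evidence, the ACMG secondary-findings disclosure
genes, and the controlled tumor-type vocabulary.

A pattern addresses a biomarker at one of the scopes used on drug labels and
in guidelines: a named protein change, a codon set, an exon set, any small
variant in a gene, amplification, deletion, fusion, or exon skipping.
Resistance markers (e.g. RAS mutations versus anti-EGFR antibodies in
colorectal cancer) are ordinary rows flagged ``contraindication``.
"""

from __future__ import annotations

import enum
import json
from importlib import resources
from pathlib import Path
from typing import TYPE_CHECKING, Optional

from pydantic import BaseModel, field_validator, model_validator

from .levels import EvidenceLevel

if TYPE_CHECKING:  # pragma: no cover
    from .variants import ObservedVariant

#: Wildcard tumor type for cross-tumor rows.
ANY_TUMOR = "ANY"

_SMALL_CLASSES = frozenset({"SNV", "INSERTION", "DELETION", "INDEL"})


class PatternScope(str, enum.Enum):
    NAMED_SNV = "NAMED_SNV"
    CODON_SET = "CODON_SET"
    EXON_SET = "EXON_SET"
    GENE_ANY_MUTATION = "GENE_ANY_MUTATION"
    AMPLIFICATION = "AMPLIFICATION"
    DELETION = "DELETION"
    FUSION = "FUSION"
    EXON_SKIP = "EXON_SKIP"


class KnowledgebaseError(ValueError):
    """Schema or vocabulary violation while building/loading a knowledgebase."""


class VariantPattern(BaseModel):
    """Biomarker pattern at nucleotide/codon/exon/gene/fusion granularity.

    ``detail`` is scope-dependent: the protein-change string for NAMED_SNV,
    codon numbers for CODON_SET, exon numbers for EXON_SET (and optionally
    EXON_SKIP), the fusion partner for FUSION. ``classes`` optionally narrows
    an exon-scoped row to specific small-variant classes (an "exon 19
    deletion" row matches deletions only).
    """

    model_config = {"frozen": True}

    gene: str
    scope: PatternScope
    protein_change: Optional[str] = None
    codons: Optional[tuple[int, ...]] = None
    exons: Optional[tuple[int, ...]] = None
    fusion_partner: Optional[str] = None
    classes: Optional[tuple[str, ...]] = None

    @field_validator("gene")
    @classmethod
    def _upper(cls, v: str) -> str:
        if not v or not v.isupper() or " " in v:
            raise KnowledgebaseError(f"gene symbol must be an uppercase token: {v!r}")
        return v

    @model_validator(mode="after")
    def _detail_required(self) -> "VariantPattern":
        need = {
            PatternScope.NAMED_SNV: self.protein_change,
            PatternScope.CODON_SET: self.codons,
            PatternScope.EXON_SET: self.exons,
        }
        if self.scope in need and not need[self.scope]:
            raise KnowledgebaseError(
                f"{self.gene} {self.scope.value}: scope requires a detail payload"
            )
        return self

    def describe(self) -> str:
        s = self.scope
        if s is PatternScope.NAMED_SNV:
            return f"{self.gene} {self.protein_change}"
        if s is PatternScope.CODON_SET:
            return f"{self.gene} codon {'/'.join(map(str, self.codons))}"
        if s is PatternScope.EXON_SET:
            kind = "/".join(self.classes).lower() if self.classes else "mutation"
            return f"{self.gene} exon {'/'.join(map(str, self.exons))} {kind}"
        if s is PatternScope.GENE_ANY_MUTATION:
            return f"{self.gene} mutation"
        if s is PatternScope.AMPLIFICATION:
            return f"{self.gene} amplification"
        if s is PatternScope.DELETION:
            return f"{self.gene} deletion"
        if s is PatternScope.FUSION:
            return f"{self.gene} fusion"
        return f"{self.gene} exon {'/'.join(map(str, self.exons or ()))} skipping"


def match(pattern: VariantPattern, variant: "ObservedVariant") -> bool:
    """True iff the observed variant falls within the pattern's scope.

    Deterministic and pure; a scope/class mismatch (e.g. a codon-set pattern
    against a fusion) is simply False, never an exception.
    """
    if pattern.gene != variant.gene:
        return False
    vclass = variant.variant_class.value
    small = vclass in _SMALL_CLASSES
    scope = pattern.scope

    if scope is PatternScope.NAMED_SNV:
        if not small or not variant.protein_change:
            return False
        return variant.protein_change.replace(" ", "") == pattern.protein_change
    if scope is PatternScope.CODON_SET:
        return small and variant.codon is not None and variant.codon in pattern.codons
    if scope is PatternScope.EXON_SET:
        if not small or variant.exon is None or variant.exon not in pattern.exons:
            return False
        return vclass in pattern.classes if pattern.classes else True
    if scope is PatternScope.GENE_ANY_MUTATION:
        return small
    if scope is PatternScope.AMPLIFICATION:
        return vclass == "CNV_GAIN"
    if scope is PatternScope.DELETION:
        return vclass == "CNV_LOSS"
    if scope is PatternScope.FUSION:
        if vclass != "FUSION":
            return False
        if pattern.fusion_partner:
            return variant.fusion_partner == pattern.fusion_partner
        return True
    if scope is PatternScope.EXON_SKIP:
        if vclass != "EXON_SKIP":
            return False
        return variant.exon in pattern.exons if pattern.exons else True
    return False  # pragma: no cover


class TherapeuticAssociation(BaseModel):
    """One disease-biomarker-therapy row at a given evidence level.

    ``row_id`` groups association entries that transcribe a single printed
    knowledgebase row whose pattern vocabulary spans several machine patterns
    (e.g. "V600E or V600K" becomes two NAMED_SNV entries sharing a row_id).
    """

    model_config = {"frozen": True}

    pattern: VariantPattern
    tumor_type: str
    level: EvidenceLevel
    therapies: tuple[str, ...]
    contraindication: bool = False
    source: str = ""
    row_id: Optional[str] = None

    @model_validator(mode="after")
    def _check(self) -> "TherapeuticAssociation":
        if not self.therapies:
            raise KnowledgebaseError(
                f"{self.pattern.describe()} ({self.tumor_type}): empty therapy list"
            )
        if self.level is EvidenceLevel.VUTS:
            raise KnowledgebaseError("VUTS is not a curated association level")
        return self


class PanelDefinition(BaseModel):
    """Gene sets covered by each assay strategy; a gene may appear in several."""

    model_config = {"frozen": True}

    hotspot_genes: frozenset[str]
    full_coding_genes: frozenset[str]
    cn_gain_genes: frozenset[str]
    cn_loss_genes: frozenset[str]
    fusion_genes: frozenset[str]

    @property
    def all_genes(self) -> frozenset[str]:
        return (self.hotspot_genes | self.full_coding_genes | self.cn_gain_genes
                | self.cn_loss_genes | self.fusion_genes)


class Knowledgebase(BaseModel):
    model_config = {"frozen": True}

    associations: tuple[TherapeuticAssociation, ...]
    panel: PanelDefinition
    level3_gene_targets: frozenset[str]
    acmg_genes: frozenset[str]
    tumor_type_vocabulary: frozenset[str]

    @model_validator(mode="after")
    def _validate(self) -> "Knowledgebase":
        vocab = self.tumor_type_vocabulary
        for i, assoc in enumerate(self.associations):
            if assoc.tumor_type != ANY_TUMOR and assoc.tumor_type not in vocab:
                raise KnowledgebaseError(
                    f"association {i} ({assoc.pattern.describe()}): unknown tumor "
                    f"type {assoc.tumor_type!r}; vocabulary: {sorted(vocab)}"
                )
            if assoc.pattern.gene not in self.panel.all_genes:
                raise KnowledgebaseError(
                    f"association {i}: gene {assoc.pattern.gene} not on panel"
                )
        return self

    def rows_at(self, level: EvidenceLevel) -> list[TherapeuticAssociation]:
        return [a for a in self.associations if a.level is level]


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _kb_to_dict(kb: Knowledgebase) -> dict:
    return {
        "associations": [
            {
                "gene": a.pattern.gene,
                "scope": a.pattern.scope.value,
                "protein_change": a.pattern.protein_change,
                "codons": list(a.pattern.codons) if a.pattern.codons else None,
                "exons": list(a.pattern.exons) if a.pattern.exons else None,
                "fusion_partner": a.pattern.fusion_partner,
                "classes": list(a.pattern.classes) if a.pattern.classes else None,
                "tumor_type": a.tumor_type,
                "level": a.level.name,
                "therapies": list(a.therapies),
                "contraindication": a.contraindication,
                "source": a.source,
                "row_id": a.row_id,
            }
            for a in kb.associations
        ],
        "panel": {
            "hotspot_genes": sorted(kb.panel.hotspot_genes),
            "full_coding_genes": sorted(kb.panel.full_coding_genes),
            "cn_gain_genes": sorted(kb.panel.cn_gain_genes),
            "cn_loss_genes": sorted(kb.panel.cn_loss_genes),
            "fusion_genes": sorted(kb.panel.fusion_genes),
        },
        "level3_gene_targets": sorted(kb.level3_gene_targets),
        "acmg_genes": sorted(kb.acmg_genes),
        "tumor_type_vocabulary": sorted(kb.tumor_type_vocabulary),
    }


def _kb_from_dict(doc: dict) -> Knowledgebase:
    try:
        assocs = []
        for i, row in enumerate(doc["associations"]):
            try:
                pattern = VariantPattern(
                    gene=row["gene"],
                    scope=PatternScope(row["scope"]),
                    protein_change=row.get("protein_change"),
                    codons=tuple(row["codons"]) if row.get("codons") else None,
                    exons=tuple(row["exons"]) if row.get("exons") else None,
                    fusion_partner=row.get("fusion_partner"),
                    classes=tuple(row["classes"]) if row.get("classes") else None,
                )
                assocs.append(TherapeuticAssociation(
                    pattern=pattern,
                    tumor_type=row["tumor_type"],
                    level=EvidenceLevel[row["level"]],
                    therapies=tuple(row["therapies"]),
                    contraindication=bool(row.get("contraindication", False)),
                    source=row.get("source", ""),
                    row_id=row.get("row_id"),
                ))
            except (KeyError, ValueError) as exc:
                raise KnowledgebaseError(
                    f"association row {i} ({row.get('gene', '?')}): {exc}"
                ) from exc
        panel = PanelDefinition(
            hotspot_genes=frozenset(doc["panel"]["hotspot_genes"]),
            full_coding_genes=frozenset(doc["panel"]["full_coding_genes"]),
            cn_gain_genes=frozenset(doc["panel"]["cn_gain_genes"]),
            cn_loss_genes=frozenset(doc["panel"]["cn_loss_genes"]),
            fusion_genes=frozenset(doc["panel"]["fusion_genes"]),
        )
        try:
            return Knowledgebase(
                associations=tuple(assocs),
                panel=panel,
                level3_gene_targets=frozenset(doc["level3_gene_targets"]),
                acmg_genes=frozenset(doc["acmg_genes"]),
                tumor_type_vocabulary=frozenset(doc["tumor_type_vocabulary"]),
            )
        except ValueError as exc:
            raise KnowledgebaseError(str(exc)) from exc
    except KeyError as exc:
        raise KnowledgebaseError(f"missing knowledgebase field: {exc}") from exc


def load_knowledgebase(path: Optional[str | Path] = None) -> Knowledgebase:
    """Load and validate a knowledgebase JSON file (bundled default if None)."""
    if path is None:
        text = resources.files("oncotier.data").joinpath("knowledgebase.json").read_text()
    else:
        text = Path(path).read_text()
    return _kb_from_dict(json.loads(text))


def save_knowledgebase(kb: Knowledgebase, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_kb_to_dict(kb), indent=1, sort_keys=True) + "\n")


def knowledgebase_to_tsv(kb: Knowledgebase, path: str | Path) -> None:
    """Flat TSV export: gene, scope, detail, tumor_type, level, therapies, ..."""
    lines = ["gene\tscope\tdetail\ttumor_type\tlevel\ttherapies\tcontraindication\tsource"]
    for a in kb.associations:
        p = a.pattern
        if p.scope is PatternScope.NAMED_SNV:
            detail = p.protein_change
        elif p.scope is PatternScope.CODON_SET:
            detail = ",".join(map(str, p.codons))
        elif p.scope in (PatternScope.EXON_SET, PatternScope.EXON_SKIP):
            detail = ",".join(map(str, p.exons or ()))
        elif p.scope is PatternScope.FUSION:
            detail = p.fusion_partner or ""
        else:
            detail = ""
        lines.append("\t".join([
            p.gene, p.scope.value, detail or "", a.tumor_type, a.level.name,
            ";".join(a.therapies), str(a.contraindication).lower(), a.source,
        ]))
    Path(path).write_text("\n".join(lines) + "\n")
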