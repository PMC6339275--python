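"""Evidence-level assignment for reportable variants.

The classification procedure for one reportable variant in one test:

1. Collect every level-1 and level-2 association whose pattern matches the
   variant and whose tumor type equals the test's tumor type (or the
   wildcard). The strongest such level is the variant's level.
2. Otherwise check level 3 by two routes: the off-label route — the variant
   matches a non-contraindication level-1 label row for a *different* tumor
   type (a resistance marker elsewhere is not a therapy opportunity, so
   contraindication rows never confer off-label evidence); or the
   gene-target route — the gene is on the trial-inclusion/direct-target
   list.
3. Otherwise the variant is a VUTS.

All matching rows are retained (reports list every association), flagged by
whether they matched in the test's own tumor context.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .knowledgebase import ANY_TUMOR, Knowledgebase, TherapeuticAssociation, match
from .levels import EvidenceLevel
from .variants import ObservedVariant


class UnknownTumorTypeError(ValueError):
    def __init__(self, tumor_type: str, vocabulary):
        super().__init__(
            f"unknown tumor type {tumor_type!r}; vocabulary: {sorted(vocabulary)}"
        )
        self.tumor_type = tumor_type


@dataclass(frozen=True)
class MatchRecord:
    """One association row matched by a variant's pattern."""

    association: TherapeuticAssociation
    same_tumor: bool

    @property
    def off_label_qualifying(self) -> bool:
        """Label (level-1) sensitizing row matched outside its tumor type."""
        return (
            not self.same_tumor
            and self.association.level is EvidenceLevel.LEVEL_1
            and not self.association.contraindication
        )


@dataclass(frozen=True)
class ClassifiedVariant:
    """A reportable variant with its assigned evidence and matched rows."""

    variant: ObservedVariant
    tumor_type: str
    matches: tuple[MatchRecord, ...]
    best_level: EvidenceLevel
    contraindicated_only: Optional[bool]
    acmg_flag: bool
    gene_target_hit: bool = field(default=False)

    @property
    def off_label(self) -> bool:
        """True when the variant's evidence includes the off-label route and
        nothing same-tumor at level 1/2 (i.e. level 3 via an off-label label)."""
        if self.best_level is not EvidenceLevel.LEVEL_3:
            return False
        return any(m.off_label_qualifying for m in self.matches)

    @property
    def same_tumor_matches(self) -> tuple[MatchRecord, ...]:
        return tuple(m for m in self.matches if m.same_tumor)

    @property
    def therapies(self) -> tuple[str, ...]:
        """Union of therapies across same-tumor matches at the best level
        (sensitizing rows only), deterministic order."""
        out: list[str] = []
        for m in self.same_tumor_matches:
            if m.association.level is self.best_level and not m.association.contraindication:
                for t in m.association.therapies:
                    if t not in out:
                        out.append(t)
        return tuple(sorted(out))


def flag_acmg(variant: ObservedVariant, kb: Knowledgebase) -> bool:
    """Germline-disclosure flag: small variant in an ACMG secondary-findings
    gene. Annotation only — never alters the evidence level."""
    return variant.is_small and variant.gene in kb.acmg_genes


def classify_variant(
    variant: ObservedVariant, tumor_type: str, kb: Knowledgebase
) -> ClassifiedVariant:
    """Assign evidence level(s) and matched associations for one variant."""
    if tumor_type not in kb.tumor_type_vocabulary:
        raise UnknownTumorTypeError(tumor_type, kb.tumor_type_vocabulary)

    matches = []
    for assoc in kb.associations:
        if match(assoc.pattern, variant):
            same = assoc.tumor_type == tumor_type or assoc.tumor_type == ANY_TUMOR
            matches.append(MatchRecord(association=assoc, same_tumor=same))
    matches = tuple(matches)

    same_tumor_levels = [m.association.level for m in matches if m.same_tumor]
    gene_target = variant.gene in kb.level3_gene_targets

    if same_tumor_levels:
        best = min(same_tumor_levels, key=lambda lv: lv.rank)
        contra_only = all(
            m.association.contraindication for m in matches
            if m.same_tumor and m.association.level.rank <= EvidenceLevel.LEVEL_2.rank
        )
    elif any(m.off_label_qualifying for m in matches) or gene_target:
        best = EvidenceLevel.LEVEL_3
        contra_only = None
    else:
        best = EvidenceLevel.VUTS
        contra_only = None

    if best.rank > EvidenceLevel.LEVEL_2.rank:
        contra_only = None

    return ClassifiedVariant(
        variant=variant,
        tumor_type=tumor_type,
        matches=matches,
        best_level=best,
        contraindicated_only=contra_only,
        acmg_flag=flag_acmg(variant, kb),
        gene_target_hit=gene_target,
    )
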