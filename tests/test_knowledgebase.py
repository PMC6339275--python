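"""Knowledgebase loading, census fidelity, and pattern matching."""

import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oncotier import (
    EvidenceLevel,
    KnowledgebaseError,
    ObservedVariant,
    PatternScope,
    VariantClass,
    VariantPattern,
    classify_variant,
    load_knowledgebase,
    match,
    save_knowledgebase,
)
from oncotier.knowledgebase import _kb_to_dict

# (gene, tumor type, contraindication) triples covered by the curated
# level-1 companion-diagnostic rows.
LEVEL1_TRIPLES = {
    ("ALK", "Lung", False),
    ("BRAF", "Melanoma", False),
    ("BRAF", "Lung", False),
    ("BRCA1", "Ovarian", False),
    ("BRCA2", "Ovarian", False),
    ("EGFR", "Lung", False),
    ("EGFR", "Lung", True),       # exon-20 insertion / T790M resistance rows
    ("ERBB2", "Breast", False),
    ("ERBB2", "Esophageal", False),
    ("ERBB2", "Stomach", False),
    ("KRAS", "Colorectal", True),
    ("NRAS", "Colorectal", True),
    ("ROS1", "Lung", False),
}

LEVEL2_TRIPLES = {
    ("ALK", "Sarcoma", False),
    ("ALK", "Lung", True),
    ("BRAF", "Thyroid", False),
    ("BRAF", "Colorectal", False),
    ("BRAF", "Lung", False),
    ("ERBB2", "Lung", False),
    ("ERBB2", "Head and Neck", False),
    ("ERBB2", "Breast", False),
    ("KIT", "Sarcoma", False),
    ("KIT", "Melanoma", False),
    ("KRAS", "Lung", True),
    ("MET", "Lung", False),
    ("NF1", "Sarcoma", True),
    ("PDGFRA", "Sarcoma", True),
    ("RET", "Lung", False),
    ("RET", "Thyroid", False),
    ("ROS1", "Lung", False),
    ("ROS1", "Lung", True),
}


def _small(gene, pc, exon=None, vclass=VariantClass.SNV, **kw):
    return ObservedVariant(gene=gene, variant_class=vclass, protein_change=pc,
                           exon=exon, read_depth=900, **kw)


def test_default_kb_census_row_for_row(kb):
    """Curated rows cover exactly the printed gene/tumor/flag combinations."""
    got1 = {(a.pattern.gene, a.tumor_type, a.contraindication)
            for a in kb.rows_at(EvidenceLevel.LEVEL_1)}
    got2 = {(a.pattern.gene, a.tumor_type, a.contraindication)
            for a in kb.rows_at(EvidenceLevel.LEVEL_2)}
    assert got1 == LEVEL1_TRIPLES
    assert got2 == LEVEL2_TRIPLES


def test_bundled_kb_key_rows(kb):
    alk = [a for a in kb.rows_at(EvidenceLevel.LEVEL_1)
           if a.pattern.gene == "ALK" and a.tumor_type == "Lung"]
    assert len(alk) == 1 and not alk[0].contraindication
    assert {"alectinib", "brigatinib", "ceritinib", "crizotinib"} <= set(alk[0].therapies)

    pdgfra = [a for a in kb.rows_at(EvidenceLevel.LEVEL_2)
              if a.pattern.gene == "PDGFRA"]
    assert len(pdgfra) == 1
    assert pdgfra[0].tumor_type == "Sarcoma"
    assert pdgfra[0].contraindication
    assert pdgfra[0].pattern.protein_change == "D842V"


def test_panel_definition(kb):
    p = kb.panel
    assert "KRAS" in p.hotspot_genes and "TP53" in p.full_coding_genes
    assert p.cn_loss_genes == p.full_coding_genes
    assert "ROS1" in p.fusion_genes and "ROS1" not in p.hotspot_genes
    # The gain list carries exactly four genes beyond the printed table,
    # required by the association and level-3 censuses.
    printed = {"ACVRL1", "AKT1", "APEX1", "AR", "ATP11B", "BCL2L1", "BCL9",
               "BIRC2", "BIRC3", "CCND1", "CCNE1", "CD274", "CD44", "CDK4",
               "CDK6", "CSNK2A1", "DCUN1D1", "EGFR", "ERBB2", "FGFR1",
               "FGFR2", "FGFR3", "FGFR4", "FLT3", "GAS6", "IGF1R"}
    assert printed < p.cn_gain_genes
    assert p.cn_gain_genes - printed == {"MDM2", "MET", "MYC", "MYCL"}


def test_roundtrip_serialization(kb, tmp_path):
    path = tmp_path / "kb.json"
    save_knowledgebase(kb, path)
    again = load_knowledgebase(path)
    assert _kb_to_dict(again) == _kb_to_dict(kb)


def test_empty_kb_classifies_level3_or_vuts(kb, tmp_path):
    doc = _kb_to_dict(kb)
    doc["associations"] = []
    path = tmp_path / "empty.json"
    path.write_text(json.dumps(doc))
    empty = load_knowledgebase(path)
    assert len(empty.associations) == 0
    cv = classify_variant(_small("EGFR", "L858R", exon=21), "Lung", empty)
    assert cv.best_level is EvidenceLevel.LEVEL_3  # gene-target route only
    cv2 = classify_variant(_small("CTNNB1", "S45F"), "Lung", empty)
    assert cv2.best_level is EvidenceLevel.VUTS


def test_unknown_tumor_type_rejected(kb, tmp_path):
    doc = _kb_to_dict(kb)
    doc["associations"][0]["tumor_type"] = "Klingon"
    path = tmp_path / "bad.json"
    path.write_text(json.dumps(doc))
    with pytest.raises(KnowledgebaseError, match="Klingon"):
        load_knowledgebase(path)


@pytest.mark.parametrize(
    "pattern,variant,expected",
    [
        (VariantPattern(gene="BRAF", scope=PatternScope.NAMED_SNV,
                        protein_change="V600E"),
         _small("BRAF", "V600E", exon=15), True),
        (VariantPattern(gene="KRAS", scope=PatternScope.CODON_SET,
                        codons=(12, 13, 61, 146)),
         _small("KRAS", "G12D", exon=2), True),
        (VariantPattern(gene="EGFR", scope=PatternScope.EXON_SET, exons=(19,),
                        classes=("DELETION",)),
         _small("EGFR", "L858R", exon=21), False),
        # scope/class mismatch is False, never an exception
        (VariantPattern(gene="ALK", scope=PatternScope.CODON_SET, codons=(12,)),
         ObservedVariant(gene="ALK", variant_class=VariantClass.FUSION,
                         fusion_partner="EML4"), False),
        (VariantPattern(gene="EGFR", scope=PatternScope.EXON_SET, exons=(19,),
                        classes=("DELETION",)),
         _small("EGFR", "E746_A750del", exon=19, vclass=VariantClass.DELETION),
         True),
        (VariantPattern(gene="ERBB2", scope=PatternScope.AMPLIFICATION),
         ObservedVariant(gene="ERBB2", variant_class=VariantClass.CNV_GAIN,
                         copy_number=9), True),
        (VariantPattern(gene="MET", scope=PatternScope.EXON_SKIP, exons=(14,)),
         ObservedVariant(gene="MET", variant_class=VariantClass.EXON_SKIP,
                         exon=14), True),
        # spaces in the observed protein change are normalized before comparison
        (VariantPattern(gene="EGFR", scope=PatternScope.NAMED_SNV,
                        protein_change="T790M"),
         _small("EGFR", "T790 M", exon=20), True),
    ],
)
def test_match_examples(pattern, variant, expected):
    assert match(pattern, variant) is expected


@given(
    gene_a=st.sampled_from(["KRAS", "NRAS", "BRAF"]),
    gene_b=st.sampled_from(["KRAS", "NRAS", "BRAF"]),
    codon=st.integers(min_value=1, max_value=700),
)
@settings(max_examples=60, deadline=None)
def test_match_requires_same_gene_and_is_pure(gene_a, gene_b, codon):
    pattern = VariantPattern(gene=gene_a, scope=PatternScope.CODON_SET,
                             codons=(codon,))
    variant = _small(gene_b, f"G{codon}D")
    first = match(pattern, variant)
    assert first == match(pattern, variant)          # purity
    if gene_a != gene_b:
        assert first is False


def test_detail_required_for_scoped_patterns():
    with pytest.raises(ValueError, match="detail"):
        VariantPattern(gene="KRAS", scope=PatternScope.CODON_SET)
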