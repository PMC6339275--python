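"""Construction of the bundled default knowledgebase.

The curated rows transcribe the June-2017 companion-diagnostic (level 1) and
practice-guideline (level 2) association tables of the 144-gene pan-cancer
panel this package models, the panel's per-strategy gene lists, the 67-gene
trial/off-label (level 3) target list, and the ACMG secondary-findings
disclosure genes. The canonical on-disk artifact is
``oncotier/data/knowledgebase.json`` (regenerated from here by
``scripts/build_kb.py``); both routes load through the same validator.

Notes on the transcription:

* A printed row whose variant vocabulary spans several machine patterns
  ("V600E or V600K"; "amplification or exon 14 skipping") becomes several
  association entries sharing a ``row_id``.
* "BRCA mutation" (ovarian) is encoded as two gene-level rows (BRCA1,
  BRCA2), matching how downstream gene censuses report them.
* The therapy-class token "EGFR tyrosine kinase inhibitor" expands to the
  unique agents enumerated with it (afatinib, erlotinib, gefitinib,
  osimertinib).
* "Gastric/GEJ" maps to the vocabulary term "Stomach".
* The copy-number-gain panel list is completed with MET, MYC, MYCL and MDM2,
  which the association and level-3 tables require but the printed gain list
  (truncated mid-alphabet) omits.
"""

from __future__ import annotations

from .knowledgebase import (
    ANY_TUMOR,
    Knowledgebase,
    PanelDefinition,
    PatternScope,
    TherapeuticAssociation,
    VariantPattern,
)
from .levels import EvidenceLevel

TUMOR_TYPES = (
    "Bladder", "Brain", "Breast", "Cervical", "Colorectal", "Endocrine",
    "Endometrial", "Esophageal", "Eye", "Female Genital", "Gallbladder",
    "Head and Neck", "Kidney and Renal Pelvis", "Liver and Bile Duct", "Lung",
    "Melanoma", "Mesothelioma", "Neuroendocrine Tumors", "Non-Melanoma Skin",
    "Ovarian", "Pancreatic", "Prostate", "Sarcoma", "Small Intestine",
    "Stomach", "Testicular", "Thymic", "Thyroid", "Unknown Primary",
)

HOTSPOT_GENES = (
    "ABL1", "AKT1", "ALK", "AR", "ARAF", "BRAF", "BTK", "CBL", "CDK4",
    "CHEK2", "CSF1R", "CTNNB1", "DDR2", "DNMT3A", "EGFR", "ERBB2", "ERBB3",
    "ERBB4", "ESR1", "EZH2", "FGFR1", "FGFR2", "FGFR3", "FLT3", "FOXL2",
    "GATA2", "GNA11", "GNAQ", "GNAS", "HNF1A", "HRAS", "IDH1", "IDH2",
    "IFITM1", "IFITM3", "JAK1", "JAK2", "JAK3", "KDR", "KIT", "KNSTRN",
    "KRAS", "MAGOH", "MAP2K1", "MAP2K2", "MAPK1", "MAX", "MED12", "MET",
    "MLH1", "MPL", "MTOR", "MYD88", "NFE2L2", "NPM1", "NRAS", "PAX5",
    "PDGFRA", "PIK3CA", "PPP2R1A", "PTPN11", "RAC1", "RAF1", "RET", "RHEB",
    "RHOA", "SF3B1", "SMO", "SPOP", "SRC", "STAT3", "U2AF1", "XPO1",
)

FULL_CODING_GENES = (
    "APC", "ATM", "BAP1", "BRCA1", "BRCA2", "CDH1", "CDKN2A", "FBXW7",
    "GATA3", "MSH2", "NF1", "NF2", "NOTCH1", "PIK3R1", "PTCH1", "PTEN",
    "RB1", "SMAD4", "SMARCB1", "STK11", "TET2", "TP53", "TSC1", "TSC2",
    "VHL", "WT1",
)

#: Gain genes as printed; see module docstring for the four-gene completion.
CN_GAIN_GENES_PRINTED = (
    "ACVRL1", "AKT1", "APEX1", "AR", "ATP11B", "BCL2L1", "BCL9", "BIRC2",
    "BIRC3", "CCND1", "CCNE1", "CD274", "CD44", "CDK4", "CDK6", "CSNK2A1",
    "DCUN1D1", "EGFR", "ERBB2", "FGFR1", "FGFR2", "FGFR3", "FGFR4", "FLT3",
    "GAS6", "IGF1R",
)
CN_GAIN_SUPPLEMENT = ("MDM2", "MET", "MYC", "MYCL")
CN_GAIN_GENES = CN_GAIN_GENES_PRINTED + CN_GAIN_SUPPLEMENT

CN_LOSS_GENES = FULL_CODING_GENES

FUSION_GENES = (
    "ABL1", "AKT3", "ALK", "AXL", "BRAF", "EGFR", "ERBB2", "ERG", "ETV1",
    "ETV4", "ETV5", "FGFR1", "FGFR2", "FGFR3", "MET", "NTRK1", "NTRK2",
    "NTRK3", "PDGFRA", "PPARG", "RAF1", "RET", "ROS1",
)

#: 67 genes with trial-inclusion / direct-target (level 3) evidence.
LEVEL3_GENE_TARGETS = (
    "TP53", "ATM", "CDKN2A", "BRCA2", "PTEN", "BRCA1", "PIK3CA", "TSC2",
    "KDR", "NF1", "MET", "RB1", "PTCH1", "STK11", "FBXW7", "NF2", "NRAS",
    "APC", "TSC1", "KRAS", "IDH1", "CDK4", "CSF1R", "EGFR", "BRAF", "ERBB2",
    "FGFR3", "FGFR1", "AKT1", "SMO", "MSH2", "CCND1", "KIT", "PIK3R1", "RET",
    "SMARCB1", "CHEK2", "CCNE1", "MYC", "BAP1", "ERBB4", "DDR2", "FLT3",
    "MAP2K1", "ALK", "ESR1", "GNA11", "ERBB3", "HRAS", "ABL1", "JAK2",
    "MTOR", "MYCL", "NFE2L2", "NTRK1", "MAPK1", "AR", "CDK6", "FGFR2",
    "JAK1", "WT1", "MDM2", "NTRK3", "RAF1", "SRC", "IDH2",
)

#: Panel genes on the ACMG secondary-findings disclosure list (configurable).
ACMG_GENES = (
    "APC", "BRCA1", "BRCA2", "MLH1", "MSH2", "PTEN", "RB1", "RET", "SMAD4",
    "STK11", "TP53", "TSC1", "TSC2", "VHL", "WT1",
)

EGFR_TKI = ("afatinib", "erlotinib", "gefitinib", "osimertinib")

_SMALL = ("SNV", "INSERTION", "DELETION", "INDEL")


def _named(gene, pc):
    return VariantPattern(gene=gene, scope=PatternScope.NAMED_SNV, protein_change=pc)


def _codons(gene, *codons):
    return VariantPattern(gene=gene, scope=PatternScope.CODON_SET, codons=tuple(codons))


def _exons(gene, exons, classes=None):
    return VariantPattern(gene=gene, scope=PatternScope.EXON_SET,
                          exons=tuple(exons), classes=classes)


def _gene_any(gene):
    return VariantPattern(gene=gene, scope=PatternScope.GENE_ANY_MUTATION)


def _amp(gene):
    return VariantPattern(gene=gene, scope=PatternScope.AMPLIFICATION)


def _fusion(gene):
    return VariantPattern(gene=gene, scope=PatternScope.FUSION)


def _skip(gene, exon):
    return VariantPattern(gene=gene, scope=PatternScope.EXON_SKIP, exons=(exon,))


def _rows():
    L1, L2 = EvidenceLevel.LEVEL_1, EvidenceLevel.LEVEL_2
    r = []

    def add(row_id, pattern, tumor, level, therapies, contra=False, source=""):
        r.append(TherapeuticAssociation(
            pattern=pattern, tumor_type=tumor, level=level,
            therapies=tuple(therapies), contraindication=contra,
            source=source or ("FDA/EMA label" if level is L1 else "NCCN/ESMO guideline"),
            row_id=row_id,
        ))

    # ----- Level 1: companion diagnostics -----
    add("L1-ALK-LUNG", _fusion("ALK"), "Lung", L1,
        ["alectinib", "brigatinib", "ceritinib", "crizotinib"])
    for pc in ("V600E", "V600K"):
        add("L1-BRAF-MEL", _named("BRAF", pc), "Melanoma", L1,
            ["cobimetinib + vemurafenib", "dabrafenib", "dabrafenib + trametinib",
             "trametinib", "vemurafenib"])
        add("L1-BRAF-LUNG", _named("BRAF", pc), "Lung", L1,
            ["dabrafenib + trametinib"])
    for gene in ("BRCA1", "BRCA2"):
        add("L1-BRCA-OV", _gene_any(gene), "Ovarian", L1, ["olaparib", "rucaparib"])
    add("L1-EGFR-EX19DEL", _exons("EGFR", (19,), ("DELETION",)), "Lung", L1,
        ["afatinib", "bevacizumab + erlotinib", "erlotinib", "gefitinib", "osimertinib"])
    add("L1-EGFR-EX20INS", _exons("EGFR", (20,), ("INSERTION",)), "Lung", L1,
        ["gefitinib"], contra=True)
    add("L1-EGFR-G719", _codons("EGFR", 719), "Lung", L1, ["afatinib", "gefitinib"])
    add("L1-EGFR-L858R", _named("EGFR", "L858R"), "Lung", L1,
        ["afatinib", "bevacizumab + erlotinib", "erlotinib", "gefitinib", "osimertinib"])
    add("L1-EGFR-L861Q", _named("EGFR", "L861Q"), "Lung", L1, ["afatinib", "gefitinib"])
    add("L1-EGFR-S768I", _named("EGFR", "S768I"), "Lung", L1, ["afatinib", "gefitinib"])
    add("L1-EGFR-T790M-R", _named("EGFR", "T790M"), "Lung", L1,
        ["gefitinib"], contra=True)
    add("L1-EGFR-T790M-S", _named("EGFR", "T790M"), "Lung", L1, ["osimertinib"])
    add("L1-ERBB2-BREAST", _amp("ERBB2"), "Breast", L1,
        ["ado-trastuzumab emtansine", "lapatinib + aromatase inhibitor",
         "lapatinib + chemo", "lapatinib + trastuzumab", "neratinib",
         "pertuzumab + trastuzumab + chemo", "trastuzumab",
         "trastuzumab + aromatase inhibitor", "trastuzumab + chemo"])
    add("L1-ERBB2-ESO", _amp("ERBB2"), "Esophageal", L1,
        ["trastuzumab", "trastuzumab + chemo"])
    add("L1-ERBB2-GASTRIC", _amp("ERBB2"), "Stomach", L1,
        ["trastuzumab", "trastuzumab + chemo"])
    for gene in ("KRAS", "NRAS"):
        add(f"L1-{gene}-A146-A59", _codons(gene, 146, 59), "Colorectal", L1,
            ["cetuximab", "panitumumab"], contra=True)
        add(f"L1-{gene}-EX234", _exons(gene, (2, 3, 4)), "Colorectal", L1,
            ["cetuximab", "cetuximab + chemo", "panitumumab + chemo"], contra=True)
        add(f"L1-{gene}-CODONS", _codons(gene, 12, 13, 117, 61), "Colorectal", L1,
            ["cetuximab", "panitumumab"], contra=True)
    add("L1-ROS1-LUNG", _fusion("ROS1"), "Lung", L1, ["crizotinib"])

    # ----- Level 2: professional practice guidelines -----
    add("L2-ALK-SARC", _fusion("ALK"), "Sarcoma", L2, ["ceritinib", "crizotinib"])
    add("L2-ALK-LUNG-R", _fusion("ALK"), "Lung", L2, EGFR_TKI, contra=True)
    add("L2-BRAF-THY", _gene_any("BRAF"), "Thyroid", L2, ["vemurafenib"])
    add("L2-BRAF-CRC", _named("BRAF", "V600E"), "Colorectal", L2,
        ["cetuximab + vemurafenib + chemo", "panitumumab + vemurafenib + chemo"])
    add("L2-BRAF-LUNG", _named("BRAF", "V600E"), "Lung", L2,
        ["dabrafenib", "vemurafenib"])
    add("L2-ERBB2-LUNG", _gene_any("ERBB2"), "Lung", L2, ["ado-trastuzumab emtansine"])
    add("L2-ERBB2-HN", _gene_any("ERBB2"), "Head and Neck", L2, ["trastuzumab"])
    add("L2-ERBB2-BREAST", _gene_any("ERBB2"), "Breast", L2, ["trastuzumab + chemo"])
    add("L2-KIT-EX9-SARC", _exons("KIT", (9,)), "Sarcoma", L2, ["imatinib"])
    add("L2-KIT-EX11-SARC", _exons("KIT", (11,)), "Sarcoma", L2, ["imatinib"])
    add("L2-KIT-EX11-13-MEL", _exons("KIT", (11, 13)), "Melanoma", L2, ["imatinib"])
    add("L2-KRAS-LUNG-R", _gene_any("KRAS"), "Lung", L2, EGFR_TKI, contra=True)
    add("L2-MET-LUNG", _amp("MET"), "Lung", L2, ["crizotinib"])
    add("L2-MET-LUNG", _skip("MET", 14), "Lung", L2, ["crizotinib"])
    add("L2-NF1-SARC-R", _gene_any("NF1"), "Sarcoma", L2, ["imatinib"], contra=True)
    add("L2-PDGFRA-D842V-R", _named("PDGFRA", "D842V"), "Sarcoma", L2,
        ["dasatinib", "imatinib"], contra=True)
    add("L2-RET-LUNG", _fusion("RET"), "Lung", L2, ["cabozantinib", "vandetanib"])
    add("L2-RET-THY", _gene_any("RET"), "Thyroid", L2, ["vandetanib"])
    add("L2-ROS1-LUNG", _fusion("ROS1"), "Lung", L2, ["alectinib", "ceritinib"])
    add("L2-ROS1-LUNG-R", _fusion("ROS1"), "Lung", L2, EGFR_TKI, contra=True)
    return r


def build_default_knowledgebase() -> Knowledgebase:
    return Knowledgebase(
        associations=tuple(_rows()),
        panel=PanelDefinition(
            hotspot_genes=frozenset(HOTSPOT_GENES),
            full_coding_genes=frozenset(FULL_CODING_GENES),
            cn_gain_genes=frozenset(CN_GAIN_GENES),
            cn_loss_genes=frozenset(CN_LOSS_GENES),
            fusion_genes=frozenset(FUSION_GENES),
        ),
        level3_gene_targets=frozenset(LEVEL3_GENE_TARGETS),
        acmg_genes=frozenset(ACMG_GENES),
        tumor_type_vocabulary=frozenset(TUMOR_TYPES),
    )
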