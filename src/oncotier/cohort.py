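"""Synthetic cohort generation.

Two generators back the test surface of the package:

* :func:`generate_fixture` — a deterministic, seed-free, fully enumerated
  657-test cohort whose classification through the bundled knowledgebase
  reproduces the published cohort's marginals: the per-level variant census,
  the per-test most-actionable buckets (89 / 100 / 419 / 49), the level-3
  per-gene census, the off-label structure (111 off-label variants in 90
  tests, 81% BRCA1/2), and the recommendation cross-tabulation. Wherever the
  published tables constrain only a variant *family* (e.g. "codon 12/13/61/146
  single nucleotide variants"), concrete exemplar alleles are chosen in a
  fixed lexical rotation; placements the tables leave unconstrained are
  arbitrary but deterministic.

* :func:`generate_random` — a seeded sampler over a :class:`CohortSpec`
  (tumor mix, per-bucket composition targets, recommendation rates) for
  property testing and convergence checks.

Neither generator models allele frequencies, mutational signatures, clonality
or tumor purity; variants are templates sufficient for knowledgebase matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, model_validator

from .variants import COHORT_COLUMNS, VARIANT_COLUMNS, TestRecord, records_from_frames


class FixtureConstraintError(RuntimeError):
    """A cohort constraint set could not be satisfied (names the violation)."""


# ---------------------------------------------------------------------------
# Published cohort marginals
# ---------------------------------------------------------------------------

#: Tests per tumor type (sums to 657).
TUMOR_COUNTS = (
    ("Bladder", 4), ("Brain", 15), ("Breast", 34), ("Cervical", 4),
    ("Colorectal", 68), ("Endocrine", 3), ("Endometrial", 25),
    ("Esophageal", 13), ("Eye", 1), ("Female Genital", 1), ("Gallbladder", 3),
    ("Head and Neck", 4), ("Kidney and Renal Pelvis", 10),
    ("Liver and Bile Duct", 1), ("Lung", 205), ("Melanoma", 51),
    ("Mesothelioma", 4), ("Neuroendocrine Tumors", 14),
    ("Non-Melanoma Skin", 2), ("Ovarian", 44), ("Pancreatic", 9),
    ("Prostate", 34), ("Sarcoma", 87), ("Small Intestine", 3),
    ("Stomach", 3), ("Testicular", 1), ("Thymic", 3), ("Thyroid", 4),
    ("Unknown Primary", 7),
)

#: Level-1-bucket tests per tumor type.
_L1_PLAN = {"Colorectal": 35, "Lung": 25, "Melanoma": 17, "Ovarian": 10, "Breast": 2}
#: Level-2-bucket tests per tumor type.
_L2_PLAN = {"Lung": 84, "Sarcoma": 9, "Melanoma": 4, "Colorectal": 2, "Thyroid": 1}
#: VUTS-bucket (no clinically significant variant) tests per tumor type.
_VUTS_PLAN = {
    "Lung": 12, "Sarcoma": 10, "Prostate": 8, "Brain": 3, "Endometrial": 3,
    "Colorectal": 3, "Kidney and Renal Pelvis": 2, "Neuroendocrine Tumors": 2,
    "Pancreatic": 2, "Bladder": 1, "Cervical": 1, "Esophageal": 1, "Stomach": 1,
}

#: Level-3 per-gene census (variants, tests) for genes allocated generically,
#: constrained genes first (tumor types where the gene would match a curated
#: same-tumor association are excluded from its placements).
_LEVEL3_GENERAL = (
    ("NF1", 50, 41, frozenset({"Sarcoma"})),
    ("MET", 37, 37, frozenset({"Lung"})),
    ("NRAS", 23, 23, frozenset({"Colorectal"})),
    ("KRAS", 19, 18, frozenset({"Colorectal", "Lung"})),
    ("KIT", 7, 6, frozenset({"Sarcoma", "Melanoma"})),
    ("RET", 6, 6, frozenset({"Thyroid"})),
    ("TP53", 310, 280, None), ("ATM", 158, 139, None), ("CDKN2A", 96, 91, None),
    ("PTEN", 85, 74, None), ("PIK3CA", 63, 56, None), ("TSC2", 45, 44, None),
    ("KDR", 43, 41, None), ("RB1", 37, 37, None), ("PTCH1", 37, 34, None),
    ("STK11", 30, 28, None), ("FBXW7", 25, 25, None), ("NF2", 24, 24, None),
    ("APC", 23, 22, None), ("TSC1", 23, 21, None), ("IDH1", 18, 17, None),
    ("CDK4", 18, 17, None), ("CSF1R", 15, 14, None), ("FGFR3", 12, 10, None),
    ("FGFR1", 10, 9, None), ("AKT1", 8, 8, None), ("SMO", 9, 8, None),
    ("MSH2", 9, 6, None), ("CCND1", 6, 6, None), ("PIK3R1", 6, 6, None),
    ("SMARCB1", 5, 4, None), ("CHEK2", 4, 4, None), ("CCNE1", 4, 4, None),
    ("MYC", 4, 4, None), ("BAP1", 4, 4, None), ("ERBB4", 3, 3, None),
    ("DDR2", 3, 3, None), ("FLT3", 3, 3, None), ("MAP2K1", 3, 3, None),
    ("ALK", 3, 3, None), ("ESR1", 2, 2, None), ("GNA11", 2, 2, None),
    ("ERBB3", 2, 2, None), ("HRAS", 2, 2, None), ("ABL1", 2, 2, None),
    ("JAK2", 2, 2, None), ("MTOR", 2, 2, None), ("MYCL", 2, 2, None),
    ("NFE2L2", 2, 2, None), ("NTRK1", 2, 2, None), ("MAPK1", 2, 2, None),
    ("AR", 1, 1, None), ("CDK6", 1, 1, None), ("FGFR2", 1, 1, None),
    ("JAK1", 1, 1, None), ("WT1", 1, 1, None), ("MDM2", 1, 1, None),
    ("NTRK3", 1, 1, None), ("RAF1", 1, 1, None), ("SRC", 1, 1, None),
    ("IDH2", 1, 1, None),
)

#: Genes allocated bespoke (off-label structure): BRCA1 69/61, BRCA2 101/90,
#: ERBB2 15/11, BRAF 13/11, EGFR 14/12.

_TSG_GENES = frozenset({
    "APC", "ATM", "BAP1", "BRCA1", "BRCA2", "CDH1", "CDKN2A", "FBXW7",
    "GATA3", "MSH2", "NF1", "NF2", "NOTCH1", "PIK3R1", "PTCH1", "PTEN",
    "RB1", "SMAD4", "SMARCB1", "STK11", "TET2", "TP53", "TSC1", "TSC2",
    "VHL", "WT1",
})
_CNV_GAIN_ONLY = frozenset({"CCND1", "CCNE1", "MYC", "MYCL", "MDM2", "CDK6"})
_FUSION_ONLY = {"NTRK1": "TPM3", "NTRK3": "ETV6"}
_NAMED_SMALL = {
    "KRAS": (("G12D", 2), ("G12V", 2), ("G13D", 2)),
    "NRAS": (("G12D", 2), ("Q61K", 3), ("G13D", 2)),
    "KIT": (("D816V", 17), ("D820G", 17)),
    "RET": (("M918T", None), ("C634R", None)),
    "ALK": (("F1174L", None), ("R1275Q", None)),
    "IDH1": (("R132H", None), ("R132C", None)),
    "PIK3CA": (("E545K", None), ("H1047R", None), ("E542K", None)),
}

#: Reportable genes with no therapeutic association at any level (VUTS pool).
_VUTS_HOTSPOT = (
    "CTNNB1", "GNAS", "GNAQ", "DNMT3A", "SF3B1", "U2AF1", "SPOP", "STAT3",
    "MYD88", "PTPN11", "MED12", "FOXL2", "MPL", "NPM1", "RHOA", "XPO1",
    "MAP2K2", "MLH1", "HNF1A", "JAK3", "CBL", "ARAF", "BTK", "RAC1", "PAX5",
    "EZH2", "GATA2", "MAX", "PPP2R1A", "RHEB",
)
_VUTS_TSG = ("CDH1", "GATA3", "NOTCH1", "SMAD4", "TET2", "VHL")

_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Recommendation plans per bucket: (category-or-None, count), assigned in a
#: deterministic test order described in :func:`_assign_recommendations`.
_REC_L1 = (("TARGETED_THERAPY", 26), ("CHEMO_RADIATION", 23),
           ("IMMUNOTHERAPY", 14), ("CLINICAL_TRIAL", 5),
           ("NON_THERAPEUTIC", 2), ("HORMONAL", 5), ("SURGERY", 3), (None, 11))
_REC_L2 = (("TARGETED_THERAPY", 11), ("CHEMO_RADIATION", 32),
           ("IMMUNOTHERAPY", 25), ("NON_THERAPEUTIC", 14),
           ("CLINICAL_TRIAL", 2), ("HORMONAL", 6), ("SURGERY", 4), (None, 6))
_REC_L3 = (("TARGETED_THERAPY", 15), ("CHEMO_RADIATION", 193),
           ("IMMUNOTHERAPY", 49), ("CLINICAL_TRIAL", 28),
           ("NON_THERAPEUTIC", 41), ("HORMONAL", 40), ("SURGERY", 25),
           ("TRANSPLANT", 2), (None, 26))
_REC_VUTS = (("CHEMO_RADIATION", 26), ("NON_THERAPEUTIC", 8),
             ("IMMUNOTHERAPY", 3), ("SURGERY", 2), ("HORMONAL", 2), (None, 8))


@dataclass
class _Test:
    idx: int
    test_id: str
    tumor: str
    bucket: str                       # "L1" | "L2" | "L3" | "VUTS"
    variants: list = field(default_factory=list)
    l3_genes: set = field(default_factory=set)
    recommendation: Optional[str] = None


def _row(test, gene, vclass, pc=None, exon=None, partner=None, cn=None,
         depth=None, sift="UNKNOWN", polyphen="UNKNOWN"):
    test.variants.append({
        "test_id": test.test_id, "gene": gene, "variant_class": vclass,
        "protein_change": pc or "", "exon": "" if exon is None else exon,
        "fusion_partner": partner or "",
        "copy_number": "" if cn is None else cn,
        "read_depth": "" if depth is None else depth,
        "sift": sift, "polyphen": polyphen,
    })


_depth_counter = [0]


def _small(test, gene, pc, exon=None, deleterious=False):
    _depth_counter[0] += 1
    depth = 500 + (_depth_counter[0] % 40) * 10
    sift = "DELETERIOUS" if deleterious else "UNKNOWN"
    poly = "DAMAGING" if deleterious else "UNKNOWN"
    vclass = "SNV"
    low = pc.lower()
    if low.endswith("del"):
        vclass = "DELETION"
    elif low.endswith(("ins", "dup")):
        vclass = "INSERTION"
    elif "delins" in low:
        vclass = "INDEL"
    _row(test, gene, vclass, pc=pc, exon=exon, depth=depth,
         sift=sift, polyphen=poly)


def _synth_pc(i: int) -> str:
    a = _AA[(i * 3) % 20]
    b = _AA[(i * 5 + 7) % 20]
    if a == b:
        b = _AA[(i * 5 + 8) % 20]
    return f"{a}{40 + 7 * i}{b}"


def _l3_template(test, gene, j):
    """Append the j-th level-3 variant of a generically allocated gene."""
    if gene == "MET":
        if j % 2 == 0:
            _row(test, gene, "CNV_GAIN", cn=8 + j % 3)
        else:
            _row(test, gene, "EXON_SKIP", exon=14)
    elif gene in _CNV_GAIN_ONLY:
        _row(test, gene, "CNV_GAIN", cn=8 + j % 4)
    elif gene in _FUSION_ONLY:
        _row(test, gene, "FUSION", partner=_FUSION_ONLY[gene])
    elif gene in _NAMED_SMALL:
        pc, exon = _NAMED_SMALL[gene][j % len(_NAMED_SMALL[gene])]
        _small(test, gene, pc, exon=exon, deleterious=gene in _TSG_GENES)
    else:
        _small(test, gene, _synth_pc(j), deleterious=gene in _TSG_GENES)
    test.l3_genes.add(gene)


# ---------------------------------------------------------------------------
# Fixture construction
# ---------------------------------------------------------------------------

def _build_tests() -> list[_Test]:
    tests = []
    idx = 0
    for tumor, n in TUMOR_COUNTS:
        n1 = _L1_PLAN.get(tumor, 0)
        n2 = _L2_PLAN.get(tumor, 0)
        nv = _VUTS_PLAN.get(tumor, 0)
        if n1 + n2 + nv > n:
            raise FixtureConstraintError(f"{tumor}: bucket plan exceeds {n} tests")
        for k in range(n):
            bucket = ("L1" if k < n1 else
                      "L2" if k < n1 + n2 else
                      "VUTS" if k < n1 + n2 + nv else "L3")
            idx += 1
            tests.append(_Test(idx=idx, test_id=f"T{idx:04d}", tumor=tumor,
                               bucket=bucket))
    if len(tests) != 657:
        raise FixtureConstraintError(f"expected 657 tests, built {len(tests)}")
    return tests


_RAS_EXON = {12: 2, 13: 2, 14: 2, 59: 3, 61: 3, 117: 4, 146: 4}


def _assign_l1(tests):
    """92 companion-diagnostic variants in 89 tests (3 EGFR double tests)."""
    by = {}
    for t in tests:
        if t.bucket == "L1":
            by.setdefault(t.tumor, []).append(t)

    kras = ["G12D", "G13D", "Q61H", "A146T", "G12V", "G12C"]
    for i, t in enumerate(by["Colorectal"][:32]):
        pc = kras[i % 6]
        _small(t, "KRAS", pc, exon=_RAS_EXON[int(pc[1:-1])])
    for i, t in enumerate(by["Colorectal"][32:35]):
        pc = ["G12D", "Q61K", "G12V"][i]
        _small(t, "NRAS", pc, exon=_RAS_EXON[int(pc[1:-1])])

    lung = by["Lung"]
    for t in lung[0:3]:                      # compound sensitizing + resistance
        _small(t, "EGFR", "L858R", exon=21)
        _small(t, "EGFR", "T790M", exon=20)
    for t in lung[3:7]:
        _small(t, "EGFR", "L858R", exon=21)
    for t in lung[7:14]:
        _small(t, "EGFR", "E746_A750del", exon=19)
    for t in lung[14:19]:
        _small(t, "BRAF", "V600E", exon=15)
    for t in lung[19:24]:
        _row(t, "ALK", "FUSION", partner="EML4")
    _row(lung[24], "ROS1", "FUSION", partner="EZR")

    for i, t in enumerate(by["Melanoma"]):
        _small(t, "BRAF", "V600E" if i < 13 else "V600K", exon=15)
    for i, t in enumerate(by["Ovarian"][:7]):
        _small(t, "BRCA1", f"E{120 + 31 * i}*", deleterious=True)
    for i, t in enumerate(by["Ovarian"][7:10]):
        _small(t, "BRCA2", f"K{210 + 47 * i}*", deleterious=True)
    for t in by["Breast"]:
        _row(t, "ERBB2", "CNV_GAIN", cn=9)


def _assign_l2(tests):
    """109 guideline-level variants in 100 tests (9 KRAS-lung double tests)."""
    by = {}
    for t in tests:
        if t.bucket == "L2":
            by.setdefault(t.tumor, []).append(t)

    kras = ["G12C", "G12V", "G12D", "G13D", "Q61H", "A146T"]
    lung = by["Lung"]
    for i, t in enumerate(lung[:73]):
        pc = kras[i % 6]
        _small(t, "KRAS", pc, exon=_RAS_EXON[int(pc[1:-1])])
        if i < 9:                             # double-KRAS tests
            pc2 = kras[(i + 1) % 6]
            _small(t, "KRAS", pc2, exon=_RAS_EXON[int(pc2[1:-1])])
    for j, t in enumerate(lung[73:80]):
        if j < 4:
            _row(t, "MET", "CNV_GAIN", cn=9)
        else:
            _row(t, "MET", "EXON_SKIP", exon=14)
    erbb2 = ["E365K", "Y742_A745dup", "D769H"]
    for j, t in enumerate(lung[80:83]):
        _small(t, "ERBB2", erbb2[j], exon=None)
    _row(lung[83], "RET", "FUSION", partner="KIF5B")

    sarc = by["Sarcoma"]
    for i, t in enumerate(sarc[:5]):
        _small(t, "NF1", _synth_pc(i + 3), deleterious=True)
    _small(sarc[5], "KIT", "A502_Y503dup", exon=9)
    _small(sarc[6], "KIT", "V559D", exon=11)
    _small(sarc[7], "KIT", "V560D", exon=11)
    _row(sarc[8], "ALK", "FUSION", partner="TPM3")

    mel = ["L576P", "K642E", "V559A", "W557R"]
    for i, t in enumerate(by["Melanoma"]):
        _small(t, "KIT", mel[i], exon=11)
    for t in by["Colorectal"]:
        _small(t, "BRAF", "V600E", exon=15)
    _small(by["Thyroid"][0], "RET", "M918T")


def _assign_level3(tests):
    """1532 level-3 variants: bespoke off-label structure + generic census."""
    tumor_order = [name for name, _ in TUMOR_COUNTS]
    free = {name: [t for t in tests if t.bucket == "L3" and t.tumor == name]
            for name in tumor_order}
    ptr = [0]

    def take_l3(forbidden):
        for k in range(len(tumor_order)):
            tumor = tumor_order[(ptr[0] + k) % len(tumor_order)]
            if forbidden and tumor in forbidden:
                continue
            if free[tumor]:
                ptr[0] = (ptr[0] + k + 1) % len(tumor_order)
                return free[tumor].pop(0)
        raise FixtureConstraintError("no eligible level-3 test available")

    ov = {"Ovarian"}
    brca_pairs = [take_l3(ov) for _ in range(21)]
    brca1_single = [take_l3(ov) for _ in range(21)]
    brca2_single = [take_l3(ov) for _ in range(27)]
    erbb2_amp_sm = [take_l3({"Breast", "Esophageal", "Stomach", "Lung",
                             "Head and Neck"}) for _ in range(4)]
    erbb2_amp = [take_l3({"Breast", "Esophageal", "Stomach"}) for _ in range(4)]
    erbb2_small = [take_l3({"Lung", "Head and Neck", "Breast"}) for _ in range(3)]
    braf_ol = [take_l3({"Melanoma", "Lung", "Colorectal", "Thyroid"})
               for _ in range(7)]
    braf_only = [take_l3({"Thyroid"}) for _ in range(4)]
    egfr_ol = [take_l3({"Lung"}) for _ in range(6)]
    egfr_amp = [take_l3(None) for _ in range(6)]

    # BRCA1/2 small variants outside ovarian cancer carry the label off-label.
    n = [0]

    def brca_small(t, gene):
        n[0] += 1
        _small(t, gene, f"Q{300 + 17 * n[0]}*", deleterious=True)
        t.l3_genes.add(gene)

    for t in brca_pairs:
        brca_small(t, "BRCA1")
        brca_small(t, "BRCA2")
    for t in brca1_single:
        brca_small(t, "BRCA1")
    for t in brca2_single:
        brca_small(t, "BRCA2")

    for j, t in enumerate(erbb2_amp_sm + erbb2_amp):
        _row(t, "ERBB2", "CNV_GAIN", cn=8 + j % 3)
        t.l3_genes.add("ERBB2")
    erbb2_pcs = ["V842I", "L755S", "S310F", "R678Q", "T862A", "V777L", "D769Y"]
    for j, t in enumerate(erbb2_amp_sm + erbb2_small):
        _small(t, "ERBB2", erbb2_pcs[j])
        t.l3_genes.add("ERBB2")
    for j, t in enumerate(braf_ol):
        _small(t, "BRAF", "V600E", exon=15)
        t.l3_genes.add("BRAF")
        if j < 2:
            _small(t, "BRAF", "G469A", exon=11)
    for t in braf_only:
        _small(t, "BRAF", "G469A", exon=11)
        t.l3_genes.add("BRAF")
    for j, t in enumerate(egfr_ol):
        _small(t, "EGFR", "L858R", exon=21)
        t.l3_genes.add("EGFR")
        if j < 2:
            _row(t, "EGFR", "CNV_GAIN", cn=12)
    for t in egfr_amp:
        _row(t, "EGFR", "CNV_GAIN", cn=12)
        t.l3_genes.add("EGFR")

    # BRCA level-3 variants in tests that do hold level-1/2 evidence (these
    # sit outside the "no level 1 or 2 evidence" off-label count).
    l1l2 = [t for t in tests if t.bucket in ("L1", "L2") and t.tumor != "Ovarian"]
    brca2_extra, brca1_extra = l1l2[:42], l1l2[42:61]
    for j, t in enumerate(brca2_extra):
        brca_small(t, "BRCA2")
        if j < 11:
            _row(t, "BRCA2", "CNV_LOSS", cn=0)
    for j, t in enumerate(brca1_extra):
        brca_small(t, "BRCA1")
        if j < 8:
            _row(t, "BRCA1", "CNV_LOSS", cn=0)

    # Generic allocation for the remaining census, covering every test that
    # still lacks a level-3 alteration (uncovered level-3-bucket tests first).
    eligible = [t for t in tests if t.bucket in ("L1", "L2", "L3")]
    uncovered = sorted((t for t in eligible if not t.l3_genes),
                       key=lambda t: (t.bucket != "L3", t.idx))
    rr = [0]
    for gene, nv, nt, forbidden in _LEVEL3_GENERAL:
        assigned = []
        rest = []
        for t in uncovered:
            if len(assigned) < nt and gene not in t.l3_genes and not (
                    forbidden and t.tumor in forbidden):
                assigned.append(t)
            else:
                rest.append(t)
        uncovered = rest
        assigned_ids = {t.idx for t in assigned}
        guard = 0
        while len(assigned) < nt:
            t = eligible[rr[0] % len(eligible)]
            rr[0] += 1
            guard += 1
            if guard > 20 * len(eligible):
                raise FixtureConstraintError(
                    f"{gene}: cannot place {nt} level-3 tests")
            if (forbidden and t.tumor in forbidden) or gene in t.l3_genes \
                    or t.idx in assigned_ids:
                continue
            assigned.append(t)
            assigned_ids.add(t.idx)
        for j, t in enumerate(assigned):
            _l3_template(t, gene, j)
        for j in range(nv - nt):
            _l3_template(assigned[j], gene, nt + j)
    if uncovered:
        raise FixtureConstraintError(
            f"{len(uncovered)} tests left without level-3 coverage")

    return {
        "l3_targeted_order": brca2_single[:11] + braf_only[:4],
        "off_label_tests": (brca_pairs + brca1_single + brca2_single
                            + erbb2_amp_sm + erbb2_amp + braf_ol + egfr_ol),
    }


def _assign_vuts(tests):
    """1045 reportable variants with no therapy association at any level."""
    pool = _VUTS_HOTSPOT + _VUTS_TSG
    k = [0]

    def vuts(t):
        gene = pool[k[0] % len(pool)]
        tsg = gene in _VUTS_TSG
        _depth_counter[0] += 1
        depth = 500 + (_depth_counter[0] % 40) * 10
        _row(t, gene, "SNV", pc=_synth_pc(k[0] % 90), depth=depth,
             sift="DELETERIOUS" if tsg else ("TOLERATED" if k[0] % 2 else "UNKNOWN"),
             polyphen="DAMAGING" if tsg else ("BENIGN" if k[0] % 2 else "UNKNOWN"))
        k[0] += 1

    for t in tests:
        if t.bucket == "VUTS":
            vuts(t)
            vuts(t)
    for t in tests:
        vuts(t)
    for t in tests[:290]:
        vuts(t)


def _assign_recommendations(tests, info):
    def fill(order, plan):
        total = sum(nn for _, nn in plan)
        if total != len(order):
            raise FixtureConstraintError(
                f"recommendation plan covers {total} of {len(order)} tests")
        i = 0
        for cat, nn in plan:
            for _ in range(nn):
                order[i].recommendation = cat
                i += 1

    l1 = [t for t in tests if t.bucket == "L1"]
    # Targeted-therapy recommendations go to tests with sensitizing level-1
    # evidence; RAS-contraindicated colorectal tests come last.
    order_l1 = ([t for t in l1 if t.tumor != "Colorectal"]
                + [t for t in l1 if t.tumor == "Colorectal"])
    fill(order_l1, _REC_L1)
    fill([t for t in tests if t.bucket == "L2"], _REC_L2)
    head = info["l3_targeted_order"]
    head_ids = {t.idx for t in head}
    l3_rest = [t for t in tests if t.bucket == "L3" and t.idx not in head_ids]
    fill(head + l3_rest, _REC_L3)
    fill([t for t in tests if t.bucket == "VUTS"], _REC_VUTS)


def _ages() -> list[int]:
    lo = [30 + round(j * 33 / 247) for j in range(248)]
    hi = [65 + round(j * 28 / 327) for j in range(328)]
    return [6] + lo + [64] * 80 + hi      # 657 values, median 64, range 6-93


def _demographics(tests) -> list[dict]:
    ages = _ages()
    rows = []
    lung_idx = [t.idx for t in tests if t.tumor == "Lung"]
    repeat_map = {lung_idx[11 + k]: lung_idx[k] for k in range(11)}
    for t in tests:
        i = t.idx - 1
        src = repeat_map.get(t.idx, t.idx)
        stage_key = (i * 13) % 657
        stage = ("I" if stage_key < 9 else "II" if stage_key < 20 else
                 "III" if stage_key < 74 else "IV" if stage_key < 580
                 else "UNKNOWN")
        prior_key = (i * 19) % 657
        prior = ("NONE" if prior_key < 156 else
                 "UNKNOWN" if prior_key < 160 else "ONE_PLUS")
        rows.append({
            "test_id": t.test_id,
            "patient_id": f"P{src:04d}",
            "tumor_type": t.tumor,
            "stage": stage,
            "age": ages[(i * 23) % 657],
            "sex": "FEMALE" if (i * 7) % 657 < 359 else "MALE",
            "prior_treatment": prior,
            "recommendation": t.recommendation or "",
            "recommendation_day": 30 if t.recommendation else "",
            "followup_days": 120,
        })
    return rows


def _self_check(tests):
    n_var = sum(len(t.variants) for t in tests)
    if n_var != 2778:
        raise FixtureConstraintError(f"expected 2778 variants, built {n_var}")
    buckets = {"L1": 0, "L2": 0, "L3": 0, "VUTS": 0}
    for t in tests:
        buckets[t.bucket] += 1
    if buckets != {"L1": 89, "L2": 100, "L3": 419, "VUTS": 49}:
        raise FixtureConstraintError(f"bucket counts off: {buckets}")
    gene_tests = {}
    for t in tests:
        for g in t.l3_genes:
            gene_tests[g] = gene_tests.get(g, 0) + 1
    expected = {g: nt for g, _, nt, _ in _LEVEL3_GENERAL}
    expected.update({"BRCA1": 61, "BRCA2": 90, "ERBB2": 11, "BRAF": 11,
                     "EGFR": 12})
    if gene_tests != expected:
        bad = {g: (gene_tests.get(g), expected.get(g))
               for g in set(gene_tests) | set(expected)
               if gene_tests.get(g) != expected.get(g)}
        raise FixtureConstraintError(f"level-3 per-gene test census off: {bad}")


def generate_fixture() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the deterministic 657-test fixture cohort.

    Returns ``(variants, cohort)`` DataFrames in the package's TSV dialects.
    Running the build twice yields identical frames (no randomness anywhere).
    """
    _depth_counter[0] = 0
    tests = _build_tests()
    _assign_l1(tests)
    _assign_l2(tests)
    info = _assign_level3(tests)
    _assign_vuts(tests)
    _assign_recommendations(tests, info)
    _self_check(tests)
    vrows = [row for t in tests for row in t.variants]
    vdf = pd.DataFrame(vrows, columns=VARIANT_COLUMNS)
    cdf = pd.DataFrame(_demographics(tests), columns=COHORT_COLUMNS)
    return vdf, cdf


def fixture_records() -> list[TestRecord]:
    """The fixture cohort as validated TestRecords."""
    vdf, cdf = generate_fixture()
    return records_from_frames(vdf.astype(str), cdf.astype(str))


def write_fixture(out_dir: str | Path) -> tuple[Path, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vdf, cdf = generate_fixture()
    vpath, cpath = out / "fixture_variants.tsv", out / "fixture_cohort.tsv"
    vdf.to_csv(vpath, sep="\t", index=False)
    cdf.to_csv(cpath, sep="\t", index=False)
    return vpath, cpath


# ---------------------------------------------------------------------------
# Seeded random cohorts
# ---------------------------------------------------------------------------

class CohortSpec(BaseModel):
    """Structure of a random synthetic cohort.

    ``per_level_test_targets`` gives the expected per-test most-actionable
    composition (level 1, level 2, level 3, VUTS) as weights; tests are
    assigned buckets by multinomial sampling of the normalized weights.
    """

    n_tests: int
    tumor_type_mix: dict[str, float]
    per_level_test_targets: tuple[float, float, float, float]
    mean_variants_per_test: float = 4.2
    recommendation_rates: Optional[dict[str, dict[str, float]]] = None
    seed: Optional[int] = None

    @model_validator(mode="after")
    def _check(self) -> "CohortSpec":
        if self.n_tests <= 0:
            raise ValueError("n_tests must be positive")
        total = sum(self.tumor_type_mix.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"tumor mix probabilities sum to {total}, not 1")
        if any(w < 0 for w in self.per_level_test_targets):
            raise ValueError("per-level targets must be non-negative")
        if sum(self.per_level_test_targets) <= 0:
            raise ValueError("per-level targets must not all be zero")
        return self


def published_marginals_spec(seed: int) -> CohortSpec:
    """A CohortSpec mirroring the fixture cohort's marginal structure."""
    mix = {name: n / 657 for name, n in TUMOR_COUNTS}
    return CohortSpec(
        n_tests=657,
        tumor_type_mix=mix,
        per_level_test_targets=(89, 100, 419, 49),
        recommendation_rates={
            "L1": {"TARGETED_THERAPY": 26 / 89, "CHEMO_RADIATION": 23 / 89,
                   "IMMUNOTHERAPY": 14 / 89},
            "L2": {"TARGETED_THERAPY": 11 / 100, "CHEMO_RADIATION": 32 / 100,
                   "IMMUNOTHERAPY": 25 / 100},
            "L3": {"TARGETED_THERAPY": 15 / 419, "CHEMO_RADIATION": 193 / 419,
                   "IMMUNOTHERAPY": 49 / 419},
            "VUTS": {"CHEMO_RADIATION": 26 / 49, "NON_THERAPEUTIC": 8 / 49},
        },
        seed=seed,
    )


_L1_ANCHORS = {
    "Colorectal": ("KRAS", "G12D", 2),
    "Lung": ("EGFR", "L858R", 21),
    "Melanoma": ("BRAF", "V600E", 15),
    "Ovarian": ("BRCA1", "E123*", None),
    "Breast": ("ERBB2", None, None),          # amplification
}
_L2_ANCHORS = {
    "Lung": ("KRAS", "G12C", 2),
    "Sarcoma": ("KIT", "V559D", 11),
    "Melanoma": ("KIT", "L576P", 11),
    "Colorectal": ("BRAF", "V600E", 15),
    "Thyroid": ("RET", "M918T", None),
}
_L3_FILLERS = ("TP53", "ATM", "KDR", "PTEN", "CDKN2A", "PIK3CA")
_VUTS_FILLERS = ("CTNNB1", "GNAS", "DNMT3A", "SF3B1", "SPOP", "STAT3")
_BUCKETS = ("L1", "L2", "L3", "VUTS")


def generate_random(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample a seeded random cohort from a CohortSpec.

    The same seed always yields identical tables. Each test draws a bucket
    from the per-level weights; its tumor type comes from the tumor mix,
    redrawn from the bucket-compatible subset when the bucket requires a
    tumor with curated (level-1/2) associations. One anchor variant realizes
    the bucket; Poisson-distributed filler variants at weaker levels bring
    the per-test count toward the configured mean.
    """
    if spec.seed is None:
        raise ValueError("CohortSpec.seed is required for reproducible cohorts")
    _depth_counter[0] = 0
    rng = np.random.default_rng(spec.seed)
    weights = np.asarray(spec.per_level_test_targets, dtype=float)
    probs = weights / weights.sum()
    tumors = sorted(spec.tumor_type_mix)
    tumor_p = np.asarray([spec.tumor_type_mix[t] for t in tumors])
    tumor_p = tumor_p / tumor_p.sum()

    vrows, crows = [], []
    for i in range(spec.n_tests):
        tid = f"R{i + 1:05d}"
        bucket = _BUCKETS[rng.choice(4, p=probs)]
        tumor = tumors[rng.choice(len(tumors), p=tumor_p)]
        if bucket == "L1":
            anchors = sorted(_L1_ANCHORS)
            tumor = anchors[rng.choice(len(anchors))]
        elif bucket == "L2":
            anchors = sorted(_L2_ANCHORS)
            tumor = anchors[rng.choice(len(anchors))]

        test = _Test(idx=i, test_id=tid, tumor=tumor, bucket=bucket)
        if bucket == "L1":
            gene, pc, exon = _L1_ANCHORS[tumor]
            if pc is None:
                _row(test, gene, "CNV_GAIN", cn=9)
            else:
                _small(test, gene, pc, exon=exon, deleterious=gene in _TSG_GENES)
        elif bucket == "L2":
            gene, pc, exon = _L2_ANCHORS[tumor]
            _small(test, gene, pc, exon=exon)
        elif bucket == "L3":
            gene = _L3_FILLERS[rng.choice(len(_L3_FILLERS))]
            _small(test, gene, _synth_pc(int(rng.integers(0, 90))),
                   deleterious=gene in _TSG_GENES)
        else:
            _small(test, _VUTS_FILLERS[rng.choice(len(_VUTS_FILLERS))],
                   _synth_pc(int(rng.integers(0, 90))))

        n_fill = int(rng.poisson(max(spec.mean_variants_per_test - 1.0, 0.0)))
        for _ in range(n_fill):
            if bucket == "VUTS" or rng.random() < 0.4:
                _small(test, _VUTS_FILLERS[int(rng.integers(0, len(_VUTS_FILLERS)))],
                       _synth_pc(int(rng.integers(0, 90))))
            else:
                gene = _L3_FILLERS[int(rng.integers(0, len(_L3_FILLERS)))]
                _small(test, gene, _synth_pc(int(rng.integers(0, 90))),
                       deleterious=gene in _TSG_GENES)

        rec = ""
        if spec.recommendation_rates:
            rates = spec.recommendation_rates.get(bucket, {})
            cats = sorted(rates)
            p = [rates[c] for c in cats]
            rest = 1.0 - sum(p)
            choice = rng.choice(len(cats) + 1, p=p + [max(rest, 0.0)])
            if choice < len(cats):
                rec = cats[choice]

        vrows.extend(test.variants)
        crows.append({
            "test_id": tid, "patient_id": f"RP{i + 1:05d}", "tumor_type": tumor,
            "stage": "IV", "age": 64, "sex": "FEMALE" if i % 2 else "MALE",
            "prior_treatment": "ONE_PLUS", "recommendation": rec,
            "recommendation_day": 30 if rec else "", "followup_days": 120,
        })
    vdf = pd.DataFrame(vrows, columns=VARIANT_COLUMNS)
    cdf = pd.DataFrame(crows, columns=COHORT_COLUMNS)
    return vdf, cdf
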