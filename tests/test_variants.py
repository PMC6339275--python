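"""Variant data model, HGVS-p parsing, QC/reportability gates, and IO."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oncotier import (
    ObservedVariant,
    PolyphenCall,
    SiftCall,
    VariantClass,
    load_knowledgebase,
    parse_protein_change,
    qc_filter,
    read_cohort,
    reportability_gate,
    write_cohort,
)
from oncotier.variants import ProteinChangeError, TestRecord, cohort_to_frames


def _oracle_first_codon(pchange: str):
    """Independent character-walk parser: first digit run after a letter."""
    s = pchange.replace(" ", "")
    if not s or not s[0].isalpha() or not s[0].isupper():
        return None
    digits = ""
    for ch in s[1:]:
        if ch.isdigit():
            digits += ch
        elif digits:
            break
        elif not digits and ch.isalpha():
            return None
    return int(digits) if digits else None


PCHANGE_FIXTURES = [
    "V600E", "V600K", "L858R", "T790M", "T790 M", "G12D", "G13D", "Q61H",
    "A146T", "G719C", "S768I", "L861Q", "E746_A750del", "L747_P753delinsS",
    "Y742_A745dup", "A502_Y503dup", "D842V", "M918T", "E545K", "Q192*",
]


@pytest.mark.parametrize("pchange", PCHANGE_FIXTURES)
def test_protein_change_codon_matches_independent_parser(pchange):
    first, _ = parse_protein_change(pchange)
    assert first == _oracle_first_codon(pchange)


def test_protein_change_rejects_garbage():
    for bad in ("", "600E", "???", "del19"):
        with pytest.raises(ProteinChangeError):
            parse_protein_change(bad)


def test_codon_derived_from_protein_change():
    v = ObservedVariant(gene="braf", variant_class=VariantClass.SNV,
                        protein_change="V600E")
    assert v.gene == "BRAF"          # symbol normalized
    assert v.codon == 600


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(gene="KRAS", variant_class=VariantClass.SNV),          # no pchange
        dict(gene="ERBB2", variant_class=VariantClass.CNV_GAIN,
             protein_change="V600E"),                               # pchange on CNV
        dict(gene="KRAS", variant_class=VariantClass.SNV,
             protein_change="G12D", fusion_partner="EML4"),         # partner on SNV
        dict(gene="KRAS", variant_class=VariantClass.SNV,
             protein_change="G12D", copy_number=4.0),               # CN on SNV
        dict(gene="ERBB2", variant_class=VariantClass.CNV_GAIN,
             copy_number=-1.0),                                     # negative CN
    ],
)
def test_observed_variant_invariants(kwargs):
    with pytest.raises(ValueError):
        ObservedVariant(**kwargs)


@pytest.mark.parametrize("depth,expected", [(457, True), (456, False), (5000, True)])
def test_qc_depth_boundary(depth, expected):
    v = ObservedVariant(gene="EGFR", variant_class=VariantClass.SNV,
                        protein_change="L858R", read_depth=depth)
    assert qc_filter(v) is expected


def test_qc_exempts_structural_classes_and_missing_depth():
    fusion = ObservedVariant(gene="ALK", variant_class=VariantClass.FUSION,
                             fusion_partner="EML4")
    assert qc_filter(fusion) is True
    nodepth = ObservedVariant(gene="EGFR", variant_class=VariantClass.SNV,
                              protein_change="L858R")
    assert qc_filter(nodepth) is True    # pass with a warning


class TestReportabilityGate:
    @pytest.fixture(autouse=True)
    def _panel(self, kb):
        self.panel = kb.panel

    def _tsg(self, sift, poly):
        return ObservedVariant(gene="TP53", variant_class=VariantClass.SNV,
                               protein_change="R175H", read_depth=900,
                               sift_call=sift, polyphen_call=poly)

    def test_tsg_requires_both_calls(self):
        assert reportability_gate(
            self._tsg(SiftCall.DELETERIOUS, PolyphenCall.DAMAGING), self.panel)
        assert not reportability_gate(
            self._tsg(SiftCall.DELETERIOUS, PolyphenCall.BENIGN), self.panel)
        assert not reportability_gate(
            self._tsg(SiftCall.TOLERATED, PolyphenCall.DAMAGING), self.panel)

    def test_hotspot_gene_exempt_from_insilico_calls(self):
        v = ObservedVariant(gene="KRAS", variant_class=VariantClass.SNV,
                            protein_change="G12D", read_depth=900,
                            sift_call=SiftCall.UNKNOWN)
        assert "KRAS" in self.panel.hotspot_genes
        assert reportability_gate(v, self.panel)

    @pytest.mark.parametrize("cn,expected", [(8.0, True), (3.0, False)])
    def test_amplification_threshold(self, cn, expected):
        v = ObservedVariant(gene="ERBB2", variant_class=VariantClass.CNV_GAIN,
                            copy_number=cn)
        assert reportability_gate(v, self.panel) is expected

    @pytest.mark.parametrize("cn,expected", [(0.0, True), (1.2, False)])
    def test_deletion_threshold(self, cn, expected):
        v = ObservedVariant(gene="PTEN", variant_class=VariantClass.CNV_LOSS,
                            copy_number=cn)
        assert reportability_gate(v, self.panel) is expected

    def test_off_panel_gene_not_reportable(self):
        v = ObservedVariant(gene="TTN", variant_class=VariantClass.SNV,
                            protein_change="A100V", read_depth=900)
        assert reportability_gate(v, self.panel) is False

    def test_fusion_requires_rna_panel_gene(self):
        ok = ObservedVariant(gene="ROS1", variant_class=VariantClass.FUSION)
        bad = ObservedVariant(gene="KRAS", variant_class=VariantClass.FUSION)
        assert reportability_gate(ok, self.panel)
        assert not reportability_gate(bad, self.panel)

def _tsg_variant(sift, poly):
    return ObservedVariant(gene="TP53", variant_class=VariantClass.SNV,
                           protein_change="R175H", read_depth=900,
                           sift_call=sift, polyphen_call=poly)


@given(sift=st.sampled_from(list(SiftCall)),
       poly=st.sampled_from(list(PolyphenCall)))
@settings(max_examples=20, deadline=None)
def test_gate_monotone_in_annotations(kb, sift, poly):
    """Upgrading a call toward deleterious never hides a reportable variant."""
    base = reportability_gate(_tsg_variant(sift, poly), kb.panel)
    upgraded = reportability_gate(
        _tsg_variant(SiftCall.DELETERIOUS, PolyphenCall.DAMAGING), kb.panel)
    assert upgraded >= base


def test_cohort_roundtrip(tmp_path, fixture_cohort):
    sample = fixture_cohort[:40]
    vp, cp = tmp_path / "v.tsv", tmp_path / "c.tsv"
    write_cohort(sample, vp, cp)
    again = read_cohort(vp, cp)
    assert again == sample


def test_orphan_variant_rows_rejected(tmp_path):
    (tmp_path / "v.tsv").write_text(
        "test_id\tgene\tvariant_class\tprotein_change\texon\tfusion_partner"
        "\tcopy_number\tread_depth\tsift\tpolyphen\n"
        "T999\tKRAS\tSNV\tG12D\t2\t\t\t900\tUNKNOWN\tUNKNOWN\n")
    (tmp_path / "c.tsv").write_text(
        "test_id\tpatient_id\ttumor_type\tstage\tage\tsex\tprior_treatment"
        "\trecommendation\trecommendation_day\tfollowup_days\n"
        "T001\tP001\tLung\tIV\t64\tMALE\tONE_PLUS\t\t\t120\n")
    with pytest.raises(ValueError, match="T999"):
        read_cohort(tmp_path / "v.tsv", tmp_path / "c.tsv")


def test_empty_variant_list_allowed(tmp_path):
    (tmp_path / "v.tsv").write_text(
        "test_id\tgene\tvariant_class\tprotein_change\texon\tfusion_partner"
        "\tcopy_number\tread_depth\tsift\tpolyphen\n")
    (tmp_path / "c.tsv").write_text(
        "test_id\tpatient_id\ttumor_type\tstage\tage\tsex\tprior_treatment"
        "\trecommendation\trecommendation_day\tfollowup_days\n"
        "T001\tP001\tLung\tIV\t64\tMALE\tONE_PLUS\t\t\t120\n")
    records = read_cohort(tmp_path / "v.tsv", tmp_path / "c.tsv")
    assert len(records) == 1 and records[0].variants == []


VCF_TEXT = """\
##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=PCHANGE,Number=1,Type=String,Description="Protein change">
##INFO=<ID=VCLASS,Number=1,Type=String,Description="Variant class">
##INFO=<ID=SIFT,Number=1,Type=String,Description="SIFT call">
##INFO=<ID=POLYPHEN,Number=1,Type=String,Description="PolyPhen call">
##INFO=<ID=CN,Number=1,Type=Float,Description="Copy number">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##INFO=<ID=EXON,Number=1,Type=Integer,Description="Exon">
##INFO=<ID=PARTNER,Number=1,Type=String,Description="Fusion partner">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=chr7>
##contig=<ID=chr17>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tT001
chr7\t55259515\t.\tT\tG\t.\tPASS\tGENE=EGFR;PCHANGE=L858R;VCLASS=SNV;DP=980;SIFT=DELETERIOUS;EXON=21\tGT\t0/1
chr17\t37880220\t.\tN\t<CNV>\t.\tPASS\tGENE=ERBB2;VCLASS=CNV_GAIN;CN=9.0\tGT\t0/1
"""


def test_minimal_vcf_reader(tmp_path):
    vcf = tmp_path / "variants.vcf"
    vcf.write_text(VCF_TEXT)
    (tmp_path / "c.tsv").write_text(
        "test_id\tpatient_id\ttumor_type\tstage\tage\tsex\tprior_treatment"
        "\trecommendation\trecommendation_day\tfollowup_days\n"
        "T001\tP001\tLung\tIV\t64\tMALE\tONE_PLUS\t\t\t120\n")
    records = read_cohort(vcf, tmp_path / "c.tsv")
    assert len(records) == 1
    v1, v2 = records[0].variants
    assert (v1.gene, v1.protein_change, v1.read_depth, v1.exon) == \
        ("EGFR", "L858R", 980, 21)
    assert v1.sift_call is SiftCall.DELETERIOUS
    assert (v2.gene, v2.variant_class, v2.copy_number) == \
        ("ERBB2", VariantClass.CNV_GAIN, 9.0)


def test_frames_preserve_record_count(fixture_cohort):
    vdf, cdf = cohort_to_frames(fixture_cohort)
    assert len(cdf) == len(fixture_cohort)
    assert len(vdf) == sum(len(r.variants) for r in fixture_cohort)
    assert isinstance(fixture_cohort[0], TestRecord)
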