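"""Observed-variant and test-record data model, readers/writers, QC gates.

A test is one NGS panel run on one tumor specimen. Each test carries zero or
more observed (already-called, already-annotated) alterations. Two gates
precede any actionability classification:

* a read-depth gate for small variants (the panel's validated minimum), and
* a reportability gate implementing the panel's dual coverage strategy —
  hotspot reporting for oncogenes versus full-coding-sequence reporting for
  tumor suppressor genes, the latter requiring concordant deleterious calls
  from both SIFT and PolyPhen.

Coordinates are protein-level (HGVS-p short form, e.g. ``V600E``); genomic
coordinates are out of scope because therapeutic associations are expressed
at the protein/codon/exon/gene level.
"""

from __future__ import annotations

import enum
import logging
import re
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, model_validator

from .knowledgebase import PanelDefinition

logger = logging.getLogger(__name__)

#: Minimum validated read depth for small-variant calls.
DEFAULT_MIN_DEPTH = 457
#: Copy-number thresholds for high-level amplification / homozygous deletion.
DEFAULT_AMP_THRESHOLD = 6.0
DEFAULT_DEL_THRESHOLD = 0.5


class VariantClass(str, enum.Enum):
    SNV = "SNV"
    INSERTION = "INSERTION"
    DELETION = "DELETION"
    INDEL = "INDEL"
    CNV_GAIN = "CNV_GAIN"
    CNV_LOSS = "CNV_LOSS"
    FUSION = "FUSION"
    EXON_SKIP = "EXON_SKIP"


#: Classes produced by DNA small-variant calling (have a protein change).
SMALL_VARIANT_CLASSES = frozenset(
    {VariantClass.SNV, VariantClass.INSERTION, VariantClass.DELETION, VariantClass.INDEL}
)
CNV_CLASSES = frozenset({VariantClass.CNV_GAIN, VariantClass.CNV_LOSS})


class SiftCall(str, enum.Enum):
    DELETERIOUS = "DELETERIOUS"
    TOLERATED = "TOLERATED"
    UNKNOWN = "UNKNOWN"


class PolyphenCall(str, enum.Enum):
    DAMAGING = "DAMAGING"
    BENIGN = "BENIGN"
    UNKNOWN = "UNKNOWN"


class Stage(str, enum.Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    UNKNOWN = "UNKNOWN"


class Sex(str, enum.Enum):
    FEMALE = "FEMALE"
    MALE = "MALE"
    UNKNOWN = "UNKNOWN"


class PriorTreatment(str, enum.Enum):
    NONE = "NONE"
    ONE_PLUS = "ONE_PLUS"
    UNKNOWN = "UNKNOWN"


_PCHANGE_RE = re.compile(r"^([A-Z])(\d+)(?:[_=]?([A-Z])(\d+))?([A-Za-z*>]*.*)$")


class ProteinChangeError(ValueError):
    """Raised for a protein-change string the short-HGVS parser cannot read."""


def parse_protein_change(pchange: str) -> tuple[int, Optional[int]]:
    """Parse a short-form HGVS-p string into (first_codon, last_codon).

    Handles simple substitutions (``V600E`` -> (600, None)), range events
    (``E746_A750del`` -> (746, 750), ``Y742_A745dup``), and nonsense
    (``Q192*``). The first affected codon is the matching key for codon-set
    patterns.
    """
    s = pchange.replace(" ", "")
    m = _PCHANGE_RE.match(s)
    if not m or not m.group(2):
        raise ProteinChangeError(f"unparseable protein change: {pchange!r}")
    first = int(m.group(2))
    last = int(m.group(4)) if m.group(4) else None
    return first, last


class ObservedVariant(BaseModel):
    """One called alteration with class, annotations, and QC fields."""

    model_config = {"frozen": True}

    gene: str
    variant_class: VariantClass
    protein_change: Optional[str] = None
    codon: Optional[int] = None
    exon: Optional[int] = None
    fusion_partner: Optional[str] = None
    copy_number: Optional[float] = None
    read_depth: Optional[int] = None
    sift_call: SiftCall = SiftCall.UNKNOWN
    polyphen_call: PolyphenCall = PolyphenCall.UNKNOWN

    @model_validator(mode="after")
    def _check_invariants(self) -> "ObservedVariant":
        object.__setattr__(self, "gene", self.gene.upper())
        small = self.variant_class in SMALL_VARIANT_CLASSES
        if small and not self.protein_change:
            raise ValueError(f"{self.gene}: small variant requires a protein change")
        if not small and self.protein_change:
            raise ValueError(
                f"{self.gene}: protein change only valid for small variants"
            )
        if self.fusion_partner and self.variant_class is not VariantClass.FUSION:
            raise ValueError(f"{self.gene}: fusion partner only valid for fusions")
        if self.copy_number is not None:
            if self.variant_class not in CNV_CLASSES:
                raise ValueError(f"{self.gene}: copy number only valid for CNVs")
            if self.copy_number < 0:
                raise ValueError(f"{self.gene}: negative copy number")
        if small and self.codon is None:
            first, _ = parse_protein_change(self.protein_change)
            object.__setattr__(self, "codon", first)
        return self

    @property
    def is_small(self) -> bool:
        return self.variant_class in SMALL_VARIANT_CLASSES


class TestRecord(BaseModel):
    """One NGS test: demographics, tumor type, variants, recommendation."""

    test_id: str
    patient_id: str
    tumor_type: str
    stage: Stage = Stage.UNKNOWN
    age: Optional[int] = None
    sex: Sex = Sex.UNKNOWN
    prior_treatment: PriorTreatment = PriorTreatment.UNKNOWN
    variants: list[ObservedVariant] = []
    recommendation: Optional[str] = None
    recommendation_day: Optional[int] = None
    followup_days: Optional[int] = None


# ---------------------------------------------------------------------------
# QC and reportability gates
# ---------------------------------------------------------------------------

def qc_filter(variant: ObservedVariant, min_depth: int = DEFAULT_MIN_DEPTH) -> bool:
    """Depth gate for small variants.

    CNV and fusion calls are exempt (read depth is not defined for them in
    this model); a small variant with no recorded depth passes with a logged
    warning rather than silently vanishing from the report.
    """
    if not variant.is_small:
        return True
    if variant.read_depth is None:
        logger.warning("%s %s: missing read depth, passing QC by default",
                       variant.gene, variant.protein_change)
        return True
    return variant.read_depth >= min_depth


def reportability_gate(
    variant: ObservedVariant,
    panel: PanelDefinition,
    amp_threshold: float = DEFAULT_AMP_THRESHOLD,
    del_threshold: float = DEFAULT_DEL_THRESHOLD,
) -> bool:
    """Panel reporting rules: hotspot vs full-coding strategy plus CNV/fusion gating.

    Small variants in full-coding (tumor suppressor) genes are reportable only
    when called deleterious by SIFT AND damaging by PolyPhen. Small variants in
    hotspot (oncogene) genes are reportable regardless of in-silico calls.
    Copy-number gains/losses are reportable only for the corresponding panel
    gene sets and only past the amplification / homozygous-deletion
    thresholds. Fusions and exon-skipping events require the gene on the RNA
    fusion panel. Genes off the panel are not reportable (logged, never an
    exception).
    """
    gene = variant.gene
    vc = variant.variant_class
    if variant.is_small:
        if gene in panel.hotspot_genes:
            return True
        if gene in panel.full_coding_genes:
            return (
                variant.sift_call is SiftCall.DELETERIOUS
                and variant.polyphen_call is PolyphenCall.DAMAGING
            )
        logger.info("%s: gene not on small-variant panel, not reportable", gene)
        return False
    if vc is VariantClass.CNV_GAIN:
        return (
            gene in panel.cn_gain_genes
            and variant.copy_number is not None
            and variant.copy_number >= amp_threshold
        )
    if vc is VariantClass.CNV_LOSS:
        return (
            gene in panel.cn_loss_genes
            and variant.copy_number is not None
            and variant.copy_number <= del_threshold
        )
    # FUSION and EXON_SKIP come off the RNA panel.
    return gene in panel.fusion_genes


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

VARIANT_COLUMNS = [
    "test_id", "gene", "variant_class", "protein_change", "exon",
    "fusion_partner", "copy_number", "read_depth", "sift", "polyphen",
]
COHORT_COLUMNS = [
    "test_id", "patient_id", "tumor_type", "stage", "age", "sex",
    "prior_treatment", "recommendation", "recommendation_day", "followup_days",
]


class CohortReadError(ValueError):
    """Raised for structural problems in cohort/variant input tables."""


def _opt(value, cast):
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return cast(value)


def _variant_from_row(row: dict, line_no: Optional[int] = None) -> ObservedVariant:
    try:
        return ObservedVariant(
            gene=str(row["gene"]),
            variant_class=VariantClass(str(row["variant_class"])),
            protein_change=_opt(row.get("protein_change"), str),
            exon=_opt(row.get("exon"), lambda v: int(float(v))),
            fusion_partner=_opt(row.get("fusion_partner"), str),
            copy_number=_opt(row.get("copy_number"), float),
            read_depth=_opt(row.get("read_depth"), lambda v: int(float(v))),
            sift_call=SiftCall(str(row.get("sift") or "UNKNOWN")),
            polyphen_call=PolyphenCall(str(row.get("polyphen") or "UNKNOWN")),
        )
    except (ValueError, ProteinChangeError) as exc:
        where = f" (line {line_no})" if line_no is not None else ""
        raise CohortReadError(f"bad variant row{where}: {exc}") from exc


def read_variants_table(path: str | Path) -> pd.DataFrame:
    """Read the variant TSV dialect into a DataFrame (one row per alteration)."""
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def read_variants_vcf(path: str | Path) -> pd.DataFrame:
    """Read the minimal annotated-VCF dialect into the variant-table layout.

    One sample per record names the test; annotations come from INFO keys
    GENE, PCHANGE, VCLASS, SIFT, POLYPHEN, CN, DP (optional EXON, PARTNER).
    """
    import pysam

    def iget(info, key):
        # INFO keys absent from a record (or the header) read as None.
        try:
            return info.get(key)
        except (KeyError, ValueError):
            return None

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = rec.info
            test_id = rec.samples.keys()[0] if rec.samples else iget(info, "TEST")
            cn, dp = iget(info, "CN"), iget(info, "DP")
            rows.append({
                "test_id": str(test_id),
                "gene": str(info["GENE"]),
                "variant_class": str(info["VCLASS"]),
                "protein_change": str(iget(info, "PCHANGE") or ""),
                "exon": str(iget(info, "EXON") or ""),
                "fusion_partner": str(iget(info, "PARTNER") or ""),
                "copy_number": "" if cn is None else str(cn),
                "read_depth": "" if dp is None else str(dp),
                "sift": str(iget(info, "SIFT") or "UNKNOWN"),
                "polyphen": str(iget(info, "POLYPHEN") or "UNKNOWN"),
            })
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS).astype(str)


def records_from_frames(vdf: pd.DataFrame, cdf: pd.DataFrame) -> list[TestRecord]:
    """Join a variant table onto a cohort table into TestRecords.

    Variant rows referencing a test_id absent from the cohort table are a
    structural error (listed in the exception); a cohort row with no variant
    rows yields a TestRecord with an empty variant list.
    """
    known = set(cdf["test_id"])
    orphans = sorted(set(vdf["test_id"]) - known)
    if orphans:
        raise CohortReadError(f"variant rows reference unknown test_ids: {orphans}")

    by_test: dict[str, list[ObservedVariant]] = {tid: [] for tid in known}
    for i, row in enumerate(vdf.to_dict("records")):
        by_test[row["test_id"]].append(_variant_from_row(row, line_no=i + 2))

    records = []
    for row in cdf.to_dict("records"):
        records.append(TestRecord(
            test_id=row["test_id"],
            patient_id=row["patient_id"],
            tumor_type=row["tumor_type"],
            stage=Stage(row.get("stage") or "UNKNOWN"),
            age=_opt(row.get("age"), lambda v: int(float(v))),
            sex=Sex(row.get("sex") or "UNKNOWN"),
            prior_treatment=PriorTreatment(row.get("prior_treatment") or "UNKNOWN"),
            variants=by_test[row["test_id"]],
            recommendation=_opt(row.get("recommendation"), str),
            recommendation_day=_opt(row.get("recommendation_day"), lambda v: int(float(v))),
            followup_days=_opt(row.get("followup_days"), lambda v: int(float(v))),
        ))
    return records


def read_cohort(variants_path: str | Path, cohort_path: str | Path) -> list[TestRecord]:
    """Read a variant table (TSV or VCF) plus a cohort TSV into TestRecords."""
    vpath = Path(variants_path)
    if vpath.suffix.lower() == ".vcf":
        vdf = read_variants_vcf(vpath)
    else:
        vdf = read_variants_table(vpath)
    cdf = pd.read_csv(cohort_path, sep="\t", dtype=str, keep_default_na=False)
    return records_from_frames(vdf, cdf)


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float) and value == int(value):
        return str(int(value))
    if isinstance(value, enum.Enum):
        return value.value
    return str(value)


def cohort_to_frames(records: list[TestRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten TestRecords back into (variant table, cohort table) DataFrames."""
    vrows, crows = [], []
    for rec in records:
        for v in rec.variants:
            vrows.append({
                "test_id": rec.test_id, "gene": v.gene,
                "variant_class": v.variant_class.value,
                "protein_change": _fmt(v.protein_change),
                "exon": _fmt(v.exon), "fusion_partner": _fmt(v.fusion_partner),
                "copy_number": _fmt(v.copy_number),
                "read_depth": _fmt(v.read_depth),
                "sift": v.sift_call.value, "polyphen": v.polyphen_call.value,
            })
        crows.append({
            "test_id": rec.test_id, "patient_id": rec.patient_id,
            "tumor_type": rec.tumor_type, "stage": rec.stage.value,
            "age": _fmt(rec.age), "sex": rec.sex.value,
            "prior_treatment": rec.prior_treatment.value,
            "recommendation": _fmt(rec.recommendation),
            "recommendation_day": _fmt(rec.recommendation_day),
            "followup_days": _fmt(rec.followup_days),
        })
    vdf = pd.DataFrame(vrows, columns=VARIANT_COLUMNS)
    cdf = pd.DataFrame(crows, columns=COHORT_COLUMNS)
    return vdf, cdf


def write_cohort(records: list[TestRecord],
                 variants_path: str | Path, cohort_path: str | Path) -> None:
    vdf, cdf = cohort_to_frames(records)
    vdf.to_csv(variants_path, sep="\t", index=False)
    cdf.to_csv(cohort_path, sep="\t", index=False)
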