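"""Recommendation classification and evidence-vs-recommendation agreement.

Physician recommendations made after an NGS test are bucketed into eight
categories and cross-tabulated against the test's most-actionable evidence
level. Eligibility requires a minimum post-test follow-up window; a
recommendation dated beyond the capture window counts as missing. The
headline statistic is the targeted-therapy recommendation rate per evidence
bucket, reported both over all level-1 tests and excluding tests whose
level-1 evidence is exclusively resistance contraindications.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .aggregate import TestClassification
from .levels import EvidenceLevel
from .variants import TestRecord

logger = logging.getLogger(__name__)

DEFAULT_MIN_FOLLOWUP_DAYS = 60
DEFAULT_WINDOW_DAYS = 120


class RecommendationCategory(str, enum.Enum):
    TARGETED_THERAPY = "TARGETED_THERAPY"
    CLINICAL_TRIAL = "CLINICAL_TRIAL"
    IMMUNOTHERAPY = "IMMUNOTHERAPY"
    HORMONAL = "HORMONAL"
    CHEMO_RADIATION = "CHEMO_RADIATION"
    SURGERY = "SURGERY"
    TRANSPLANT = "TRANSPLANT"
    NON_THERAPEUTIC = "NON_THERAPEUTIC"


BUCKETS = (EvidenceLevel.LEVEL_1, EvidenceLevel.LEVEL_2,
           EvidenceLevel.LEVEL_3, EvidenceLevel.VUTS)


def eligibility_filter(
    record: TestRecord,
    min_followup_days: int = DEFAULT_MIN_FOLLOWUP_DAYS,
) -> bool:
    """True iff the test has the minimum post-test follow-up available.

    Tests with no recorded follow-up time are excluded (with a warning) —
    absence of follow-up cannot establish eligibility.
    """
    if record.followup_days is None:
        logger.warning("%s: missing followup_days, excluded from agreement "
                       "analysis", record.test_id)
        return False
    return record.followup_days >= min_followup_days


def effective_recommendation(
    record: TestRecord,
    window_days: int = DEFAULT_WINDOW_DAYS,
) -> Optional[RecommendationCategory]:
    """The recommendation counted for a test: the first in-window one.

    A recommendation dated beyond the capture window is treated as missing.
    """
    if not record.recommendation:
        return None
    if record.recommendation_day is not None and record.recommendation_day > window_days:
        return None
    return RecommendationCategory(record.recommendation)


@dataclass(frozen=True)
class AgreementTable:
    """Bucket x category cross-tabulation with per-bucket denominators."""

    counts: pd.DataFrame           # index: bucket names; columns: categories
    denominators: pd.Series        # per-bucket test counts
    rates: pd.DataFrame            # counts / denominators (NaN when empty)
    targeted_rate_l1_excl_contra: float   # NaN when undefined
    n_l1_excl_contra: int
    n_l1_targeted_excl_contra: int

    def rate(self, bucket: EvidenceLevel, category: RecommendationCategory) -> float:
        return float(self.rates.loc[bucket.name, category.value])


def cross_tabulate(pairs) -> AgreementTable:
    """Cross-tabulate (TestClassification, recommendation-or-None) pairs.

    Also computes the targeted-therapy rate among level-1 tests after
    dropping tests whose level-1 evidence is contraindication-only.
    Empty buckets yield NaN rates, never zero.
    """
    idx = [b.name for b in BUCKETS]
    cols = [c.value for c in RecommendationCategory]
    counts = pd.DataFrame(0, index=idx, columns=cols, dtype=int)
    denom = pd.Series(0, index=idx, dtype=int)

    n_l1_ok = 0
    n_l1_ok_targeted = 0
    for tc, rec in pairs:
        bucket = tc.most_actionable.name
        denom[bucket] += 1
        if rec is not None:
            counts.loc[bucket, RecommendationCategory(rec).value] += 1
        if tc.most_actionable is EvidenceLevel.LEVEL_1 and not tc.level1_contraindicated_only:
            n_l1_ok += 1
            if rec is not None and RecommendationCategory(rec) is RecommendationCategory.TARGETED_THERAPY:
                n_l1_ok_targeted += 1

    rates = counts.astype(float)
    for b in idx:
        if denom[b] == 0:
            rates.loc[b] = math.nan
        else:
            rates.loc[b] = counts.loc[b] / denom[b]

    excl = (n_l1_ok_targeted / n_l1_ok) if n_l1_ok else math.nan
    return AgreementTable(
        counts=counts,
        denominators=denom,
        rates=rates,
        targeted_rate_l1_excl_contra=excl,
        n_l1_excl_contra=n_l1_ok,
        n_l1_targeted_excl_contra=n_l1_ok_targeted,
    )


@dataclass(frozen=True)
class OffLabelSummary:
    """Off-label indications among tests with no level-1/2 evidence."""

    variant_count: int
    test_count: int
    brca_variant_count: int
    targeted_test_count: int
    uptake_numerator: int            # off-label variants in targeted-rec tests
    uptake_rate: float               # NaN when no off-label variants
    brca_fraction: float             # NaN when no off-label variants


def off_label_uptake(pairs) -> OffLabelSummary:
    """Count off-label-indicated variants/tests among level-3-bucket tests
    and the targeted-therapy uptake over those variants."""
    n_var = 0
    n_test = 0
    n_brca = 0
    n_targeted_tests = 0
    uptake_num = 0
    for tc, rec in pairs:
        if tc.most_actionable is not EvidenceLevel.LEVEL_3:
            continue
        hits = tc.off_label_hits
        if not hits:
            continue
        n_test += 1
        n_var += len(hits)
        n_brca += sum(1 for cv in hits if cv.variant.gene in ("BRCA1", "BRCA2"))
        targeted = (rec is not None and
                    RecommendationCategory(rec) is RecommendationCategory.TARGETED_THERAPY)
        if targeted:
            n_targeted_tests += 1
            uptake_num += len(hits)
    return OffLabelSummary(
        variant_count=n_var,
        test_count=n_test,
        brca_variant_count=n_brca,
        targeted_test_count=n_targeted_tests,
        uptake_numerator=uptake_num,
        uptake_rate=(uptake_num / n_var) if n_var else math.nan,
        brca_fraction=(n_brca / n_var) if n_var else math.nan,
    )


def pair_records(tests: list[TestClassification], records: list[TestRecord],
                 min_followup_days: int = DEFAULT_MIN_FOLLOWUP_DAYS,
                 window_days: int = DEFAULT_WINDOW_DAYS):
    """Join classifications with eligibility-filtered recommendations."""
    by_id = {r.test_id: r for r in records}
    pairs = []
    for tc in tests:
        rec = by_id[tc.test_id]
        if not eligibility_filter(rec, min_followup_days):
            continue
        pairs.append((tc, effective_recommendation(rec, window_days)))
    return pairs


def agreement_to_dict(table: AgreementTable) -> dict:
    """JSON-ready export of the agreement table."""
    return {
        "counts": {b: table.counts.loc[b].to_dict() for b in table.counts.index},
        "denominators": table.denominators.to_dict(),
        "rates": {
            b: {c: (None if math.isnan(v) else v)
                for c, v in table.rates.loc[b].to_dict().items()}
            for b in table.rates.index
        },
        "targeted_rate_l1_excl_contra": (
            None if math.isnan(table.targeted_rate_l1_excl_contra)
            else table.targeted_rate_l1_excl_contra
        ),
        "n_l1_excl_contra": table.n_l1_excl_contra,
    }
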