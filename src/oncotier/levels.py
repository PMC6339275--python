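"""Evidence levels for somatic variant actionability.

The three-tier scheme used by US regulators for NGS tumor panels:

* ``LEVEL_1`` — companion diagnostic: the biomarker is required on an
  approved drug label for safe and effective use of that drug.
* ``LEVEL_2`` — the biomarker-therapy association is supported by
  professional practice guidelines (NCCN, ESMO) rather than a label.
* ``LEVEL_3`` — the biomarker supports enrollment in a clinical trial or
  off-label use of a label-listed biomarker in a different tumor type.
* ``VUTS`` — variant of unknown therapeutic significance: reportable but
  with no therapy association at any level.

Levels are totally ordered by strength of evidence; smaller rank = stronger.
"""

from __future__ import annotations

import enum


class EvidenceLevel(enum.Enum):
    LEVEL_1 = 1
    LEVEL_2 = 2
    LEVEL_3 = 3
    VUTS = 4

    @property
    def rank(self) -> int:
        """Ordering rank: 1 strongest ... 4 weakest."""
        return self.value

    @property
    def label(self) -> str:
        return {1: "Level 1", 2: "Level 2", 3: "Level 3", 4: "VUTS"}[self.value]

    def __lt__(self, other: "EvidenceLevel") -> bool:
        if not isinstance(other, EvidenceLevel):
            return NotImplemented
        return self.rank < other.rank

    def __le__(self, other: "EvidenceLevel") -> bool:
        if not isinstance(other, EvidenceLevel):
            return NotImplemented
        return self.rank <= other.rank

    def __gt__(self, other: "EvidenceLevel") -> bool:
        if not isinstance(other, EvidenceLevel):
            return NotImplemented
        return self.rank > other.rank

    def __ge__(self, other: "EvidenceLevel") -> bool:
        if not isinstance(other, EvidenceLevel):
            return NotImplemented
        return self.rank >= other.rank


def strongest(levels) -> EvidenceLevel:
    """Return the strongest (lowest-rank) level in an iterable; VUTS if empty."""
    levels = list(levels)
    if not levels:
        return EvidenceLevel.VUTS
    return min(levels, key=lambda lv: lv.rank)
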