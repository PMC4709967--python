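"""Somatic/germline classification of candidate small indels.

A candidate indel (already called and locally realigned upstream) is
annotated germline when any normal sample shows evidence for the same event
at the locus, somatic when no normal does, and unevaluable when no normal
has coverage there.  "Any evidence" defaults to a single supporting read; a
``min_support`` knob is exposed because one noisy read is an aggressive
germline call at high depth.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

SOMATIC = "somatic"
GERMLINE = "germline"
UNEVALUABLE = "unevaluable"


@dataclass(frozen=True)
class IndelCandidate:
    """One candidate indel with tumor support and per-normal-sample support."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    tumor_support: int
    tumor_total: int
    normal_support: tuple[int, ...]  # supporting reads per normal sample
    normal_total: tuple[int, ...]  # total reads per normal sample

    def __post_init__(self) -> None:
        if len(self.ref) == len(self.alt):
            raise ValueError(
                f"not an indel at {self.chrom}:{self.pos}: ref/alt lengths equal"
            )
        if len(self.normal_support) != len(self.normal_total):
            raise ValueError("normal support/total vectors differ in length")
        if self.tumor_support > self.tumor_total:
            raise ValueError("tumor supporting reads exceed total reads")
        for s, t in zip(self.normal_support, self.normal_total):
            if s > t:
                raise ValueError("normal supporting reads exceed total reads")


def classify_indel(candidate: IndelCandidate, min_support: int = 1) -> str:
    """Classify one indel by evidence in the panel of normals.

    germline iff any covered normal has >= min_support supporting reads;
    somatic otherwise; unevaluable when every normal has zero total reads.
    """
    covered = [
        s for s, t in zip(candidate.normal_support, candidate.normal_total) if t > 0
    ]
    if not covered:
        return UNEVALUABLE
    if any(s >= min_support for s in covered):
        return GERMLINE
    return SOMATIC


def classify_cohort(
    candidates: Sequence[IndelCandidate], min_support: int = 1
) -> tuple[list[tuple[IndelCandidate, str]], Counter]:
    """Classify every candidate; the class counts partition the input."""
    annotated = [(c, classify_indel(c, min_support)) for c in candidates]
    counts = Counter(cls for _, cls in annotated)
    for cls in (SOMATIC, GERMLINE, UNEVALUABLE):
        counts.setdefault(cls, 0)
    return annotated, counts
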