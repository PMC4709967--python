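"""High-confidence somatic SNV filtering from tumor/normal per-read evidence.

A candidate site passes only if all nine criteria hold:

1. tumor and normal depth both >= 10;
2. tumor VAF >= 10 % (5 % in validation mode for deep target-capture
   re-sequencing) and normal VAF < 2 %;
3. >= 3 alt-supporting tumor reads;
4. nearest candidate on the same chromosome > 10 bp away (cohort-level
   adjacency rule, applied by :func:`adjacency_filter`);
5. alt-read mapping qualities significantly above 30
   (one-sided Wilcoxon signed-rank, p < 0.2);
6. alt-read base qualities significantly above 20 (p < 0.05);
7. alt calls not enriched within 5 bp of read ends
   (one-sided rank-sum vs ref reads, reject if p < 0.1);
8. tumor-vs-normal allele-frequency contrast significant
   (two-sided Fisher exact, p < 0.05);
9. alt reads not strand-biased (two-sided Fisher exact, reject if p < 1e-4).

All alpha comparisons are strict (p < alpha), matching the stated cutoffs.
Criteria 5-6 are read as one-sample, one-sided signed-rank tests against the
constant (a two-sample rank-sum test needs two samples); zero differences
are dropped.  Reads supporting neither ref nor alt count toward depth but
join neither group in the per-read tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from ._rank import rank_sum_p, signed_rank_greater

CRITERION_NAMES = (
    "depth", "vaf", "alt_reads", "adjacency", "mapq",
    "baseq", "read_end", "vaf_contrast", "strand_bias",
)


@dataclass(frozen=True)
class ReadObservation:
    """One read's call at the candidate locus."""

    allele: str  # 'ref', 'alt' or 'other'
    mapq: int
    baseq: int
    offset5: int  # 0-based distance of the call from the 5' read end
    read_length: int
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.allele not in ("ref", "alt", "other"):
            raise ValueError(f"allele must be ref/alt/other, got {self.allele!r}")
        if not 0 <= self.offset5 < self.read_length:
            raise ValueError(
                f"offset5 {self.offset5} outside read of length {self.read_length}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def end_distance(self) -> int:
        """Distance to the nearest read end."""
        return min(self.offset5, self.read_length - 1 - self.offset5)


@dataclass(frozen=True)
class SiteEvidence:
    """Tumor and matched-normal per-read observations at one candidate SNV."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    tumor_obs: tuple[ReadObservation, ...]
    normal_obs: tuple[ReadObservation, ...]

    @staticmethod
    def _counts(obs: Sequence[ReadObservation]) -> tuple[int, int, int]:
        alt = sum(o.allele == "alt" for o in obs)
        ref = sum(o.allele == "ref" for o in obs)
        return alt, ref, len(obs)

    @property
    def tumor_depth(self) -> int:
        return len(self.tumor_obs)

    @property
    def normal_depth(self) -> int:
        return len(self.normal_obs)

    @property
    def tumor_vaf(self) -> float:
        d = self.tumor_depth
        return self._counts(self.tumor_obs)[0] / d if d else 0.0

    @property
    def normal_vaf(self) -> float:
        d = self.normal_depth
        return self._counts(self.normal_obs)[0] / d if d else 0.0


@dataclass(frozen=True)
class SnvFilterThresholds:
    min_depth: int = 10
    min_tumor_vaf: float = 0.10
    max_normal_vaf: float = 0.02
    min_alt_reads: int = 3
    min_adjacent_distance_bp: int = 10
    mapq_ref_value: float = 30.0
    mapq_alpha: float = 0.2
    baseq_ref_value: float = 20.0
    baseq_alpha: float = 0.05
    readend_window_bp: int = 5
    readend_alpha: float = 0.1
    vaf_contrast_alpha: float = 0.05
    strand_alpha: float = 0.0001
    validation_min_vaf: float = 0.05

    def __post_init__(self) -> None:
        for name in ("mapq_alpha", "baseq_alpha", "readend_alpha",
                     "vaf_contrast_alpha", "strand_alpha"):
            a = getattr(self, name)
            if not 0.0 < a < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {a}")
        if self.min_depth <= 0 or self.min_alt_reads <= 0:
            raise ValueError("count thresholds must be positive")


@dataclass
class FilterVerdict:
    """Per-criterion outcome for one site; overall = AND of all nine."""

    flags: dict  # criterion name -> bool
    pvalues: dict  # criterion name -> float, for the statistical criteria

    @property
    def overall(self) -> bool:
        return all(self.flags.values())

    def failed(self) -> list[str]:
        return [k for k in CRITERION_NAMES if not self.flags.get(k, True)]


# ---------------------------------------------------------------------------
# per-criterion tests


def vaf_contrast_test(
    tumor_alt: int, tumor_ref: int, normal_alt: int, normal_ref: int
) -> float:
    """Two-sided Fisher exact p for the alt/ref x tumor/normal table."""
    if tumor_alt + tumor_ref == 0 or normal_alt + normal_ref == 0:
        raise ValueError("zero-depth sample in allele-frequency contrast")
    table = [[tumor_alt, tumor_ref], [normal_alt, normal_ref]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def strand_bias_test(alt_fwd: int, alt_rev: int, ref_fwd: int, ref_rev: int) -> float:
    """Two-sided Fisher exact p for alt/ref x forward/reverse strand."""
    if alt_fwd + alt_rev + ref_fwd + ref_rev == 0:
        raise ValueError("no stranded observations for strand-bias test")
    table = [[alt_fwd, alt_rev], [ref_fwd, ref_rev]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def mapq_support_test(alt_mapqs: Sequence[float], reference: float = 30.0) -> float:
    """One-sided signed-rank p that alt-read mapping qualities exceed ``reference``."""
    if len(alt_mapqs) == 0:
        raise ValueError("no alt-supporting reads for mapping-quality test")
    return signed_rank_greater(alt_mapqs, reference)


def baseq_support_test(alt_baseqs: Sequence[float], reference: float = 20.0) -> float:
    """One-sided signed-rank p that alt-read base qualities exceed ``reference``."""
    if len(alt_baseqs) == 0:
        raise ValueError("no alt-supporting reads for base-quality test")
    return signed_rank_greater(alt_baseqs, reference)


def read_end_enrichment_test(
    alt_obs: Sequence[ReadObservation], ref_obs: Sequence[ReadObservation]
) -> float:
    """One-sided rank-sum p that alt calls sit closer to read ends than ref calls.

    Each observation is scored by its distance to the nearest read end; a
    small p means the mutation is end-enriched (likely alignment artifact)
    and the site should be rejected.
    """
    if len(alt_obs) == 0 or len(ref_obs) == 0:
        raise ValueError("read-end test needs at least one alt and one ref read")
    alt_d = [o.end_distance for o in alt_obs]
    ref_d = [o.end_distance for o in ref_obs]
    return rank_sum_p(alt_d, ref_d, alternative="less")


def adjacency_filter(
    positions_by_chrom: Mapping[str, Sequence[int]],
    min_distance_bp: int = 10,
    keep_first: bool = False,
) -> dict[str, list[int]]:
    """Drop candidates whose nearest same-chromosome neighbour is <= min_distance_bp.

    Both members of a close pair are removed by default (the violation is a
    property of the pair); ``keep_first`` retains the left member instead.
    """
    out: dict[str, list[int]] = {}
    for chrom, positions in positions_by_chrom.items():
        pos = sorted(positions)
        keep = []
        for i, p in enumerate(pos):
            too_close_left = i > 0 and (p - pos[i - 1]) <= min_distance_bp
            too_close_right = i + 1 < len(pos) and (pos[i + 1] - p) <= min_distance_bp
            if keep_first:
                # greedy left-to-right: drop a site only if it crowds a kept one
                if not keep or (p - keep[-1]) > min_distance_bp:
                    keep.append(p)
            elif not (too_close_left or too_close_right):
                keep.append(p)
        out[chrom] = keep
    return out


def evaluate_site(
    site: SiteEvidence,
    thresholds: SnvFilterThresholds | None = None,
    mode: str = "discovery",
) -> FilterVerdict:
    """Apply criteria 1-3 and 5-9 to one site (criterion 4 is cohort-level).

    In ``validation`` mode (deep target-capture re-sequencing) the minimum
    tumor VAF drops to ``validation_min_vaf`` so that low-frequency
    mutations are retained.
    """
    t = thresholds or SnvFilterThresholds()
    if mode not in ("discovery", "validation"):
        raise ValueError(f"unknown mode {mode!r}")
    if not site.normal_obs:
        raise ValueError(f"missing normal evidence at {site.chrom}:{site.pos}")
    min_vaf = t.min_tumor_vaf if mode == "discovery" else t.validation_min_vaf

    t_alt = [o for o in site.tumor_obs if o.allele == "alt"]
    t_ref = [o for o in site.tumor_obs if o.allele == "ref"]
    n_alt = sum(o.allele == "alt" for o in site.normal_obs)
    n_ref = sum(o.allele == "ref" for o in site.normal_obs)

    flags: dict[str, bool] = {}
    pvals: dict[str, float] = {}

    flags["depth"] = (
        site.tumor_depth >= t.min_depth and site.normal_depth >= t.min_depth
    )
    flags["vaf"] = site.tumor_vaf >= min_vaf and site.normal_vaf < t.max_normal_vaf
    flags["alt_reads"] = len(t_alt) >= t.min_alt_reads

    if t_alt:
        pvals["mapq"] = mapq_support_test([o.mapq for o in t_alt], t.mapq_ref_value)
        flags["mapq"] = pvals["mapq"] < t.mapq_alpha
        pvals["baseq"] = baseq_support_test([o.baseq for o in t_alt], t.baseq_ref_value)
        flags["baseq"] = pvals["baseq"] < t.baseq_alpha
    else:
        flags["mapq"] = False
        flags["baseq"] = False

    if t_alt and t_ref:
        pvals["read_end"] = read_end_enrichment_test(t_alt, t_ref)
        flags["read_end"] = pvals["read_end"] >= t.readend_alpha
    else:
        # without both groups end-enrichment cannot be demonstrated
        flags["read_end"] = True

    if site.tumor_depth and site.normal_depth:
        pvals["vaf_contrast"] = vaf_contrast_test(
            len(t_alt), len(t_ref), n_alt, n_ref
        )
        flags["vaf_contrast"] = pvals["vaf_contrast"] < t.vaf_contrast_alpha
    else:
        flags["vaf_contrast"] = False

    alt_fwd = sum(o.strand == "+" for o in t_alt)
    ref_fwd = sum(o.strand == "+" for o in t_ref)
    if t_alt or t_ref:
        pvals["strand_bias"] = strand_bias_test(
            alt_fwd, len(t_alt) - alt_fwd, ref_fwd, len(t_ref) - ref_fwd
        )
        flags["strand_bias"] = pvals["strand_bias"] >= t.strand_alpha
    else:
        flags["strand_bias"] = False

    return FilterVerdict(flags=flags, pvalues=pvals)


def filter_cohort(
    sites: Sequence[SiteEvidence],
    thresholds: SnvFilterThresholds | None = None,
    mode: str = "discovery",
    keep_first: bool = False,
) -> tuple[list[SiteEvidence], list[FilterVerdict]]:
    """Evaluate every site, then apply the cohort-level adjacency rule.

    Returns the passing sites and a verdict per input site (in input order)
    with the adjacency flag filled in.
    """
    t = thresholds or SnvFilterThresholds()
    verdicts = [evaluate_site(s, t, mode) for s in sites]
    by_chrom: dict[str, list[int]] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append(s.pos)
    kept_pos = adjacency_filter(by_chrom, t.min_adjacent_distance_bp, keep_first)
    kept_sets = {c: set(p) for c, p in kept_pos.items()}
    passing = []
    for s, v in zip(sites, verdicts):
        v.flags["adjacency"] = s.pos in kept_sets.get(s.chrom, set())
        if v.overall:
            passing.append(s)
    return passing, verdicts
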