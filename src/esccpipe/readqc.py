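"""Lane, read, and sample sequencing QC gates.

Three tiers of quality control precede somatic variant calling:

* lane level — sequencing error rate, Phred base-call accuracy (Q20/Q30),
  and GC/AT base-composition separation;
* read level — adaptor contamination, N content, and low-quality-base
  content of every single read;
* sample level — mean depth (assay-dependent), mapping rate, mismatch rate.

All threshold comparisons are inclusive (<= / >=) exactly as stated by the
defaults in :class:`QcThresholds`.  "GC or AT separation rate" is taken to
be |GC fraction - AT fraction| over non-N bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np


@dataclass(frozen=True)
class QcThresholds:
    """Cutoffs for lane, read and sample gates (rates as fractions)."""

    max_error_rate: float = 0.025
    min_q20: float = 0.80
    min_q30: float = 0.75
    max_gc_at_separation: float = 0.004
    max_adaptor_rate: float = 0.10
    max_n_rate: float = 0.10
    lowqual_base_q: int = 5
    max_lowqual_rate: float = 0.50
    min_depth_wgs: float = 30.0
    min_depth_wes: float = 100.0
    min_mapping_rate: float = 0.95
    max_mismatch_rate: float = 0.10

    def __post_init__(self) -> None:
        for name in (
            "max_error_rate", "min_q20", "min_q30", "max_gc_at_separation",
            "max_adaptor_rate", "max_n_rate", "max_lowqual_rate",
            "min_mapping_rate", "max_mismatch_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.lowqual_base_q < 0:
            raise ValueError("lowqual_base_q must be non-negative")


@dataclass(frozen=True)
class LaneMetrics:
    error_rate: float
    q20_fraction: float
    q30_fraction: float
    gc_fraction: float
    at_fraction: float
    adaptor_rate: float

    @property
    def gc_at_separation(self) -> float:
        return abs(self.gc_fraction - self.at_fraction)


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read: bases over {A,C,G,T,N} plus Phred qualities."""

    bases: str
    quals: Sequence[int]
    adaptor_flag: bool = False

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"base/quality length mismatch: {len(self.bases)} vs {len(self.quals)}"
            )

    @property
    def n_rate(self) -> float:
        return self.bases.count("N") / len(self.bases) if self.bases else 0.0

    def lowqual_rate(self, q_cut: int) -> float:
        if not self.quals:
            return 0.0
        return sum(q < q_cut for q in self.quals) / len(self.quals)


def compute_lane_metrics(
    reads: Sequence[ReadRecord], error_rate: float = 0.0
) -> LaneMetrics:
    """Aggregate per-base metrics over a lane of reads.

    ``error_rate`` is instrument-reported (from spiked-in controls) and is
    passed through; the base-derived metrics are computed here.  Q20/Q30
    fractions are over all base calls, GC/AT fractions over non-N calls.
    """
    if not reads:
        raise ValueError("cannot compute lane metrics on an empty read set")
    n_bases = 0
    n_q20 = 0
    n_q30 = 0
    n_gc = 0
    n_at = 0
    n_adaptor = 0
    for r in reads:
        n_bases += len(r.quals)
        for q in r.quals:
            if q >= 20:
                n_q20 += 1
            if q >= 30:
                n_q30 += 1
        n_gc += r.bases.count("G") + r.bases.count("C")
        n_at += r.bases.count("A") + r.bases.count("T")
        n_adaptor += bool(r.adaptor_flag)
    non_n = n_gc + n_at
    return LaneMetrics(
        error_rate=error_rate,
        q20_fraction=n_q20 / n_bases,
        q30_fraction=n_q30 / n_bases,
        gc_fraction=n_gc / non_n if non_n else 0.0,
        at_fraction=n_at / non_n if non_n else 0.0,
        adaptor_rate=n_adaptor / len(reads),
    )


def check_lane(metrics: LaneMetrics, thresholds: QcThresholds | None = None) -> dict:
    """Per-criterion lane pass flags; overall pass iff every criterion passes."""
    t = thresholds or QcThresholds()
    flags = {
        "error_rate": metrics.error_rate <= t.max_error_rate,
        "q20": metrics.q20_fraction >= t.min_q20,
        "q30": metrics.q30_fraction >= t.min_q30,
        "gc_at_separation": metrics.gc_at_separation <= t.max_gc_at_separation,
    }
    flags["overall"] = all(flags.values())
    return flags


def filter_reads(
    reads: Iterable[ReadRecord], thresholds: QcThresholds | None = None
) -> tuple[list[ReadRecord], list[tuple[ReadRecord, str]]]:
    """Partition reads into (kept, discarded-with-reason).

    Per-read rules: N rate <= max_n_rate and low-quality-base rate
    (quality < lowqual_base_q) <= max_lowqual_rate.  The adaptor rule is a
    batch property (fraction of adaptor-flagged reads <= max_adaptor_rate);
    when the batch exceeds it, adaptor-flagged reads are discarded with
    reason ``adaptor``.  Reason codes name the first failed rule.
    """
    t = thresholds or QcThresholds()
    reads = list(reads)
    n_flagged = sum(bool(r.adaptor_flag) for r in reads)
    adaptor_excess = bool(reads) and (n_flagged / len(reads)) > t.max_adaptor_rate
    kept: list[ReadRecord] = []
    discarded: list[tuple[ReadRecord, str]] = []
    for r in reads:
        if adaptor_excess and r.adaptor_flag:
            discarded.append((r, "adaptor"))
        elif r.n_rate > t.max_n_rate:
            discarded.append((r, "n_rate"))
        elif r.lowqual_rate(t.lowqual_base_q) > t.max_lowqual_rate:
            discarded.append((r, "lowqual_rate"))
        else:
            kept.append(r)
    return kept, discarded


def check_sample(
    mean_depth: float,
    mapping_rate: float,
    mismatch_rate: float,
    mode: str,
    thresholds: QcThresholds | None = None,
) -> dict:
    """Sample-level gate: depth (by assay mode), mapping rate, mismatch rate."""
    t = thresholds or QcThresholds()
    if mode == "wgs":
        min_depth = t.min_depth_wgs
    elif mode == "wes":
        min_depth = t.min_depth_wes
    else:
        raise ValueError(f"unknown sequencing mode {mode!r} (expected 'wgs' or 'wes')")
    flags = {
        "depth": mean_depth >= min_depth,
        "mapping_rate": mapping_rate >= t.min_mapping_rate,
        "mismatch_rate": mismatch_rate <= t.max_mismatch_rate,
    }
    flags["overall"] = all(flags.values())
    return flags
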