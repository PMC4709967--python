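"""GISTIC-style recurrent copy-number significance on absolute-CN segments.

Per-sample absolute copy-number segments (diploid = 2) are projected onto
fixed 1-kb marker windows, gains/losses are called by inclusive thresholds
(CN <= 1.5 deletion, CN >= 2.5 amplification), and each marker receives an
amplification and a deletion G-score combining alteration frequency with
mean amplitude.  Significance comes from a permutation null built by
independent per-sample circular shifts of each sample's marker vector,
which breaks marker-sample association while preserving within-sample
segment autocorrelation.  A marker is significant when its G-score exceeds
the cutoff AND its empirical permutation p is below alpha; adjacent
significant markers merge into regions.

With k of N samples altered at a marker and amplitudes a_i = |CN_i - 2|
over the altered samples,

    G = (k / N) * mean(a_i)  =  sum(a_i) / N,

i.e. frequency times mean amplitude among altered samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DELETION = "deletion"
NEUTRAL = "neutral"
AMPLIFICATION = "amplification"


@dataclass(frozen=True)
class CnSegment:
    """0-based half-open genomic interval carrying one absolute copy number."""

    chrom: str
    start: int
    end: int
    copy_number: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"malformed segment {self.chrom}:{self.start}-{self.end}"
            )
        if self.copy_number < 0:
            raise ValueError("copy number must be non-negative")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CnvParams:
    del_threshold: float = 1.5
    amp_threshold: float = 2.5
    marker_window_bp: int = 1000
    gscore_cutoff: float = 0.1
    perm_alpha: float = 0.05
    n_permutations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.del_threshold < 2.0 < self.amp_threshold:
            raise ValueError("thresholds must bracket the diploid value 2")
        if self.marker_window_bp < 1:
            raise ValueError("marker window must be >= 1 bp")


def call_gain_loss(copy_number: float, params: CnvParams | None = None) -> str:
    """Inclusive-threshold call: CN <= 1.5 deletion, CN >= 2.5 amplification."""
    p = params or CnvParams()
    if copy_number <= p.del_threshold:
        return DELETION
    if copy_number >= p.amp_threshold:
        return AMPLIFICATION
    return NEUTRAL


def gene_copy_number(
    segments_by_sample: Mapping[str, Sequence[CnSegment]],
    gene_models: pd.DataFrame,
) -> pd.DataFrame:
    """Overlap-length-weighted mean copy number of each gene in each sample.

    ``gene_models`` needs columns gene, chrom, start, end (0-based
    half-open).  Genes with no covering segment in a sample get NaN.
    """
    bad = gene_models[gene_models["start"] >= gene_models["end"]]
    if len(bad):
        raise ValueError(f"malformed gene intervals: {bad['gene'].tolist()}")
    out = pd.DataFrame(
        np.nan, index=gene_models["gene"], columns=list(segments_by_sample)
    )
    for sample, segments in segments_by_sample.items():
        for row in gene_models.itertuples(index=False):
            wsum = 0.0
            cov = 0
            for seg in segments:
                if seg.chrom != row.chrom:
                    continue
                ov = min(seg.end, row.end) - max(seg.start, row.start)
                if ov > 0:
                    wsum += ov * seg.copy_number
                    cov += ov
            if cov > 0:
                out.loc[row.gene, sample] = wsum / cov
    return out


def make_marker_matrix(
    segments_by_sample: Mapping[str, Sequence[CnSegment]],
    genome: Sequence[tuple[str, int]],
    window_bp: int = 1000,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Project segments onto fixed windows -> (markers x samples matrix, marker table).

    Each window's value is the bp-weighted mean CN over it; bp not covered
    by any segment contribute the neutral value 2 (so fully uncovered
    windows are exactly 2).  Trailing partial windows are kept.
    """
    if not genome or any(length <= 0 for _, length in genome):
        raise ValueError("genome must list chromosomes with positive lengths")
    rows = []
    offsets = {}
    for chrom, length in genome:
        n_win = -(-length // window_bp)  # ceil
        offsets[chrom] = (len(rows), n_win, length)
        for w in range(n_win):
            rows.append((chrom, w * window_bp, min((w + 1) * window_bp, length)))
    marker_table = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    win_len = (marker_table["end"] - marker_table["start"]).to_numpy(float)
    samples = list(segments_by_sample)
    X = np.empty((len(rows), len(samples)))
    for j, sample in enumerate(samples):
        acc = np.zeros(len(rows))  # sum of overlap_bp * CN
        cov = np.zeros(len(rows))  # covered bp
        for seg in segments_by_sample[sample]:
            if seg.chrom not in offsets:
                continue
            base, n_win, chrom_len = offsets[seg.chrom]
            s, e = seg.start, min(seg.end, chrom_len)
            if s >= e:
                continue
            w0, w1 = s // window_bp, (e - 1) // window_bp
            for w in range(w0, w1 + 1):
                ws, we = w * window_bp, min((w + 1) * window_bp, chrom_len)
                ov = min(e, we) - max(s, ws)
                acc[base + w] += ov * seg.copy_number
                cov[base + w] += ov
        X[:, j] = (acc + (win_len - cov) * 2.0) / win_len
    return X, marker_table


def gscore(
    marker_matrix: np.ndarray, params: CnvParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-marker amplification and deletion G-scores."""
    p = params or CnvParams()
    X = np.asarray(marker_matrix, dtype=float)
    if X.size == 0:
        raise ValueError("empty marker matrix")
    n = X.shape[1]
    amp = np.where(X >= p.amp_threshold, np.maximum(X - 2.0, 0.0), 0.0)
    dele = np.where(X <= p.del_threshold, np.maximum(2.0 - X, 0.0), 0.0)
    return amp.sum(axis=1) / n, dele.sum(axis=1) / n


def permutation_null(
    marker_matrix: np.ndarray,
    params: CnvParams | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical per-marker p-values for the amp and del G-scores.

    Null: each sample's marker vector is circularly shifted by an
    independent uniform offset each permutation.  p = (1 + #{null G >=
    observed G}) / (1 + n_permutations), so p is never zero.
    """
    p = params or CnvParams()
    if p.n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    X = np.asarray(marker_matrix, dtype=float)
    m, n = X.shape
    if rng is None:
        rng = np.random.default_rng(p.seed)
    g_amp, g_del = gscore(X, p)
    ge_amp = np.zeros(m, dtype=np.int64)
    ge_del = np.zeros(m, dtype=np.int64)
    rows = np.arange(m)[:, None]
    for _ in range(p.n_permutations):
        shifts = rng.integers(0, m, size=n)
        Xp = X[(rows - shifts[None, :]) % m, np.arange(n)[None, :]]
        na, nd = gscore(Xp, p)
        ge_amp += na >= g_amp
        ge_del += nd >= g_del
    p_amp = (1.0 + ge_amp) / (1.0 + p.n_permutations)
    p_del = (1.0 + ge_del) / (1.0 + p.n_permutations)
    return p_amp, p_del


def gscore_track(
    marker_matrix: np.ndarray,
    marker_table: pd.DataFrame,
    params: CnvParams | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Full per-marker track: G-scores, permutation p, significance flags."""
    p = params or CnvParams()
    g_amp, g_del = gscore(marker_matrix, p)
    p_amp, p_del = permutation_null(marker_matrix, p, rng)
    track = marker_table.copy()
    track["g_amp"] = g_amp
    track["g_del"] = g_del
    track["p_amp"] = p_amp
    track["p_del"] = p_del
    track["sig_amp"] = (g_amp > p.gscore_cutoff) & (p_amp < p.perm_alpha)
    track["sig_del"] = (g_del > p.gscore_cutoff) & (p_del < p.perm_alpha)
    return track


def significant_regions(track: pd.DataFrame, direction: str) -> pd.DataFrame:
    """Merge runs of adjacent significant markers into regions with a peak.

    direction 'amp' or 'del'.  Returns chrom, start, end, peak_start,
    peak_end, peak_g per merged region.
    """
    if direction not in ("amp", "del"):
        raise ValueError(f"direction must be 'amp' or 'del', got {direction!r}")
    sig_col, g_col = f"sig_{direction}", f"g_{direction}"
    regions = []
    for chrom, sub in track.groupby("chrom", sort=False):
        sub = sub.sort_values("start").reset_index(drop=True)
        run: list[int] = []
        for i in range(len(sub) + 1):
            in_run = i < len(sub) and bool(sub.loc[i, sig_col])
            contiguous = bool(run) and i < len(sub) and (
                sub.loc[i, "start"] == sub.loc[run[-1], "end"]
            )
            if in_run and (not run or contiguous):
                run.append(i)
                continue
            if run:
                block = sub.loc[run]
                peak = block.loc[block[g_col].idxmax()]
                regions.append(
                    (chrom, int(block["start"].min()), int(block["end"].max()),
                     int(peak["start"]), int(peak["end"]), float(peak[g_col]))
                )
                run = []
            if in_run:
                run.append(i)
    return pd.DataFrame(
        regions,
        columns=["chrom", "start", "end", "peak_start", "peak_end", "peak_g"],
    )


def scna_burden(
    segments: Sequence[CnSegment], params: CnvParams | None = None
) -> float:
    """Fraction of assayed bp called deleted or amplified (length-weighted)."""
    p = params or CnvParams()
    total = sum(s.length for s in segments)
    if total == 0:
        return 0.0
    altered = sum(
        s.length
        for s in segments
        if s.copy_number <= p.del_threshold or s.copy_number >= p.amp_threshold
    )
    return altered / total
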