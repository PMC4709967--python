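"""Seeded synthetic cohort generator for every pipeline input.

Emulates a two-stage squamous-carcinoma cohort (defaults: 51 stage I and
53 stage III tumors) with:

* a binary samples x genes non-silent mutation matrix with planted
  stage-biased genes (default: one gene mutated in 35 % of stage I vs 8 %
  of stage III samples) over a Bernoulli background;
* per-sample absolute copy-number segments around the diploid value with
  Gaussian jitter, plus planted recurrent amplification/deletion regions
  carried by a configurable fraction of samples of the biased stage;
* tumor/normal per-read evidence at candidate SNV loci drawn from six site
  classes — one clean somatic class built to satisfy all nine filtering
  criteria, and five contaminant classes each built to violate a specific
  criterion (germline, sub-threshold VAF, strand bias, read-end clustering,
  low base quality);
* qPCR Ct tables consistent with each sample's simulated copy number under
  the comparative-Ct model, in triplicate, with a diploid calibrator;
* raw read records (bases + Phred qualities) for the lane/read QC gates.

All randomness flows from the single config seed through named substreams,
so identical (config, seed) reproduces identical outputs.  The generative
distributions are modelling choices of this package (negative-binomial
depths, discrete Illumina-like quality ranges); no claim is made that they
reproduce any particular instrument.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort_stats import CohortMatrix
from .cnv_gscore import CnSegment
from .readqc import ReadRecord
from .snv_filter import ReadObservation, SiteEvidence

SITE_CLASSES = (
    "clean_somatic", "germline", "low_vaf",
    "strand_artifact", "readend_artifact", "lowqual_artifact",
)


@dataclass(frozen=True)
class PlantedRegion:
    """Recurrent copy-number region planted in a fraction of one stage."""

    chrom: str
    start: int
    end: int
    mean_cn: float
    stage_bias: str  # 'stage1', 'stage3' or 'both'
    carrier_fraction: float = 0.4


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_stage1: int = 51
    n_stage3: int = 53
    genome: tuple[tuple[str, int], ...] = (("chr1", 500_000), ("chr2", 500_000))
    n_genes: int = 200
    planted_genes: tuple[tuple[str, float, float], ...] = (
        ("NOTCH1", 0.35, 0.08),
    )
    background_rate: float = 0.02
    planted_cnv_regions: tuple[PlantedRegion, ...] = (
        PlantedRegion("chr1", 100_000, 200_000, 3.2, "stage1"),
        PlantedRegion("chr2", 300_000, 400_000, 0.8, "stage3"),
    )
    site_class_mix: tuple[float, ...] = (1 / 6,) * 6
    n_sites: int = 120
    depth_mean: float = 100.0
    depth_dispersion: float = 25.0  # negative-binomial size parameter
    read_length: int = 100
    segment_bp: int = 25_000
    segment_noise_sd: float = 0.15

    def __post_init__(self) -> None:
        if not self.genome:
            raise ValueError("genome must list at least one chromosome")
        if any(length <= 0 for _, length in self.genome):
            raise ValueError("chromosome lengths must be positive")
        if len(self.site_class_mix) != len(SITE_CLASSES):
            raise ValueError(
                f"site_class_mix needs {len(SITE_CLASSES)} proportions"
            )
        if any(p < 0 for p in self.site_class_mix) or abs(
            sum(self.site_class_mix) - 1.0
        ) > 1e-9:
            raise ValueError("site class proportions must be >= 0 and sum to 1")
        for gene, r1, r3 in self.planted_genes:
            if not (0 <= r1 <= 1 and 0 <= r3 <= 1):
                raise ValueError(f"planted rates for {gene!r} outside [0, 1]")
        if not 0 <= self.background_rate <= 1:
            raise ValueError("background_rate outside [0, 1]")
        for r in self.planted_cnv_regions:
            if r.stage_bias not in ("stage1", "stage3", "both"):
                raise ValueError(f"unknown stage bias {r.stage_bias!r}")
            if not 0 <= r.carrier_fraction <= 1:
                raise ValueError("carrier_fraction outside [0, 1]")


@dataclass(frozen=True)
class LabeledSite:
    """A SiteEvidence payload with its ground-truth generating class."""

    site: SiteEvidence
    truth_class: str


@dataclass
class SimulatedCohort:
    cohort: CohortMatrix
    segments_by_sample: dict[str, list[CnSegment]]
    labeled_sites: list[LabeledSite]
    ct_table: pd.DataFrame
    reads: list[ReadRecord]
    config: SimConfig


# ---------------------------------------------------------------------------
# per-read evidence


def _depth(rng: np.random.Generator, cfg: SimConfig, floor: int = 15) -> int:
    r = cfg.depth_dispersion
    d = rng.negative_binomial(r, r / (r + cfg.depth_mean))
    return max(floor, int(d))


def _stratified_offsets(rng: np.random.Generator, k: int, L: int) -> list[int]:
    """k offsets evenly spread over [0, L) with within-stratum jitter.

    High-depth loci are tiled nearly evenly by read starts; stratified
    sampling keeps the uniform marginal while avoiding the chance end
    clustering that i.i.d. draws produce at small k.
    """
    off = np.floor((np.arange(k) + rng.random(k)) * L / k).astype(int)
    rng.shuffle(off)
    return off.tolist()


def _obs(
    rng: np.random.Generator,
    allele: str,
    cfg: SimConfig,
    mapq_lo: int = 50,
    mapq_hi: int = 60,
    baseq_lo: int = 33,
    baseq_hi: int = 41,
    end_biased: bool = False,
    strand: str | None = None,
    offset5: int | None = None,
) -> ReadObservation:
    L = cfg.read_length
    if offset5 is not None:
        off = offset5
    elif end_biased:
        edge = int(rng.integers(0, 6))
        off = edge if rng.random() < 0.5 else L - 1 - edge
    else:
        off = int(rng.integers(0, L))
    return ReadObservation(
        allele=allele,
        mapq=int(rng.integers(mapq_lo, mapq_hi + 1)),
        baseq=int(rng.integers(baseq_lo, baseq_hi + 1)),
        offset5=off,
        read_length=L,
        strand=strand if strand is not None else ("+" if rng.random() < 0.5 else "-"),
    )


def simulate_site_evidence(
    site_class: str,
    config: SimConfig | None = None,
    rng: np.random.Generator | None = None,
    chrom: str = "chr1",
    pos: int = 1000,
) -> LabeledSite:
    """Draw tumor/normal per-read evidence for one site of the given class.

    ``clean_somatic`` is built to satisfy all nine filtering criteria; each
    contaminant class is built to violate its target criterion (germline ->
    normal VAF, low_vaf -> tumor VAF, strand_artifact -> strand Fisher,
    readend_artifact -> end-distance rank-sum, lowqual_artifact -> base
    quality).
    """
    if site_class not in SITE_CLASSES:
        raise ValueError(f"unknown site class {site_class!r}")
    cfg = config or SimConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)

    td = _depth(rng, cfg)
    nd = _depth(rng, cfg)
    t_obs: list[ReadObservation] = []
    n_obs: list[ReadObservation] = []

    def fill(obs, n, allele, **kw):
        for _ in range(n):
            obs.append(_obs(rng, allele, cfg, **kw))

    if site_class == "clean_somatic":
        vaf = rng.uniform(0.2, 0.4)
        k = max(3, int(np.ceil(0.10 * td)), int(rng.binomial(td, vaf)))
        for off in _stratified_offsets(rng, k, cfg.read_length):
            t_obs.append(_obs(rng, "alt", cfg, offset5=off))
        for off in _stratified_offsets(rng, td - k, cfg.read_length):
            t_obs.append(_obs(rng, "ref", cfg, offset5=off))
        fill(n_obs, nd, "ref")
    elif site_class == "germline":
        vaf = rng.uniform(0.35, 0.65)
        kt = int(rng.binomial(td, vaf))
        kn = max(int(rng.binomial(nd, vaf)), int(np.ceil(0.02 * nd)))
        fill(t_obs, kt, "alt")
        fill(t_obs, td - kt, "ref")
        fill(n_obs, kn, "alt")
        fill(n_obs, nd - kn, "ref")
    elif site_class == "low_vaf":
        vaf = rng.uniform(0.03, 0.08)
        cap = int(np.ceil(0.10 * td)) - 1
        k = min(max(1, int(rng.binomial(td, vaf))), max(1, cap))
        fill(t_obs, k, "alt")
        fill(t_obs, td - k, "ref")
        fill(n_obs, nd, "ref")
    elif site_class == "strand_artifact":
        td = max(td, 80)
        vaf = rng.uniform(0.3, 0.5)
        k = max(15, int(rng.binomial(td, vaf)))
        one_strand = "+" if rng.random() < 0.5 else "-"
        fill(t_obs, k, "alt", strand=one_strand)
        fill(t_obs, td - k, "ref")
        fill(n_obs, nd, "ref")
    elif site_class == "readend_artifact":
        td = max(td, 40)
        vaf = rng.uniform(0.2, 0.4)
        k = max(8, int(rng.binomial(td, vaf)))
        fill(t_obs, k, "alt", end_biased=True)
        fill(t_obs, td - k, "ref")
        fill(n_obs, nd, "ref")
    else:  # lowqual_artifact
        vaf = rng.uniform(0.2, 0.4)
        k = max(3, int(rng.binomial(td, vaf)))
        fill(t_obs, k, "alt", baseq_lo=5, baseq_hi=18)
        fill(t_obs, td - k, "ref")
        fill(n_obs, nd, "ref")

    site = SiteEvidence(
        chrom=chrom, pos=pos, ref="C", alt="T",
        tumor_obs=tuple(t_obs), normal_obs=tuple(n_obs),
    )
    return LabeledSite(site=site, truth_class=site_class)


def simulate_labeled_sites(
    config: SimConfig, rng: np.random.Generator
) -> list[LabeledSite]:
    """Draw config.n_sites sites per the class mix, at well-separated loci."""
    classes = rng.choice(
        len(SITE_CLASSES), size=config.n_sites, p=np.asarray(config.site_class_mix)
    )
    sites = []
    for i, ci in enumerate(classes):
        sites.append(
            simulate_site_evidence(
                SITE_CLASSES[ci], config, rng, chrom="chr1", pos=1000 * (i + 1)
            )
        )
    return sites


# ---------------------------------------------------------------------------
# cohort-level structures


def _sample_names(cfg: SimConfig) -> tuple[list[str], list[str]]:
    s1 = [f"S1-{i + 1:03d}" for i in range(cfg.n_stage1)]
    s3 = [f"S3-{i + 1:03d}" for i in range(cfg.n_stage3)]
    return s1, s3


def simulate_mutation_matrix(
    config: SimConfig, rng: np.random.Generator
) -> CohortMatrix:
    s1, s3 = _sample_names(config)
    samples = s1 + s3
    planted = {g: (r1, r3) for g, r1, r3 in config.planted_genes}
    genes = list(planted) + [
        f"gene_{i + 1:04d}" for i in range(config.n_genes - len(planted))
    ]
    X = (rng.random((len(samples), len(genes))) < config.background_rate).astype(int)
    mat = pd.DataFrame(X, index=samples, columns=genes)
    for g, (r1, r3) in planted.items():
        mat.loc[s1, g] = (rng.random(len(s1)) < r1).astype(int)
        mat.loc[s3, g] = (rng.random(len(s3)) < r3).astype(int)
    stage = pd.Series(["I"] * len(s1) + ["III"] * len(s3), index=samples)
    return CohortMatrix(mutations=mat, stage=stage)


def simulate_segments(
    config: SimConfig, rng: np.random.Generator
) -> dict[str, list[CnSegment]]:
    """Per-sample segments: diploid baseline with jitter plus planted regions."""
    s1, s3 = _sample_names(config)
    carriers: dict[int, set[str]] = {}
    for ri, region in enumerate(config.planted_cnv_regions):
        pool = {"stage1": s1, "stage3": s3, "both": s1 + s3}[region.stage_bias]
        n_carry = int(round(region.carrier_fraction * len(pool)))
        carriers[ri] = set(rng.choice(pool, size=n_carry, replace=False))
    out: dict[str, list[CnSegment]] = {}
    for sample in s1 + s3:
        segs: list[CnSegment] = []
        for chrom, length in config.genome:
            pos = 0
            while pos < length:
                end = min(pos + config.segment_bp, length)
                mean = 2.0
                for ri, region in enumerate(config.planted_cnv_regions):
                    if (
                        region.chrom == chrom
                        and sample in carriers[ri]
                        and pos < region.end
                        and end > region.start
                    ):
                        mean = region.mean_cn
                cn = max(0.0, mean + rng.normal(0.0, config.segment_noise_sd))
                segs.append(CnSegment(chrom, pos, end, cn))
                pos = end
        out[sample] = segs
    return out


def simulate_ct_table(
    config: SimConfig,
    segments_by_sample: dict[str, list[CnSegment]],
    rng: np.random.Generator,
    genes: Sequence[tuple[str, str, int, int]] | None = None,
    replicates: int = 3,
    ct_noise_sd: float = 0.05,
) -> pd.DataFrame:
    """Ct table consistent with each sample's simulated CN under the ddCt model.

    ``genes``: (gene, chrom, start, end) assay loci; defaults to the
    midpoints of the planted regions.  The calibrator sample 'CAL' is
    diploid.  Reference assay is the diploid control 'RNaseP'.
    """
    if genes is None:
        genes = [
            (f"assay_{r.chrom}_{r.start}", r.chrom, r.start, r.end)
            for r in config.planted_cnv_regions
        ]
    dct_base = {g: rng.uniform(1.0, 3.0) for g, _, _, _ in genes}
    rows = []

    def true_cn(sample: str, chrom: str, start: int, end: int) -> float:
        if sample == "CAL":
            return 2.0
        wsum = cov = 0.0
        for seg in segments_by_sample[sample]:
            if seg.chrom != chrom:
                continue
            ov = min(seg.end, end) - max(seg.start, start)
            if ov > 0:
                wsum += ov * seg.copy_number
                cov += ov
        return wsum / cov if cov else 2.0

    for sample in ["CAL"] + list(segments_by_sample):
        ct_ref = rng.uniform(24.0, 26.0)
        for rep in range(replicates):
            rows.append(
                {"sample": sample, "gene": "RNaseP", "role": "reference",
                 "ct": ct_ref + rng.normal(0, ct_noise_sd), "replicate": rep,
                 "calibrator": sample == "CAL"}
            )
        for g, chrom, start, end in genes:
            cn = max(true_cn(sample, chrom, start, end), 0.05)
            ct_t = ct_ref + dct_base[g] - np.log2(cn / 2.0)
            for rep in range(replicates):
                rows.append(
                    {"sample": sample, "gene": g, "role": "target",
                     "ct": ct_t + rng.normal(0, ct_noise_sd), "replicate": rep,
                     "calibrator": sample == "CAL"}
                )
    return pd.DataFrame(rows)


def simulate_reads(
    config: SimConfig,
    rng: np.random.Generator,
    n_reads: int = 200,
    mean_q: int = 36,
    n_read_fraction: float = 0.02,
    adaptor_fraction: float = 0.01,
) -> list[ReadRecord]:
    """Illumina-like read records (bases + Phred qualities) for the QC gates."""
    reads = []
    L = config.read_length
    for _ in range(n_reads):
        bases = rng.choice(list("ACGT"), size=L)
        quals = np.clip(rng.normal(mean_q, 3.0, size=L).round(), 2, 41).astype(int)
        if rng.random() < n_read_fraction:
            n_n = int(rng.integers(1, max(2, L // 5)))
            idx = rng.choice(L, size=n_n, replace=False)
            bases[idx] = "N"
        reads.append(
            ReadRecord(
                bases="".join(bases),
                quals=quals.tolist(),
                adaptor_flag=bool(rng.random() < adaptor_fraction),
            )
        )
    return reads


def simulate_cohort(config: SimConfig | None = None) -> SimulatedCohort:
    """Generate every pipeline input from one seeded configuration."""
    cfg = config or SimConfig()
    streams = np.random.SeedSequence(cfg.seed).spawn(5)
    rng_mut, rng_seg, rng_site, rng_ct, rng_read = (
        np.random.default_rng(s) for s in streams
    )
    cohort = simulate_mutation_matrix(cfg, rng_mut)
    segments = simulate_segments(cfg, rng_seg)
    sites = simulate_labeled_sites(cfg, rng_site)
    ct = simulate_ct_table(cfg, segments, rng_ct)
    reads = simulate_reads(cfg, rng_read)
    return SimulatedCohort(
        cohort=cohort,
        segments_by_sample=segments,
        labeled_sites=sites,
        ct_table=ct,
        reads=reads,
        config=cfg,
    )
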