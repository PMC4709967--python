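"""Readers/writers for the pipeline's on-disk formats, plus the pipeline driver.

Coordinate conventions: VCF positions are 1-based; segment/gene BED-like
TSVs are 0-based half-open.  All tables are plain TSV.  Results go to
stdout/files; logging goes to standard error with stage-scoped prefixes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml

from .cnv_gscore import CnSegment, CnvParams, gscore_track, scna_burden, significant_regions
from .cohort_stats import (
    CohortMatrix,
    LandscapeParams,
    PathwayDb,
    compare_burden,
    gene_frequency_table,
    stage_association_family,
)
from .qpcr_cn import cohort_cn_table
from .readqc import QcThresholds, ReadRecord, check_lane, compute_lane_metrics, filter_reads
from .simulate import SimConfig, simulate_cohort
from .snv_filter import (
    CRITERION_NAMES,
    FilterVerdict,
    ReadObservation,
    SiteEvidence,
    SnvFilterThresholds,
    filter_cohort,
)


class ConfigError(ValueError):
    """Invalid configuration; CLI exit code 2."""


class DataError(ValueError):
    """Malformed input data; CLI exit code 1."""


def get_logger(stage: str) -> logging.Logger:
    logger = logging.getLogger(f"esccpipe.{stage}")
    if not logger.handlers:
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter(f"[{stage}] %(levelname)s %(message)s"))
        logger.addHandler(h)
        logger.setLevel(logging.INFO)
        logger.propagate = False
    return logger


# ---------------------------------------------------------------------------
# VCF


def _vcf_header(contigs: Sequence[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for c in contigs:
        header.add_line(f"##contig=<ID={c}>")
    for name in CRITERION_NAMES:
        header.add_line(
            f'##FILTER=<ID=fail_{name},Description="Failed criterion {name}">'
        )
    header.add_line(
        '##INFO=<ID=TVAF,Number=1,Type=Float,Description="Tumor variant allele frequency">'
    )
    header.add_line(
        '##INFO=<ID=NVAF,Number=1,Type=Float,Description="Normal variant allele frequency">'
    )
    return header


def write_sites_vcf(
    path: str | Path,
    sites: Sequence[SiteEvidence],
    verdicts: Sequence[FilterVerdict] | None = None,
) -> None:
    """Minimal VCF 4.2: FILTER is PASS or the first failed criterion."""
    contigs = sorted({s.chrom for s in sites})
    header = _vcf_header(contigs)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for i, s in enumerate(sites):
            rec = vcf.new_record(
                contig=s.chrom, start=s.pos - 1, alleles=(s.ref, s.alt)
            )
            rec.info["TVAF"] = float(s.tumor_vaf)
            rec.info["NVAF"] = float(s.normal_vaf)
            if verdicts is not None:
                failed = verdicts[i].failed()
                rec.filter.add(f"fail_{failed[0]}" if failed else "PASS")
            vcf.write(rec)


def read_sites_vcf(path: str | Path) -> pd.DataFrame:
    """Site table (chrom, pos, ref, alt, filter) from a VCF 4.2 file.

    A light pre-scan validates the body lines so a corrupted line aborts
    with its line number.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8 or not fields[1].isdigit():
                raise DataError(f"{path}: malformed VCF record at line {lineno}")
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            rows.append(
                {
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alts[0] if rec.alts else ".",
                    "filter": ";".join(rec.filter.keys()) or ".",
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "filter"])


# ---------------------------------------------------------------------------
# evidence / segments / metadata / Ct TSVs

EVIDENCE_COLUMNS = (
    "chrom", "pos", "ref", "alt", "role", "allele",
    "mapq", "baseq", "offset5", "read_length", "strand",
)


def write_evidence_tsv(path: str | Path, sites: Sequence[SiteEvidence]) -> None:
    rows = []
    for s in sites:
        for role, obs in (("tumor", s.tumor_obs), ("normal", s.normal_obs)):
            for o in obs:
                rows.append(
                    (s.chrom, s.pos, s.ref, s.alt, role, o.allele,
                     o.mapq, o.baseq, o.offset5, o.read_length, o.strand)
                )
    pd.DataFrame(rows, columns=EVIDENCE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_evidence_tsv(path: str | Path) -> list[SiteEvidence]:
    df = pd.read_csv(path, sep="\t")
    missing = set(EVIDENCE_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"{path}: evidence TSV missing columns {sorted(missing)}")
    sites = []
    for (chrom, pos, ref, alt), grp in df.groupby(
        ["chrom", "pos", "ref", "alt"], sort=True
    ):
        obs = {"tumor": [], "normal": []}
        for row in grp.itertuples(index=False):
            obs[row.role].append(
                ReadObservation(
                    allele=row.allele, mapq=int(row.mapq), baseq=int(row.baseq),
                    offset5=int(row.offset5), read_length=int(row.read_length),
                    strand=row.strand,
                )
            )
        sites.append(
            SiteEvidence(
                chrom=str(chrom), pos=int(pos), ref=str(ref), alt=str(alt),
                tumor_obs=tuple(obs["tumor"]), normal_obs=tuple(obs["normal"]),
            )
        )
    return sites


def write_segments_tsv(
    path: str | Path, segments_by_sample: Mapping[str, Sequence[CnSegment]]
) -> None:
    rows = [
        (sample, s.chrom, s.start, s.end, s.copy_number)
        for sample, segs in segments_by_sample.items()
        for s in segs
    ]
    pd.DataFrame(
        rows, columns=["sample", "chrom", "start", "end", "copy_number"]
    ).to_csv(path, sep="\t", index=False)


def read_segments_tsv(path: str | Path) -> dict[str, list[CnSegment]]:
    # round_trip float parsing so write->read is the identity on the model
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    out: dict[str, list[CnSegment]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.sample), []).append(
            CnSegment(str(row.chrom), int(row.start), int(row.end), float(row.copy_number))
        )
    return out


def write_matrix_tsv(path: str | Path, cohort: CohortMatrix) -> None:
    df = cohort.mutations.copy()
    df.insert(0, "stage", cohort.stage)
    df.to_csv(path, sep="\t", index_label="sample")


def read_matrix_tsv(path: str | Path) -> CohortMatrix:
    df = pd.read_csv(path, sep="\t", index_col="sample")
    stage = df.pop("stage")
    return CohortMatrix(mutations=df.astype(int), stage=stage)


def read_maf_lite(path: str | Path, samples: Sequence[str], stage: pd.Series) -> CohortMatrix:
    """MAF-lite (sample, gene, effect) -> binary matrix; silent effects skipped."""
    df = pd.read_csv(path, sep="\t")
    df = df[df["effect"].str.lower() != "silent"]
    genes = sorted(df["gene"].unique())
    mat = pd.DataFrame(0, index=list(samples), columns=genes)
    for row in df.itertuples(index=False):
        if row.sample in mat.index:
            mat.loc[row.sample, row.gene] = 1
    return CohortMatrix(mutations=mat, stage=stage.reindex(mat.index))


def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> PathwayDb:
    """GMT pathway file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    pathways: dict[str, frozenset] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            pathways[fields[0]] = frozenset(g for g in fields[2:] if g)
    all_genes = frozenset().union(*pathways.values()) if pathways else frozenset()
    uni = frozenset(universe) | all_genes if universe else all_genes
    return PathwayDb(pathways=pathways, universe=uni)


def read_fastq(path: str | Path) -> list[ReadRecord]:
    """Sanger Phred+33 FASTQ -> ReadRecord list (uncompressed or gzip)."""
    reads = []
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            quals = entry.get_quality_array()
            reads.append(
                ReadRecord(bases=entry.sequence.upper(), quals=list(quals))
            )
    return reads


# ---------------------------------------------------------------------------
# pipeline config and driver


@dataclass
class PipelineConfig:
    outdir: Path
    seed: int = 0
    mode: str = "discovery"
    sim: SimConfig = field(default_factory=SimConfig)
    snv_thresholds: SnvFilterThresholds = field(default_factory=SnvFilterThresholds)
    qc_thresholds: QcThresholds = field(default_factory=QcThresholds)
    cnv_params: CnvParams = field(default_factory=CnvParams)
    landscape_params: LandscapeParams = field(default_factory=LandscapeParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
            kwargs: dict = {"outdir": Path(raw.get("outdir", "pipeline_out"))}
            if "seed" in raw:
                kwargs["seed"] = int(raw["seed"])
            if "mode" in raw:
                kwargs["mode"] = str(raw["mode"])
            for key, klass in (
                ("sim", SimConfig),
                ("snv_thresholds", SnvFilterThresholds),
                ("qc_thresholds", QcThresholds),
                ("cnv_params", CnvParams),
                ("landscape_params", LandscapeParams),
            ):
                if key in raw:
                    kwargs[key] = klass(**raw[key])
            return cls(**kwargs)
        except (TypeError, ValueError, yaml.YAMLError) as exc:
            raise ConfigError(f"invalid pipeline config {path}: {exc}") from exc


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate a cohort and run every stage, writing outputs plus a manifest.

    Stage order: simulate -> read/lane QC -> SNV filtering -> copy-number
    G-scoring and burden -> qPCR CN -> cohort statistics.  Rerunning with
    the same config is byte-identical.
    """
    log = get_logger("pipeline")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim_cfg = config.sim
    if sim_cfg.seed != config.seed:
        from dataclasses import replace

        sim_cfg = replace(sim_cfg, seed=config.seed)

    log.info("simulating cohort (seed=%d)", config.seed)
    sim = simulate_cohort(sim_cfg)
    write_matrix_tsv(out / "mutation_matrix.tsv", sim.cohort)
    write_segments_tsv(out / "segments.tsv", sim.segments_by_sample)
    write_evidence_tsv(out / "evidence.tsv", [ls.site for ls in sim.labeled_sites])
    sim.ct_table.to_csv(out / "ct_table.tsv", sep="\t", index=False)

    log.info("read/lane QC on %d reads", len(sim.reads))
    metrics = compute_lane_metrics(sim.reads)
    lane_flags = check_lane(metrics, config.qc_thresholds)
    kept, discarded = filter_reads(sim.reads, config.qc_thresholds)
    qc_summary = {
        "lane": {k: bool(v) for k, v in lane_flags.items()},
        "reads_kept": len(kept),
        "reads_discarded": len(discarded),
    }

    log.info("SNV filtering %d candidate sites", len(sim.labeled_sites))
    sites = [ls.site for ls in sim.labeled_sites]
    passing, verdicts = filter_cohort(sites, config.snv_thresholds, config.mode)
    write_sites_vcf(out / "sites.vcf", sites, verdicts)
    verdict_rows = []
    for ls, v in zip(sim.labeled_sites, verdicts):
        row = {"chrom": ls.site.chrom, "pos": ls.site.pos,
               "truth_class": ls.truth_class, "pass": v.overall}
        row.update({f"c_{k}": v.flags.get(k) for k in CRITERION_NAMES})
        row.update({f"p_{k}": v.pvalues.get(k) for k in
                    ("mapq", "baseq", "read_end", "vaf_contrast", "strand_bias")})
        verdict_rows.append(row)
    pd.DataFrame(verdict_rows).to_csv(out / "snv_verdicts.tsv", sep="\t", index=False)

    log.info("copy-number G-scores over %d samples", len(sim.segments_by_sample))
    from .cnv_gscore import make_marker_matrix

    X, marker_table = make_marker_matrix(
        sim.segments_by_sample, list(sim_cfg.genome), config.cnv_params.marker_window_bp
    )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    track = gscore_track(X, marker_table, config.cnv_params, rng)
    track.to_csv(out / "gscore_track.tsv", sep="\t", index=False)
    regions = pd.concat(
        [
            significant_regions(track, "amp").assign(direction="amp"),
            significant_regions(track, "del").assign(direction="del"),
        ]
    )
    regions.to_csv(out / "significant_regions.tsv", sep="\t", index=False)

    burdens = {
        sample: scna_burden(segs, config.cnv_params)
        for sample, segs in sim.segments_by_sample.items()
    }
    b1 = [burdens[s] for s in sim.cohort.samples_in_stage("I")]
    b3 = [burdens[s] for s in sim.cohort.samples_in_stage("III")]
    burden_p, burden_dir = compare_burden(b1, b3)

    log.info("qPCR copy-number table")
    qpcr = cohort_cn_table(sim.ct_table, config.cnv_params)
    qpcr.to_csv(out / "qpcr_cn.tsv", sep="\t", index=False)

    log.info("cohort statistics")
    freq = gene_frequency_table(sim.cohort, config.landscape_params)
    freq.to_csv(out / "gene_frequency.tsv", sep="\t", index=False)
    planted = {g: g for g, _, _ in sim_cfg.planted_genes}
    stage_tests = stage_association_family(sim.cohort, planted, "greater")
    stage_tests.to_csv(out / "stage_tests.tsv", sep="\t", index=False)

    outputs = sorted(p for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "seed": config.seed,
        "mode": config.mode,
        "n_sites_pass": len(passing),
        "qc": qc_summary,
        "burden_p_stage3_gt_stage1": burden_p,
        "burden_direction": burden_dir,
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("wrote %d outputs to %s", len(outputs) + 1, out)
    return manifest
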