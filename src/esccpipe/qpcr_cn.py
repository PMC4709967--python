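"""Comparative-Ct (ddCt) copy-number quantification for qPCR validation.

Each sample is assayed for a target gene and a diploid reference gene
(RNase P in the original assays), in replicate (triplicate by default).
Replicate Ct values are averaged first; then

    dCt(s)  = mean Ct_target(s) - mean Ct_reference(s)
    ddCt(s) = dCt(s) - dCt(calibrator)
    CN(s)   = 2 * 2^(-ddCt(s))

with the calibrator assumed diploid, so CN(calibrator) = 2 exactly and CN
halves per unit of ddCt.  Amplification efficiency is fixed at 2.0 per
cycle (no efficiency correction).  An inferred CN below 0.3 is flagged as a
homozygous deletion.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cnv_gscore import CnvParams, call_gain_loss

HOMOZYGOUS_DELETION_CN = 0.3

CT_COLUMNS = ("sample", "gene", "role", "ct", "replicate", "calibrator")


def _validate(ct: pd.DataFrame) -> None:
    missing = set(CT_COLUMNS) - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if (ct["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    if not ct["calibrator"].any():
        raise ValueError("Ct table has no calibrator sample")


def _mean_ct(ct: pd.DataFrame, sample: str, gene: str, role: str) -> float:
    rows = ct[(ct["sample"] == sample) & (ct["gene"] == gene) & (ct["role"] == role)]
    if rows.empty:
        raise ValueError(f"no {role} Ct for gene {gene!r} in sample {sample!r}")
    return float(rows["ct"].mean())


def ddct_copy_number(ct: pd.DataFrame, target_gene: str, sample: str) -> float:
    """Inferred absolute copy number of ``target_gene`` in ``sample``."""
    _validate(ct)
    calibrators = ct.loc[ct["calibrator"], "sample"].unique()
    calibrator = str(calibrators[0])
    ref_gene = ct.loc[ct["role"] == "reference", "gene"]
    if ref_gene.empty:
        raise ValueError("Ct table has no reference assay")
    ref_gene = str(ref_gene.iloc[0])
    dct_s = _mean_ct(ct, sample, target_gene, "target") - _mean_ct(
        ct, sample, ref_gene, "reference"
    )
    dct_cal = _mean_ct(ct, calibrator, target_gene, "target") - _mean_ct(
        ct, calibrator, ref_gene, "reference"
    )
    ddct = dct_s - dct_cal
    return float(2.0 * 2.0 ** (-ddct))


def is_homozygous_deletion(copy_number: float) -> bool:
    """CN < 0.3 indicates loss of both copies."""
    return copy_number < HOMOZYGOUS_DELETION_CN


def cohort_cn_table(
    ct: pd.DataFrame,
    cnv_params: CnvParams | None = None,
) -> pd.DataFrame:
    """Per-gene, per-sample inferred CN with replicate spread and status calls.

    Returns one row per (gene, sample): mean and SD of the replicate Ct
    values for the target assay, inferred CN, the gain/loss status at the
    segment-calling thresholds, and the homozygous-deletion flag.
    """
    _validate(ct)
    p = cnv_params or CnvParams()
    targets = ct[ct["role"] == "target"]
    rows = []
    for (gene, sample), grp in targets.groupby(["gene", "sample"], sort=True):
        cn = ddct_copy_number(ct, str(gene), str(sample))
        rows.append(
            {
                "gene": gene,
                "sample": sample,
                "ct_mean": float(grp["ct"].mean()),
                "ct_sd": float(grp["ct"].std(ddof=1)) if len(grp) > 1 else 0.0,
                "n_replicates": int(len(grp)),
                "copy_number": cn,
                "status": call_gain_loss(cn, p),
                "homozygous_deletion": is_homozygous_deletion(cn),
            }
        )
    return pd.DataFrame(rows)
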