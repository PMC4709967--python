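"""Cohort-level mutation and copy-number statistics.

Operates on a binary samples x genes non-silent-mutation matrix with
per-sample tumor stage labels (AJCC stage I vs stage III, plus atypical
hyperplasia 'AH' for premalignant validation tissue):

* mutation-landscape frequency classes ("mountains" >= 10 % of samples,
  "hills" 5-10 %, low-frequency 2-5 %);
* printed-style percentage arithmetic (round-half-up);
* significantly-mutated-gene (SMG) combination summary;
* per-gene / per-gene-set stage association by Fisher's exact test with
  Benjamini-Hochberg correction across a feature family;
* hypergeometric pathway enrichment with Benjamini-Hochberg correction;
* stage comparison of per-sample SCNA burden by one-sided Wilcoxon
  rank-sum;
* six-class pyrimidine-folded substitution spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._rank import rank_sum_p

STAGE_I = "I"
STAGE_III = "III"
STAGE_AH = "AH"

MOUNTAIN = "mountain"
HILL = "hill"
LOW = "low"
UNCLASSIFIED = "unclassified"

SPECTRUM_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class CohortMatrix:
    """Binary non-silent mutation indicators plus stage labels.

    ``mutations``: DataFrame indexed by sample, one 0/1 column per gene
    (multiple mutations in a gene in one sample collapse to 1).
    ``stage``: Series indexed by sample with values I / III / AH.
    """

    mutations: pd.DataFrame
    stage: pd.Series
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        vals = self.mutations.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mutation matrix must be binary")
        if not self.mutations.index.equals(self.stage.index):
            self.stage = self.stage.reindex(self.mutations.index)
            if self.stage.isna().any():
                raise ValueError("every sample needs a stage label")

    def samples_in_stage(self, stage: str) -> pd.Index:
        return self.mutations.index[self.stage == stage]


@dataclass(frozen=True)
class PathwayDb:
    """Pathway id -> member gene set, with a background universe."""

    pathways: Mapping[str, frozenset]
    universe: frozenset

    def __post_init__(self) -> None:
        for pid, genes in self.pathways.items():
            if not genes <= self.universe:
                raise ValueError(f"pathway {pid!r} has genes outside the universe")


@dataclass(frozen=True)
class LandscapeParams:
    mountain_min: float = 0.10
    hill_band: tuple[float, float] = (0.05, 0.10)
    low_band: tuple[float, float] = (0.02, 0.05)

    def classify(self, frequency: float) -> str:
        if frequency >= self.mountain_min:
            return MOUNTAIN
        if self.hill_band[0] <= frequency < self.hill_band[1]:
            return HILL
        if self.low_band[0] <= frequency < self.low_band[1]:
            return LOW
        return UNCLASSIFIED


def fisher_exact_p(
    table: Sequence[Sequence[int]] | np.ndarray, alternative: str = "two-sided"
) -> float:
    """Fisher exact p on a 2x2 table; the single code path for all stage tests."""
    return float(stats.fisher_exact(np.asarray(table), alternative=alternative)[1])


def gene_frequency_table(
    matrix: CohortMatrix, params: LandscapeParams | None = None
) -> pd.DataFrame:
    """Per-gene mutated-sample count, cohort frequency, and landscape class."""
    p = params or LandscapeParams()
    n = len(matrix.mutations)
    counts = matrix.mutations.sum(axis=0)
    freq = counts / n
    return pd.DataFrame(
        {
            "gene": counts.index,
            "mutated_samples": counts.to_numpy(int),
            "frequency": freq.to_numpy(float),
            "class": [p.classify(f) for f in freq],
        }
    ).reset_index(drop=True)


def cohort_frequency(k: int, n: int, decimals: int = 0) -> float:
    """Percentage 100*k/n rounded half-up to ``decimals`` places."""
    if n <= 0:
        raise ValueError("cohort size must be positive")
    pct = Decimal(100 * k) / Decimal(n)
    q = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


def smg_combination_summary(
    matrix: CohortMatrix, smg_list: Sequence[str]
) -> dict:
    """Counts of samples carrying 0, 1, >= 2 SMGs and distinct SMG subsets."""
    present = [g for g in smg_list if g in matrix.mutations.columns]
    sub = matrix.mutations[present]
    per_sample = sub.sum(axis=1)
    combos = {
        frozenset(sub.columns[row.to_numpy(bool)])
        for _, row in sub.iterrows()
        if row.any()
    }
    return {
        "n_zero": int((per_sample == 0).sum()),
        "n_one": int((per_sample == 1).sum()),
        "n_two_plus": int((per_sample >= 2).sum()),
        "n_combinations": len(combos),
    }


def stage_association_test(
    matrix: CohortMatrix,
    feature: str | Iterable[str],
    alternative: str = "two-sided",
) -> tuple[np.ndarray, float, float]:
    """Fisher exact test of mutation prevalence, stage I vs stage III.

    ``feature`` is a gene or a gene set (a sample counts as mutated when any
    member is).  Table rows are (stage I, stage III), columns (mutated, not).
    ``alternative`` 'greater' tests stage-I enrichment, 'less' stage-III.
    Returns (table, odds ratio, p).
    """
    genes = [feature] if isinstance(feature, str) else list(feature)
    missing = [g for g in genes if g not in matrix.mutations.columns]
    if missing:
        raise KeyError(f"genes not in matrix: {missing}")
    hit = matrix.mutations[genes].any(axis=1)
    table = np.empty((2, 2), dtype=int)
    for i, stage in enumerate((STAGE_I, STAGE_III)):
        idx = matrix.samples_in_stage(stage)
        if len(idx) == 0:
            raise ValueError(f"no samples in stage {stage}")
        table[i, 0] = int(hit.loc[idx].sum())
        table[i, 1] = len(idx) - table[i, 0]
    odds = stats.fisher_exact(table, alternative=alternative)[0]
    return table, float(odds), fisher_exact_p(table, alternative)


def stage_association_family(
    matrix: CohortMatrix,
    features: Mapping[str, str | Iterable[str]],
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Stage tests over a feature family with BH-adjusted p-values."""
    rows = []
    for name, feature in features.items():
        table, odds, p = stage_association_test(matrix, feature, alternative)
        rows.append(
            {
                "feature": name,
                "stage1_mutated": table[0, 0],
                "stage1_total": table[0].sum(),
                "stage3_mutated": table[1, 0],
                "stage3_total": table[1].sum(),
                "odds_ratio": odds,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def pathway_enrichment(mutated_genes: Iterable[str], db: PathwayDb) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment per pathway, BH-corrected.

    With universe size M, pathway size K, and n mutated genes of which k
    overlap the pathway, p = P(X >= k) for X ~ Hypergeom(M, K, n).
    """
    mutated = frozenset(mutated_genes)
    if not mutated <= db.universe:
        raise ValueError("mutated genes must be a subset of the universe")
    M = len(db.universe)
    n = len(mutated)
    rows = []
    for pid, genes in db.pathways.items():
        K = len(genes)
        k = len(mutated & genes)
        p = float(stats.hypergeom.sf(k - 1, M, K, n))
        rows.append({"pathway": pid, "size": K, "overlap": k, "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def compare_burden(
    burdens_stage1: Sequence[float], burdens_stage3: Sequence[float]
) -> tuple[float, str]:
    """One-sided rank-sum p that stage III SCNA burden exceeds stage I.

    Exact conditional null for small groups, tie-corrected normal beyond.
    Returns (p, direction), direction by comparison of group means.
    """
    b1 = np.asarray(burdens_stage1, float)
    b3 = np.asarray(burdens_stage3, float)
    p = rank_sum_p(b3, b1, alternative="greater")
    if b3.mean() > b1.mean():
        direction = "stage3>stage1"
    elif b3.mean() < b1.mean():
        direction = "stage1>stage3"
    else:
        direction = "none"
    return p, direction


def mutation_spectrum(variants: Iterable[tuple[str, str]]) -> dict[str, int]:
    """Counts over the six pyrimidine-context substitution classes.

    Substitutions with a purine reference are folded onto the complementary
    pyrimidine strand (e.g. G>A counts as C>T).
    """
    counts = {c: 0 for c in SPECTRUM_CLASSES}
    for ref, alt in variants:
        ref, alt = ref.upper(), alt.upper()
        if ref in ("G", "A"):
            ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        key = f"{ref}>{alt}"
        if key not in counts:
            raise ValueError(f"not a single-nucleotide substitution: {ref}>{alt}")
        counts[key] += 1
    return counts
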