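"""Landscape classes, stage-association tests, enrichment, burden, spectrum."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from esccpipe.cohort_stats import (
    CohortMatrix,
    LandscapeParams,
    PathwayDb,
    cohort_frequency,
    compare_burden,
    gene_frequency_table,
    mutation_spectrum,
    pathway_enrichment,
    smg_combination_summary,
    stage_association_family,
    stage_association_test,
)

from oracles import bh_oracle, fisher_oracle, hypergeom_tail_oracle


def _matrix(data, stages):
    df = pd.DataFrame(data)
    return CohortMatrix(mutations=df, stage=pd.Series(stages, index=df.index))


def _two_stage_matrix(gene_hits_by_stage, n1, n3):
    """gene -> (hits in stage I, hits in stage III), deterministic layout."""
    samples = [f"a{i}" for i in range(n1)] + [f"b{i}" for i in range(n3)]
    stages = ["I"] * n1 + ["III"] * n3
    data = {}
    for gene, (k1, k3) in gene_hits_by_stage.items():
        data[gene] = [1] * k1 + [0] * (n1 - k1) + [1] * k3 + [0] * (n3 - k3)
    df = pd.DataFrame(data, index=samples)
    return CohortMatrix(mutations=df, stage=pd.Series(stages, index=samples))


class TestLandscape:
    def test_frequency_and_class_bands(self):
        mat = _matrix(
            {"g0": [0] * 20, "g_hill": [1] * 1 + [0] * 19,
             "g_mtn": [1, 1, 1] + [0] * 17},
            ["I"] * 10 + ["III"] * 10,
        )
        table = gene_frequency_table(mat).set_index("gene")
        assert table.loc["g0", "frequency"] == 0.0
        assert table.loc["g0", "class"] == "unclassified"
        assert table.loc["g_hill", "frequency"] == pytest.approx(0.05)
        assert table.loc["g_hill", "class"] == "hill"  # band edge inclusive
        assert table.loc["g_mtn", "frequency"] == pytest.approx(0.15)
        assert table.loc["g_mtn", "class"] == "mountain"

    def test_band_edges(self):
        p = LandscapeParams()
        assert p.classify(0.10) == "mountain"
        assert p.classify(0.05) == "hill"
        assert p.classify(0.02) == "low"
        assert p.classify(0.0199) == "unclassified"


class TestCohortFrequency:
    @pytest.mark.parametrize(
        "k,n,decimals,expected",
        [(22, 104, 0, 21.0), (6, 36, 1, 16.7), (46, 104, 0, 44.0),
         (8, 104, 0, 8.0), (0, 50, 2, 0.0), (1, 8, 0, 13.0)],
    )
    def test_round_half_up_percentages(self, k, n, decimals, expected):
        assert cohort_frequency(k, n, decimals) == expected

    def test_half_up_not_banker_rounding(self):
        assert cohort_frequency(1, 8, 1) == 12.5
        assert cohort_frequency(25, 1000, 1) == 2.5
        assert cohort_frequency(25, 1000, 0) == 3.0  # 2.5 rounds up, not to even

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            cohort_frequency(1, 0)


class TestSmgSummary:
    def test_empty_matrix_all_zero_class(self):
        mat = _matrix({"A": [0, 0, 0]}, ["I", "I", "III"])
        s = smg_combination_summary(mat, ["A"])
        assert s == {"n_zero": 3, "n_one": 0, "n_two_plus": 0, "n_combinations": 0}

    def test_toy_subsets_hand_enumeration(self):
        mat = _matrix(
            {"A": [1, 1, 1, 0, 0], "B": [0, 0, 1, 0, 1]},
            ["I"] * 5,
        )
        s = smg_combination_summary(mat, ["A", "B"])
        # subsets: {A},{A},{A,B},{},{B} -> classes (1 zero, 3 one, 1 two+)
        assert (s["n_zero"], s["n_one"], s["n_two_plus"]) == (1, 3, 1)
        assert s["n_combinations"] == 3

    def test_classes_partition_cohort(self, small_sim):
        genes = list(small_sim.cohort.mutations.columns[:5])
        s = smg_combination_summary(small_sim.cohort, genes)
        assert s["n_zero"] + s["n_one"] + s["n_two_plus"] == len(
            small_sim.cohort.mutations
        )


class TestStageAssociation:
    def test_equal_proportions_give_p_one(self):
        mat = _two_stage_matrix({"G": (5, 5)}, 10, 10)
        _, _, p = stage_association_test(mat, "G")
        assert p == 1.0

    def test_reconstructed_stage_biased_gene(self):
        # 35% of 51 stage I vs 8% of 53 stage III, 22 mutated in total
        mat = _two_stage_matrix({"G": (18, 4)}, 51, 53)
        table, odds, p = stage_association_test(mat, "G", alternative="greater")
        assert table.tolist() == [[18, 33], [4, 49]]
        assert p <= 0.0006
        assert p == pytest.approx(fisher_oracle(18, 33, 4, 49)[1], abs=1e-12)

    def test_gene_set_feature_uses_any_member(self):
        mat = _two_stage_matrix({"A": (3, 0), "B": (2, 1)}, 6, 6)
        # overlap: with this layout samples a0..a2 have A, a0..a1 have B
        table, _, _ = stage_association_test(mat, ["A", "B"])
        assert table[0, 0] == 3 and table[1, 0] == 1

    def test_missing_gene_raises(self):
        mat = _two_stage_matrix({"A": (1, 1)}, 3, 3)
        with pytest.raises(KeyError):
            stage_association_test(mat, "nope")

    def test_family_bh_adjustment_monotone(self):
        mat = _two_stage_matrix(
            {"A": (9, 1), "B": (6, 3), "C": (5, 5), "D": (2, 8)}, 10, 10
        )
        fam = stage_association_family(
            mat, {g: g for g in "ABCD"}, alternative="greater"
        )
        order = fam.sort_values("p")
        assert (order["p_adj"].diff().dropna() >= -1e-12).all()
        assert (fam["p_adj"] <= 1.0).all()
        assert np.allclose(fam["p_adj"], bh_oracle(fam["p"]), atol=1e-12)

    def test_null_rejection_rate_matches_exact_discrete_level(self):
        """Fisher's exact test is conservative on discrete tables; the
        empirical null rejection rate must match its exactly-enumerated
        expected level, not exceed nominal alpha."""
        n1, n3, rate, alpha = 51, 53, 0.3, 0.05
        # exact expected rejection probability under binomial sampling
        pk1 = stats.binom.pmf(np.arange(n1 + 1), n1, rate)
        pk3 = stats.binom.pmf(np.arange(n3 + 1), n3, rate)
        rej = np.zeros((n1 + 1, n3 + 1), dtype=bool)
        for k1 in range(n1 + 1):
            for k3 in range(n3 + 1):
                p = stats.fisher_exact([[k1, n1 - k1], [k3, n3 - k3]])[1]
                rej[k1, k3] = p < alpha
        expected = float(pk1 @ rej @ pk3)
        assert expected < alpha  # conservativeness of the exact test

        rng = np.random.default_rng(314159)
        m = 2000
        k1s = rng.binomial(n1, rate, size=m)
        k3s = rng.binomial(n3, rate, size=m)
        observed = np.mean(rej[k1s, k3s])
        half = 2.576 * np.sqrt(expected * (1 - expected) / m)
        assert abs(observed - expected) <= half


class TestPathwayEnrichment:
    def test_pathway_equal_to_universe_gives_p_one(self):
        uni = frozenset(f"g{i}" for i in range(10))
        db = PathwayDb({"all": uni}, uni)
        out = pathway_enrichment(["g1", "g2"], db)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_overlap_tail_matches_term_summation(self):
        uni = frozenset(f"g{i}" for i in range(20))
        pw = frozenset(f"g{i}" for i in range(5))
        db = PathwayDb({"pw": pw}, uni)
        mutated = ["g0", "g1", "g2", "g3", "g10"]  # overlap 4 of 5 mutated
        out = pathway_enrichment(mutated, db)
        assert out["p"].iloc[0] == pytest.approx(
            hypergeom_tail_oracle(20, 5, 5, 4), abs=1e-12
        )

    def test_bh_textbook_arithmetic(self):
        assert np.allclose(bh_oracle([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
        uni = frozenset(f"g{i}" for i in range(30))
        db = PathwayDb(
            {f"p{j}": frozenset(f"g{i}" for i in range(j, j + 5)) for j in range(3)},
            uni,
        )
        out = pathway_enrichment([f"g{i}" for i in range(6)], db)
        assert np.allclose(out["p_adj"], bh_oracle(out["p"]), atol=1e-12)

    def test_mutated_outside_universe_rejected(self):
        db = PathwayDb({"p": frozenset(["a"])}, frozenset(["a", "b"]))
        with pytest.raises(ValueError):
            pathway_enrichment(["z"], db)


class TestBurdenComparison:
    def test_identical_groups_no_evidence(self):
        p, _ = compare_burden([0.1, 0.1, 0.1], [0.1, 0.1, 0.1])
        assert p == 1.0

    def test_exact_small_case_one_twentieth(self):
        p, direction = compare_burden([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(1 / 20)
        assert direction == "stage3>stage1"

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(321)
        b1 = rng.normal(0.1, 0.05, size=40).clip(0)
        b3 = rng.normal(0.3, 0.05, size=40).clip(0)
        p, direction = compare_burden(b1, b3)
        assert p < 1e-6 and direction == "stage3>stage1"


class TestMutationSpectrum:
    def test_purine_reference_folds_to_pyrimidine(self):
        counts = mutation_spectrum([("G", "A")])
        assert counts["C>T"] == 1 and sum(counts.values()) == 1

    def test_empty_list_all_zero(self):
        assert all(v == 0 for v in mutation_spectrum([]).values())

    def test_hand_tally_of_twelve_variants(self):
        variants = [
            ("C", "A"), ("C", "A"), ("G", "T"),  # 3x C>A
            ("C", "G"), ("G", "C"),              # 2x C>G
            ("C", "T"), ("G", "A"), ("G", "A"),  # 3x C>T
            ("T", "A"),                          # 1x T>A
            ("T", "C"), ("A", "G"),              # 2x T>C
            ("T", "G"),                          # 1x T>G
        ]
        counts = mutation_spectrum(variants)
        assert counts == {"C>A": 3, "C>G": 2, "C>T": 3, "T>A": 1, "T>C": 2, "T>G": 1}
        assert sum(counts.values()) == 12

    def test_non_snv_rejected(self):
        with pytest.raises(ValueError):
            mutation_spectrum([("C", "C")])


def test_matrix_validation():
    with pytest.raises(ValueError):
        _matrix({"A": [0, 2]}, ["I", "III"])
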