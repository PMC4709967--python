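"""Marker projection, G-scores, permutation null, regions, SCNA burden."""

import numpy as np
import pandas as pd
import pytest

from esccpipe.cnv_gscore import (
    AMPLIFICATION,
    DELETION,
    NEUTRAL,
    CnSegment,
    CnvParams,
    call_gain_loss,
    gene_copy_number,
    gscore,
    gscore_track,
    make_marker_matrix,
    permutation_null,
    scna_burden,
    significant_regions,
)


class TestGeneCopyNumber:
    GENES = pd.DataFrame(
        [("g1", "chr1", 100, 200), ("g2", "chr1", 900, 1100), ("g3", "chr2", 0, 100)],
        columns=["gene", "chrom", "start", "end"],
    )

    def test_gene_inside_one_segment(self):
        segs = {"s": [CnSegment("chr1", 0, 500, 3.1)]}
        cn = gene_copy_number(segs, self.GENES)
        assert cn.loc["g1", "s"] == pytest.approx(3.1)

    def test_split_gene_is_weighted_mean(self):
        segs = {"s": [CnSegment("chr1", 0, 1000, 2.0), CnSegment("chr1", 1000, 2000, 4.0)]}
        cn = gene_copy_number(segs, self.GENES)
        assert cn.loc["g2", "s"] == pytest.approx(3.0)

    def test_uncovered_gene_is_missing(self):
        segs = {"s": [CnSegment("chr1", 0, 500, 3.0)]}
        assert np.isnan(gene_copy_number(segs, self.GENES).loc["g3", "s"])

    def test_malformed_gene_interval_rejected(self):
        bad = pd.DataFrame(
            [("g", "chr1", 50, 50)], columns=["gene", "chrom", "start", "end"]
        )
        with pytest.raises(ValueError):
            gene_copy_number({}, bad)


class TestCallGainLoss:
    @pytest.mark.parametrize(
        "cn,expected",
        [(1.5, DELETION), (2.5, AMPLIFICATION), (2.0, NEUTRAL),
         (1.51, NEUTRAL), (2.49, NEUTRAL), (0.0, DELETION), (4.0, AMPLIFICATION)],
    )
    def test_inclusive_thresholds(self, cn, expected):
        assert call_gain_loss(cn) == expected


class TestMarkerMatrix:
    def test_window_count_includes_trailing_partial(self):
        X, table = make_marker_matrix(
            {"s": [CnSegment("chr1", 0, 10_000, 2.0)]}, [("chr1", 10_000)], 1000
        )
        assert X.shape == (10, 1)
        X2, table2 = make_marker_matrix({"s": []}, [("chr1", 10_500)], 1000)
        assert X2.shape == (11, 1)
        assert table2.iloc[-1]["end"] - table2.iloc[-1]["start"] == 500

    def test_partial_overlap_weighted_mean(self):
        segs = {"s": [CnSegment("chr1", 0, 1500, 4.0), CnSegment("chr1", 1500, 10_000, 2.0)]}
        X, _ = make_marker_matrix(segs, [("chr1", 10_000)], 1000)
        assert X[0, 0] == pytest.approx(4.0)
        assert X[1, 0] == pytest.approx(3.0)  # (500*4 + 500*2)/1000

    def test_uncovered_windows_fill_neutral(self):
        X, _ = make_marker_matrix(
            {"s": [CnSegment("chr1", 0, 1000, 5.0)]}, [("chr1", 3000)], 1000
        )
        assert X[1, 0] == 2.0 and X[2, 0] == 2.0

    def test_all_diploid_gives_constant_matrix(self):
        segs = {
            a: [CnSegment("chr1", 0, 5000, 2.0)] for a in ("s1", "s2", "s3")
        }
        X, _ = make_marker_matrix(segs, [("chr1", 5000)], 1000)
        assert (X == 2.0).all()

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            make_marker_matrix({}, [], 1000)

    def test_agrees_with_per_bp_average_on_toy_genome(self, rng):
        # brute-force oracle: per-bp CN vector, averaged within windows
        length = 20_000
        breaks = np.sort(rng.choice(np.arange(1, length), 6, replace=False))
        edges = [0, *breaks.tolist(), length]
        cns = rng.uniform(0.5, 4.5, size=len(edges) - 1)
        segs = [
            CnSegment("chr1", s, e, cn)
            for s, e, cn in zip(edges[:-1], edges[1:], cns)
        ]
        X, _ = make_marker_matrix({"s": segs}, [("chr1", length)], 1000)
        per_bp = np.empty(length)
        for seg in segs:
            per_bp[seg.start:seg.end] = seg.copy_number
        oracle = per_bp.reshape(-1, 1000).mean(axis=1)
        assert np.allclose(X[:, 0], oracle, atol=1e-12)


class TestGScore:
    def test_all_diploid_gives_zero_scores(self):
        X = np.full((5, 8), 2.0)
        g_amp, g_del = gscore(X)
        assert (g_amp == 0).all() and (g_del == 0).all()

    def test_frequency_times_mean_amplitude(self):
        X = np.full((1, 10), 2.0)
        X[0, :4] = 3.0  # 40% of samples at amplitude 1.0
        g_amp, g_del = gscore(X)
        assert g_amp[0] == pytest.approx(0.4)
        assert g_del[0] == 0.0

    def test_linearity_in_amplitude(self):
        X = np.full((1, 10), 2.0)
        X[0, :4] = 3.0
        X2 = X.copy()
        X2[0, :4] = 4.0  # doubled excess
        assert gscore(X2)[0][0] == pytest.approx(2 * gscore(X)[0][0])

    def test_sub_threshold_gains_do_not_score(self):
        X = np.full((1, 10), 2.4)
        g_amp, _ = gscore(X)
        assert g_amp[0] == 0.0

    def test_invariant_to_sample_order(self, rng):
        X = rng.uniform(0.5, 4.0, size=(20, 15))
        g1 = gscore(X)
        perm = rng.permutation(15)
        g2 = gscore(X[:, perm])
        assert np.allclose(g1[0], g2[0]) and np.allclose(g1[1], g2[1])


class TestPermutationNull:
    def test_constant_matrix_nothing_significant(self):
        X = np.full((20, 6), 2.0)
        params = CnvParams(n_permutations=200, seed=1)
        p_amp, p_del = permutation_null(X, params)
        assert (p_amp == 1.0).all() and (p_del == 1.0).all()

    def test_p_floor_and_range(self, rng):
        X = rng.normal(2.0, 0.5, size=(50, 10))
        params = CnvParams(n_permutations=200, seed=2)
        p_amp, p_del = permutation_null(X, params)
        floor = 1 / 201
        for p in (p_amp, p_del):
            assert (p >= floor - 1e-12).all() and (p <= 1.0).all()

    def test_seeded_and_reproducible(self, rng):
        X = rng.normal(2.0, 0.4, size=(30, 8))
        params = CnvParams(n_permutations=150, seed=9)
        assert np.array_equal(permutation_null(X, params)[0],
                              permutation_null(X, params)[0])

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ValueError):
            permutation_null(np.full((5, 5), 2.0), CnvParams(n_permutations=50))


class TestSignificantRegions:
    def _track(self, sig, g):
        n = len(sig)
        return pd.DataFrame(
            {
                "chrom": ["chr1"] * n,
                "start": np.arange(n) * 1000,
                "end": (np.arange(n) + 1) * 1000,
                "g_amp": g,
                "p_amp": [0.01] * n,
                "sig_amp": sig,
            }
        )

    def test_empty_when_nothing_significant(self):
        track = self._track([False] * 5, [0.05] * 5)
        assert significant_regions(track, "amp").empty

    def test_contiguous_run_merges_into_one_region(self):
        sig = [False, True, True, True, True, True, True, True, False]
        g = [0, 0.2, 0.3, 0.9, 0.4, 0.3, 0.2, 0.2, 0]
        regions = significant_regions(self._track(sig, g), "amp")
        assert len(regions) == 1
        r = regions.iloc[0]
        assert r["end"] - r["start"] == 7000
        assert r["peak_start"] == 3000 and r["peak_g"] == pytest.approx(0.9)

    def test_gap_splits_regions(self):
        sig = [True, True, False, True]
        regions = significant_regions(self._track(sig, [0.2] * 4), "amp")
        assert len(regions) == 2

    def test_gscore_cutoff_is_strict(self):
        X = np.full((5, 10), 2.0)
        X[2, :] = 2.5  # amplitude 0.5 in all samples -> G exactly 0.5
        X[3, :5] = 2.2  # sub-threshold, G = 0
        params = CnvParams(n_permutations=100, seed=3, gscore_cutoff=0.5)
        track = gscore_track(X, pd.DataFrame({
            "chrom": ["chr1"] * 5, "start": np.arange(5) * 1000,
            "end": (np.arange(5) + 1) * 1000,
        }), params)
        # G == cutoff exactly must NOT be flagged
        assert not track["sig_amp"].any()


class TestScnaBurden:
    def test_all_neutral_is_zero(self):
        segs = [CnSegment("chr1", 0, 30_000_000, 2.0)]
        assert scna_burden(segs) == 0.0

    def test_length_weighted_fraction(self):
        segs = [
            CnSegment("chr1", 0, 3_000_000, 3.0),
            CnSegment("chr1", 3_000_000, 30_000_000, 2.0),
        ]
        assert scna_burden(segs) == pytest.approx(0.1)

    def test_whole_genome_amplified_is_one(self):
        assert scna_burden([CnSegment("chr1", 0, 1000, 4.0)]) == 1.0

    def test_no_segments_is_zero(self):
        assert scna_burden([]) == 0.0
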