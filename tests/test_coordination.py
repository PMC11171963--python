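import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coordinome import (
    CorrelationHistogram,
    ThresholdPair,
    coordination_entropy,
    fit_beta_threshold,
    fit_beta_thresholds,
    histogram_and_chi2,
    histogram_correlations,
    pairwise_pearson,
    reevaluate_pairs,
    strong_pairs,
    zscore_standardize,
)


def _table(rs):
    return pd.DataFrame(
        {"gene_a": [f"a{i}" for i in range(len(rs))],
         "gene_b": [f"b{i}" for i in range(len(rs))],
         "r": rs}
    )


class TestZscore:
    def test_simple_vector(self):
        m = pd.DataFrame({"A_1": [1.0], "A_2": [2.0], "A_3": [3.0]}, index=["g"])
        z = zscore_standardize(m, "A")
        assert np.allclose(z.loc["g"], [-1.0, 0.0, 1.0])

    def test_constant_gene_flagged_and_excluded(self):
        m = pd.DataFrame({"A_1": [1.0, 5.0], "A_2": [2.0, 5.0], "A_3": [3.0, 5.0]},
                         index=["g1", "flat"])
        with pytest.warns(UserWarning, match="zero-variance"):
            z = zscore_standardize(m, "A")
        assert "flat" not in z.index
        assert z.attrs["excluded"] == ["flat"]

    def test_mean_zero_sd_one(self, two_state_data):
        matrix, _ = two_state_data
        z = zscore_standardize(matrix, "stateA")
        assert np.abs(z.mean(axis=1)).max() < 1e-12
        assert np.abs(z.std(axis=1, ddof=1) - 1).max() < 1e-12

    def test_single_replicate_rejected(self):
        m = pd.DataFrame({"A_1": [1.0]}, index=["g"])
        with pytest.raises(ValueError, match="replicates"):
            zscore_standardize(m, "A")


class TestPairwisePearson:
    @staticmethod
    def _z(rows):
        m = pd.DataFrame(rows, columns=["A_1", "A_2", "A_3"]).astype(float)
        m.index = [f"g{i}" for i in range(len(rows))]
        return zscore_standardize(m, "A")

    def test_perfect_positive_negative_and_zero(self):
        z = self._z([[1, 2, 3], [2, 4, 6], [3, 2, 1], [0, 1, 0]])
        table = pairwise_pearson(z)
        lut = {(a, b): r for a, b, r in table.itertuples(index=False)}
        assert lut[("g0", "g1")] == pytest.approx(1.0)
        assert lut[("g0", "g2")] == pytest.approx(-1.0)
        assert lut[("g0", "g3")] == pytest.approx(0.0)

    def test_each_unordered_pair_once(self, two_state_data):
        matrix, _ = two_state_data
        z = zscore_standardize(matrix, "stateA")
        table = pairwise_pearson(z)
        n = len(z)
        assert len(table) == n * (n - 1) // 2
        assert (table["gene_a"] < table["gene_b"]).all()

    def test_r_invariant_under_zscoring(self, two_state_data):
        matrix, _ = two_state_data
        cols = ["stateA_1", "stateA_2", "stateA_3"]
        raw = matrix[cols].iloc[:30]
        z = zscore_standardize(matrix, "stateA").iloc[:30]
        r_raw = np.corrcoef(raw.values)
        r_z = (z.values @ z.values.T) / (len(cols) - 1)
        iu = np.triu_indices(30, 1)
        assert np.abs(r_raw[iu] - r_z[iu]).max() < 1e-10

    def test_cross_set_excludes_self_pairs_and_dedupes(self):
        z = self._z([[1, 2, 3], [2, 4, 6], [3, 2, 1], [0, 1, 0]])
        table = pairwise_pearson(z, set_x=["g0", "g1"], set_y=["g1", "g2"])
        pairs = {tuple(p) for p in table[["gene_a", "gene_b"]].itertuples(index=False)}
        assert pairs == {("g0", "g1"), ("g0", "g2"), ("g1", "g2")}

    def test_cross_set_on_disjoint_blocks_is_specific(self, two_state_data, two_state_spec):
        # genes of different planted blocks are mutually unstructured, so
        # cross-set strong pairs stay at the null false-positive level
        matrix, truth = two_state_data
        z = zscore_standardize(matrix, "stateA")
        block_a = truth.block_members("blockA")
        block_b = truth.block_members("blockB")
        cross = pairwise_pearson(z, set_x=block_a, set_y=block_b)
        thresholds = ThresholdPair.fixed(0.99)
        summary = strong_pairs(cross, thresholds)
        cross_frac = (summary.n_positive + summary.n_negative) / len(cross)
        within = pairwise_pearson(z, set_x=block_a)
        within_frac = strong_pairs(within, thresholds).n_positive / len(within)
        # with 3 replicates the null |r| > 0.99 rate is ~9%, so specificity
        # is asserted as a wide margin below the planted within-block rate
        assert within_frac > 0.7
        assert cross_frac < within_frac - 0.5
        assert cross_frac < 0.3


class TestHistogramAndChi2:
    def test_identical_tables_give_zero_chi2(self):
        rng = np.random.default_rng(0)
        t = _table(rng.uniform(-1, 1, 500))
        res = histogram_and_chi2(t, t)
        assert res["chi2_stat"] == 0.0
        assert res["hist_a"].total == 500

    def test_chi2_matches_hand_computation(self):
        # two bins [-1, 0) and [0, 1]: A has (30, 70), B has (50, 50)
        a = _table(np.concatenate([np.full(30, -0.5), np.full(70, 0.5)]))
        b = _table(np.concatenate([np.full(50, -0.5), np.full(50, 0.5)]))
        res = histogram_and_chi2(a, b, edges=np.array([-1.0, 0.0, 1.0]))
        expected = (30 - 50) ** 2 / 50 + (70 - 50) ** 2 / 50
        assert res["chi2_stat"] == pytest.approx(expected)
        assert res["chi2_p"] == pytest.approx(stats.chi2.sf(expected, 1))

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            histogram_and_chi2(_table([]), _table([0.5]))


class TestBetaThreshold:
    def test_uniform_sample_recovers_flat_beta(self):
        rng = np.random.default_rng(42)
        t = _table(rng.uniform(0, 1, 10_000))
        fit = fit_beta_threshold(t, "positive")
        assert abs(fit.alpha - 1) < 0.1 and abs(fit.beta - 1) < 0.1
        assert 0.94 < fit.threshold < 0.96

    def test_beta_5_2_parameter_recovery(self):
        rng = np.random.default_rng(7)
        t = _table(rng.beta(5, 2, 10_000))
        fit = fit_beta_threshold(t, "positive")
        assert abs(fit.alpha - 5) / 5 < 0.1
        assert abs(fit.beta - 2) / 2 < 0.1

    def test_negative_side_is_mirrored(self):
        rng = np.random.default_rng(3)
        t = _table(np.concatenate([rng.uniform(0, 1, 200), -rng.uniform(0, 1, 200)]))
        pair = fit_beta_thresholds(t)
        assert pair.r_pos > 0 > pair.r_neg
        assert pair.r_neg == pytest.approx(-pair.positive.threshold, abs=0.05)

    def test_degenerate_sample_rejected(self):
        t = _table(np.full(100, 0.999))
        with pytest.raises(ValueError, match="degenerate"):
            fit_beta_threshold(t, "positive")

    def test_too_few_pairs_rejected(self):
        t = _table(np.linspace(0.1, 0.9, 10))
        with pytest.raises(ValueError, match=">= 50"):
            fit_beta_threshold(t, "positive")


class TestStrongPairs:
    def test_enumerated_example(self):
        t = _table([0.97, 0.5, -0.99])
        summary = strong_pairs(t, ThresholdPair.fixed(0.96))
        assert (summary.n_positive, summary.n_negative) == (1, 1)
        assert summary.r_avg_positive == pytest.approx(0.97)
        assert summary.r_avg_negative == pytest.approx(-0.99)

    def test_empty_table_flags_undefined_averages(self):
        summary = strong_pairs(_table([]), ThresholdPair.fixed(0.96))
        assert (summary.n_positive, summary.n_negative) == (0, 0)
        assert np.isnan(summary.r_avg_positive)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            ThresholdPair.fixed(1.2)

    def test_reference_selected_pairs_consistent_in_reference(self, two_state_data):
        matrix, _ = two_state_data
        z = zscore_standardize(matrix, "stateA")
        table = pairwise_pearson(z)
        summary = strong_pairs(table, ThresholdPair.fixed(0.96))
        back = reevaluate_pairs(summary.positive_pairs, table)
        assert back["n_found"] == summary.n_positive
        assert back["r_avg"] >= 0.96

    def test_reevaluation_in_other_condition_decays(self, two_state_data, two_state_spec):
        # pairs strong in stateA (blockA planted there) lose coordination in
        # stateB, where the block is dissolved
        matrix, _ = two_state_data
        za = zscore_standardize(matrix, "stateA")
        zb = zscore_standardize(matrix, "stateB")
        ta, tb = pairwise_pearson(za), pairwise_pearson(zb)
        sa = strong_pairs(ta, ThresholdPair.fixed(0.96))
        other = reevaluate_pairs(sa.positive_pairs, tb)
        assert other["r_avg"] < sa.r_avg_positive - 0.3


class TestCoordinationEntropy:
    def test_uniform_is_maximal(self):
        assert coordination_entropy(np.full(50, 7)) == pytest.approx(1.0)

    def test_point_mass_is_zero(self):
        counts = np.zeros(50)
        counts[10] = 123
        assert coordination_entropy(counts) == pytest.approx(0.0)

    def test_half_and_half_case(self):
        assert coordination_entropy(np.array([50, 50, 0, 0])) == pytest.approx(
            np.log(2) / np.log(4)
        )

    def test_entropy_decreases_under_concentration(self):
        # majorization: moving mass into fewer bins lowers entropy
        seq = [np.array([25, 25, 25, 25]), np.array([40, 30, 20, 10]),
               np.array([70, 20, 5, 5]), np.array([97, 1, 1, 1])]
        entropies = [coordination_entropy(c) for c in seq]
        assert entropies == sorted(entropies, reverse=True)

    def test_histogram_object_accepted(self):
        hist = CorrelationHistogram(edges=np.linspace(-1, 1, 5),
                                    counts=np.array([1, 1, 1, 1]))
        assert coordination_entropy(hist) == pytest.approx(1.0)

    def test_empty_histogram_rejected(self):
        with pytest.raises(ValueError, match="no counts"):
            coordination_entropy(np.zeros(10))


def test_histogram_bins_partition_unit_interval():
    rng = np.random.default_rng(5)
    t = _table(rng.uniform(-1, 1, 1000))
    hist = histogram_correlations(t)
    assert hist.counts.sum() == 1000
    assert hist.edges[0] == -1.0 and hist.edges[-1] == 1.0
    assert hist.n_bins == 50
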