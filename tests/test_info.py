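"""Mutual information estimation, bias correction and decompositions."""

import numpy as np
import pytest

from objcode.info import (
    corrected_mi,
    energy_decomposition,
    equipopulated_bins,
    invariance_decomposition,
    joint_counts,
    luminance_object_info,
    permutation_significance,
    plugin_mi,
    pt_bias,
    luminance_sensitivity_curve,
    sparseness,
    support_size,
)


def brute_force_mi(table):
    """Direct summation over P(s) P(r|s) log2 P(r|s)/P(r)."""
    table = np.asarray(table, float)
    total = table.sum()
    mi = 0.0
    pr = table.sum(axis=0) / total
    for s in range(table.shape[0]):
        ps = table[s].sum() / total
        if ps == 0:
            continue
        for r in range(table.shape[1]):
            prs = table[s, r] / table[s].sum()
            if prs > 0:
                mi += ps * prs * np.log2(prs / pr[r])
    return mi


class TestBinning:
    def test_exact_tertiles(self):
        b = equipopulated_bins(np.arange(9), 3)
        assert b.bin_index.tolist() == [0, 0, 0, 1, 1, 1, 2, 2, 2]

    def test_single_bin_gives_zero_information(self):
        b = equipopulated_bins(np.arange(30), 1)
        table = joint_counts(np.repeat(np.arange(3), 10), b.bin_index, 3, 1)
        assert plugin_mi(table) == pytest.approx(0.0)

    def test_heavy_ties_against_quantile_oracle(self):
        values = np.array([0] * 15 + list(range(1, 16)), dtype=float)
        b = equipopulated_bins(values, 3)
        edges = np.quantile(values, [1 / 3, 2 / 3])
        oracle = np.digitize(values, edges, right=True)
        assert np.array_equal(b.bin_index, oracle)
        # ties at an edge all land in the lower bin
        assert len(set(b.bin_index[values == edges[0]])) <= 1

    def test_collapse_warning_when_too_few_distinct(self):
        with pytest.warns(UserWarning):
            equipopulated_bins(np.array([1.0, 1.0, 2.0]), 3)

    def test_empty_values_rejected(self):
        with pytest.raises(ValueError):
            equipopulated_bins(np.array([]), 3)


class TestPluginMI:
    def test_independent_table_zero(self):
        table = np.outer([10, 20, 30], [5, 15])
        assert plugin_mi(table) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_binary_association_one_bit(self):
        assert plugin_mi(np.array([[30, 0], [0, 30]])) == pytest.approx(1.0)

    def test_example_table_matches_direct_summation(self):
        table = np.array([[25, 5], [5, 25]])
        assert plugin_mi(table) == pytest.approx(brute_force_mi(table), abs=1e-12)
        assert plugin_mi(table) == pytest.approx(0.350, abs=5e-4)

    def test_relabeling_invariance(self, rng):
        table = rng.integers(0, 20, (6, 4)).astype(float)
        assert plugin_mi(table[::-1]) == pytest.approx(plugin_mi(table))
        assert plugin_mi(table[:, ::-1]) == pytest.approx(plugin_mi(table))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            plugin_mi(np.zeros((2, 2)))


class TestBiasCorrection:
    def test_hand_evaluated_bias(self):
        # (1/(2*60*ln2)) * [((3-1)+(2-1)) - (3-1)] = 1/(120 ln 2)
        assert pt_bias([3, 2], 3, 60) == pytest.approx(
            1.0 / (120.0 * np.log(2)), rel=1e-12
        )
        assert pt_bias([3, 2], 3, 60) == pytest.approx(0.0120, abs=5e-5)

    def test_degenerate_support_zero_bias(self):
        assert pt_bias([1, 1, 1], 1, 50) == 0.0

    def test_support_estimators(self):
        dense = np.array([40, 35, 25])
        assert support_size(dense, "naive") == 3
        assert support_size(dense, "bayes") == 3
        sparse = np.array([1, 1, 0, 0, 0, 0])
        assert support_size(sparse, "bayes") >= support_size(sparse, "naive")

    def test_corrected_mi_unbiased_on_independent_data(self, rng):
        # the purpose of the correction: on independent R, S (10 stimuli,
        # responses over 3 bins, 30 trials/stimulus = 10 per stimulus and
        # bin) the plug-in MI is biased upward but the corrected
        # estimate averages ~0
        n_stim, n_trials, reps = 10, 30, 200
        corrected, plug = [], []
        for _ in range(reps):
            idx = rng.integers(0, 3, n_stim * n_trials)
            stim = np.repeat(np.arange(n_stim), n_trials)
            table = joint_counts(stim, idx, n_stim, 3)
            corrected.append(corrected_mi(table))
            plug.append(plugin_mi(table))
        corrected = np.array(corrected)
        sem = corrected.std(ddof=1) / np.sqrt(reps)
        assert abs(corrected.mean()) < 2 * sem
        # raw plug-in on the same data is clearly biased upward
        assert np.mean(plug) > 5 * sem


class TestEnergyDecomposition:
    def test_luminance_only_neuron_low_f_high(self, rng):
        n_cond = 230
        L = rng.uniform(0, 0.6, n_cond)
        rates = 2.0 + 30.0 * L  # deterministic monotone function of L
        counts = rng.poisson(rates[:, None] * 0.15, (n_cond, 50))
        d = energy_decomposition(counts, L)
        assert d.f_high <= 0.1
        assert abs(d.identity_gap_plugin) < 1e-9

    def test_identity_only_equal_luminance_high_f_high(self, rng):
        # 10 objects x 23 views; every object shows the same L profile
        L = np.tile(rng.uniform(0.1, 0.5, 23), 10)
        rates = np.repeat(np.linspace(1, 25, 10), 23)
        counts = rng.poisson(rates[:, None] * 0.15, (230, 50))
        d = energy_decomposition(counts, L)
        assert d.f_high >= 0.9
        assert abs(d.identity_gap_plugin) < 1e-9

    def test_chain_rule_identity_on_random_data(self, rng):
        counts = rng.poisson(3.0, (46, 12))
        L = rng.uniform(0, 1, 46)
        d = energy_decomposition(counts, L, n_L_bins=23)
        assert abs(d.identity_gap_plugin) < 1e-9

    def test_too_few_conditions_rejected(self, rng):
        with pytest.raises(ValueError):
            energy_decomposition(rng.poisson(3, (10, 5)), np.linspace(0, 1, 10))


class TestInvarianceDecomposition:
    def test_noiseless_object_code(self):
        counts_i = np.full((23, 26), 8.0)
        counts_j = np.full((23, 26), 1.0)
        d = invariance_decomposition(counts_i, counts_j)
        assert d.I_RO == pytest.approx(1.0, abs=0.01)
        assert d.I_RT_given_O == pytest.approx(0.0, abs=0.01)
        assert abs(d.identity_gap_plugin) < 1e-9

    def test_uninformative_neuron_near_zero(self, rng):
        counts_i = rng.poisson(4.0, (23, 26))
        counts_j = rng.poisson(4.0, (23, 26))
        d = invariance_decomposition(counts_i, counts_j)
        assert abs(d.I_RO) < 0.02
        assert abs(d.I_RT_given_O) < 0.05

    def test_view_only_code_matches_plugin_oracle(self, rng):
        # rate depends only on the view, identically for both objects
        view_rates = np.linspace(1, 20, 23)
        counts_i = rng.poisson(view_rates[:, None], (23, 40))
        counts_j = rng.poisson(view_rates[:, None], (23, 40))
        d = invariance_decomposition(counts_i, counts_j)
        assert abs(d.I_RO) < 0.01
        assert d.I_RT_given_O > 0.2
        # oracle: conditional plug-in term computed from explicit
        # per-object stimulus x bin tables (equal-weight objects)
        counts = np.vstack([counts_i, counts_j])
        b = equipopulated_bins(counts.ravel().astype(float), 3)
        idx = b.bin_index.reshape(46, 40)
        oracle_plug = 0.5 * sum(
            plugin_mi(
                joint_counts(
                    np.repeat(np.arange(23), 40),
                    idx[o * 23 : (o + 1) * 23].ravel(),
                    23,
                    3,
                )
            )
            for o in (0, 1)
        )
        # I(R;T|O) = I(R;S) - I(R;O) for the plug-in estimator
        o_table = np.vstack(
            [np.bincount(idx[:23].ravel(), minlength=3),
             np.bincount(idx[23:].ravel(), minlength=3)]
        )
        plug_cond = (
            d.I_RS_plugin - d.identity_gap_plugin - plugin_mi(o_table)
        )
        assert plug_cond == pytest.approx(oracle_plug, abs=1e-9)

    def test_data_processing_inequality(self, rng):
        # plug-in I(R;O) never exceeds plug-in I(R;S) on the same binning
        for _ in range(20):
            counts_i = rng.poisson(rng.uniform(1, 8), (23, 10))
            counts_j = rng.poisson(rng.uniform(1, 8), (23, 10))
            counts = np.vstack([counts_i, counts_j])
            b = equipopulated_bins(counts.ravel().astype(float), 3)
            idx = b.bin_index.reshape(46, 10)
            full = joint_counts(
                np.repeat(np.arange(46), 10), idx.ravel(), 46, 3
            )
            merged = np.vstack(
                [full[:23].sum(axis=0), full[23:].sum(axis=0)]
            )
            assert plugin_mi(merged) <= plugin_mi(full) + 1e-12

    def test_mismatched_views_rejected(self, rng):
        with pytest.raises(ValueError):
            invariance_decomposition(rng.poisson(3, (23, 5)), rng.poisson(3, (20, 5)))


class TestLuminanceObjectInfo:
    def test_disjoint_ranges_near_one_bit(self, rng):
        L_i = rng.uniform(0.0, 0.3, 23)
        L_j = rng.uniform(0.5, 0.9, 23)
        assert luminance_object_info(L_i, L_j) > 0.9

    def test_identical_distributions_near_zero(self):
        L = np.linspace(0.1, 0.6, 23)
        assert abs(luminance_object_info(L, L)) < 0.05

    def test_half_overlap_matches_plugin_oracle(self):
        L_i = np.linspace(0.0, 0.5, 23)
        L_j = np.linspace(0.25, 0.75, 23)
        values = np.concatenate([L_i, L_j])
        b = equipopulated_bins(values, 23)
        table = joint_counts(np.repeat([0, 1], 23), b.bin_index, 2, 23) * 26
        oracle = brute_force_mi(table) - (plugin_mi(table) - corrected_mi(table))
        assert luminance_object_info(L_i, L_j) == pytest.approx(oracle, abs=1e-12)
        assert 0.0 < luminance_object_info(L_i, L_j) < 1.0


class TestPermutationTest:
    def test_strong_tuning_is_significant(self, rng):
        rates = np.linspace(1, 30, 10)
        counts = rng.poisson(rates[:, None], (10, 30))
        _, p = permutation_significance(counts, n_perm=100, seed=1)
        assert p <= 0.01

    def test_constant_responses_give_p_one(self):
        counts = np.full((5, 10), 4.0)
        with pytest.warns(UserWarning):
            _, p = permutation_significance(counts, n_perm=50, seed=1)
        assert p == 1.0  # every null draw >= observed under the >= rule

    def test_null_p_values_approximately_uniform(self, rng):
        from scipy.stats import kstest

        pvals = []
        for k in range(200):
            counts = rng.poisson(3.0, (10, 8))
            _, p = permutation_significance(counts, n_perm=60, seed=k)
            pvals.append(p)
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestSparseness:
    def test_limits_and_hand_value(self):
        assert sparseness([0, 0, 5, 0]) == pytest.approx(1.0)
        assert sparseness([3, 3, 3, 3]) == pytest.approx(0.0)
        assert sparseness([1, 1, 0, 0]) == pytest.approx(2.0 / 3.0)
        assert np.isnan(sparseness([0.0, 0.0]))

    def test_luminance_sensitivity_curve(self):
        resp = np.array([[1.0, 2.0, 4.0, 8.0], [0.5, 1.0, 2.0, 4.0]])
        curve, sp = luminance_sensitivity_curve(resp)
        assert curve.max() == pytest.approx(1.0)
        assert np.all(np.diff(curve) > 0)
        assert sp == pytest.approx(sparseness(curve))
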