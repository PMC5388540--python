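"""Single-neuron QDA-threshold decoders and their controls."""

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.stats import norm, spearmanr

from objcode.single import (
    chance_performance,
    generalization,
    luminosity_ratio,
    neuron_summary,
    position_generalization_curve,
    qda_threshold,
    separability,
    shuffle_within_views,
    size_generalization,
)


def log_posterior_ratio(r, mu_i, s_i, mu_j, s_j):
    return norm.logpdf(r, mu_i, s_i) - norm.logpdf(r, mu_j, s_j)


class TestQDAThreshold:
    def test_equal_variance_midpoint(self):
        r, flag = qda_threshold(6.0, 1.0, 2.0, 1.0)
        assert r == 4.0 and flag == "equal-variance"

    def test_unequal_variance_between_means_root(self):
        r, flag = qda_threshold(6.0, 2.0, 2.0, 1.0)
        assert flag == "ok"
        oracle = brentq(
            log_posterior_ratio, 2.0, 6.0, args=(6.0, 2.0, 2.0, 1.0), xtol=1e-12
        )
        assert r == pytest.approx(oracle, abs=1e-9)
        assert 2.0 <= r <= 6.0

    def test_degenerate_cases(self):
        r, flag = qda_threshold(5.0, 0.0, 5.0, 0.0)
        assert np.isnan(r) and flag == "undecidable"
        r, flag = qda_threshold(5.0, 0.0, 2.0, 0.0)
        assert r == 3.5 and flag == "equal-variance"
        r, flag = qda_threshold(4.0, 0.0, 2.0, 1.0)
        assert r == 3.0 and flag == "midpoint-fallback"
        # equal means, unequal SDs: handled without raising
        r, flag = qda_threshold(3.0, 2.0, 3.0, 1.0)
        assert np.isfinite(r)

    def test_label_swap_symmetry(self):
        a = qda_threshold(6.0, 2.0, 2.0, 1.0)[0]
        b = qda_threshold(2.0, 1.0, 6.0, 2.0)[0]
        assert a == pytest.approx(b, abs=1e-12)

    def test_against_dense_root_search_on_random_draws(self, rng):
        n_checked = 0
        for _ in range(1000):
            mu_j, mu_i = np.sort(rng.uniform(0.0, 20.0, 2))
            if mu_i - mu_j < 0.05:
                continue
            s_i, s_j = rng.uniform(0.3, 5.0, 2)
            if abs(s_i - s_j) < 1e-6:
                continue
            f = lambda r: log_posterior_ratio(r, mu_i, s_i, mu_j, s_j)
            if f(mu_j) * f(mu_i) < 0:
                oracle = brentq(f, mu_j, mu_i, xtol=1e-10)
                r, flag = qda_threshold(mu_i, s_i, mu_j, s_j)
                assert flag == "ok"
                assert r == pytest.approx(oracle, abs=1e-6)
                n_checked += 1
        assert n_checked > 500  # between-means roots dominate


class TestSeparability:
    def test_perfectly_separated_pair(self, rng):
        ci = rng.poisson(3.0, (23, 25)) + 30.0
        cj = rng.poisson(3.0, (23, 25))
        res = separability(ci, cj, seed=0)
        assert res.net_info_bits == pytest.approx(1.0, abs=0.02)
        assert res.accuracy_pct == pytest.approx(100.0, abs=0.5)

    def test_identical_distributions_near_zero(self, rng):
        ci = rng.poisson(4.0, (23, 25))
        cj = rng.poisson(4.0, (23, 25))
        res = separability(ci, cj, seed=0)
        assert abs(res.net_info_bits) < 0.05

    def test_confusion_rows_sum_to_tested_trials(self, rng):
        ci = rng.poisson(4.0, (23, 25))
        cj = rng.poisson(6.0, (23, 25))
        res = separability(ci, cj, seed=0)
        assert res.confusion.sum(axis=1) == pytest.approx([23 * 25, 23 * 25])

    def test_object_label_swap_invariance(self, rng):
        ci = rng.poisson(6.0, (23, 25))
        cj = rng.poisson(3.0, (23, 25))
        a = separability(ci, cj, seed=3)
        b = separability(cj, ci, seed=3)
        assert a.info_bits == pytest.approx(b.info_bits, abs=0.03)
        assert a.accuracy_pct == pytest.approx(b.accuracy_pct, abs=2.0)

    def test_gaussian_d_prime_one_matches_bayes_simulation(self, rng):
        # counts ~ N(mu, 1) with d' = 1: ideal-observer accuracy is
        # Phi(1/2) ~ 69.1%; the cross-validated decoder should land
        # within Monte-Carlo error of a brute-force simulation
        mu_i, mu_j = 11.0, 10.0
        ci = rng.normal(mu_i, 1.0, (23, 40))
        cj = rng.normal(mu_j, 1.0, (23, 40))
        res = separability(ci, cj, seed=0, compute_chance=False)
        sim = rng.normal(mu_i, 1.0, 200_000) > 10.5
        sim_acc = 100 * 0.5 * (np.mean(sim) + np.mean(rng.normal(mu_j, 1.0, 200_000) < 10.5))
        assert res.accuracy_pct == pytest.approx(sim_acc, abs=1.5)

    def test_insufficient_trials_rejected(self, rng):
        with pytest.raises(ValueError):
            separability(rng.poisson(3, (23, 3)), rng.poisson(3, (23, 3)), k_folds=5)


class TestGeneralization:
    def test_view_invariant_identity_code(self, rng):
        ci = rng.poisson(3.0, (23, 25)) + 25.0
        cj = rng.poisson(3.0, (23, 25))
        res = generalization(ci, cj, n_iter=50, seed=0)
        assert res.net_info_bits == pytest.approx(1.0, abs=0.02)

    def test_view_only_code_near_zero(self, rng):
        view_rates = np.linspace(1, 15, 23)
        ci = rng.poisson(view_rates[:, None], (23, 25))
        cj = rng.poisson(view_rates[:, None], (23, 25))
        res = generalization(ci, cj, n_iter=50, seed=0)
        assert abs(res.net_info_bits) < 0.05

    def test_generalization_not_above_separability_paired(self, rng):
        # partially tolerant units: training on a single view carries
        # strictly less information than pooled-view training
        diffs = []
        for u in range(50):
            gains = 1.0 + rng.lognormal(0.0, 0.8, 23)
            a_i, a_j = 6.0, 2.0
            ci = rng.poisson((1.0 + a_i * gains)[:, None] * 0.4, (23, 20))
            cj = rng.poisson((1.0 + a_j * gains)[:, None] * 0.4, (23, 20))
            sep = separability(ci, cj, seed=u, compute_chance=False)
            gen = generalization(ci, cj, n_iter=30, seed=u, compute_chance=False)
            diffs.append(sep.info_bits - gen.info_bits)
        assert np.mean(diffs) > 0
        assert np.mean(np.array(diffs) >= -0.02) > 0.8

    def test_axis_restriction_requires_two_views(self, rng):
        with pytest.raises(ValueError):
            generalization(
                rng.poisson(3, (23, 10)), rng.poisson(3, (23, 10)), views=[4]
            )

    def test_net_performance_on_noise_units_calibrated(self, rng):
        nets = []
        for u in range(100):
            ci = rng.poisson(4.0, (23, 15))
            cj = rng.poisson(4.0, (23, 15))
            nets.append(separability(ci, cj, seed=u).net_info_bits)
        nets = np.array(nets)
        sem = nets.std(ddof=1) / np.sqrt(nets.size)
        assert abs(nets.mean()) < 2 * sem + 1e-3

    def test_monotone_in_identity_signal_strength(self, rng):
        medians = []
        for delta in [0.0, 0.5, 1.0, 2.0, 4.0]:
            nets = []
            for u in range(50):
                ci = rng.poisson(3.0 + delta, (23, 15))
                cj = rng.poisson(3.0, (23, 15))
                nets.append(
                    separability(ci, cj, seed=u, compute_chance=False).info_bits
                )
            medians.append(np.median(nets))
        assert all(a <= b + 1e-9 for a, b in zip(medians, medians[1:]))
        assert medians[-1] > medians[0]


class TestParametricGeneralization:
    def test_position_tolerant_unit_flat_curve(self, rng):
        ci = rng.poisson(10.0, (8, 25))
        cj = rng.poisson(2.0, (8, 25))
        net, acc = position_generalization_curve(ci, cj, seed=0)
        assert np.ptp(net) < 0.15
        assert np.all(net > 0.5)

    def test_rf_localized_units_decay_with_distance(self, rng):
        # identity signal gated by a spatial RF profile: discrimination
        # degrades as the testing position moves away from training
        curves = []
        positions = np.arange(8)
        for u in range(50):
            center = rng.uniform(1, 6)
            gate = np.exp(-0.5 * ((positions - center) / 1.2) ** 2)
            ci = rng.poisson((1 + 12 * gate)[:, None], (8, 20))
            cj = rng.poisson((1 + 3 * gate)[:, None], (8, 20))
            net, _ = position_generalization_curve(ci, cj, seed=u)
            curves.append(net)
        mean_curve = np.mean(curves, axis=0)
        rho, _ = spearmanr([7.5, 15.0, 22.5, 30.0], mean_curve)
        assert rho < 0

    def test_size_invariant_unit_near_ceiling(self, rng):
        ci = rng.poisson(2.0, (5, 25)) + 25.0
        cj = rng.poisson(2.0, (5, 25))
        g1, g2 = size_generalization(ci, cj, seed=0)
        assert g1 == pytest.approx(1.0, abs=0.05)
        assert g2 == pytest.approx(1.0, abs=0.05)

    def test_default_size_only_unit_near_zero(self, rng):
        gate = np.array([0.0, 0.0, 1.0, 0.0, 0.0])  # responds only at 35 deg
        ci = rng.poisson((1 + 15 * gate)[:, None], (5, 25))
        cj = rng.poisson((1 + 4 * gate)[:, None], (5, 25))
        g1, g2 = size_generalization(ci, cj, seed=0)
        assert abs(g1) < 0.12 and abs(g2) < 0.12


class TestChanceControls:
    def test_shuffle_preserves_per_view_counts(self, rng):
        ci = rng.poisson(5.0, (23, 12)).astype(float)
        cj = rng.poisson(2.0, (23, 12)).astype(float)
        si, sj = shuffle_within_views(ci, cj, rng)
        for t in range(23):
            assert sorted(np.r_[si[t], sj[t]]) == sorted(np.r_[ci[t], cj[t]])

    def test_chance_pipeline_near_zero_info(self, rng):
        ci = rng.poisson(8.0, (23, 20))
        cj = rng.poisson(2.0, (23, 20))
        res = chance_performance(ci, cj, mode="separability", seed=5)
        assert abs(res.info_bits) < 0.05
        assert res.accuracy_pct == pytest.approx(50.0, abs=7.0)


class TestSummaries:
    def test_luminosity_ratio_definition(self):
        assert luminosity_ratio([0.2] * 23, [0.4] * 23) == pytest.approx(0.5)
        assert luminosity_ratio([0.4] * 23, [0.2] * 23) == pytest.approx(0.5)
        assert luminosity_ratio([0.0] * 23, [0.0] * 23) == 1.0

    def test_threshold_filters_pairs(self):
        metrics = {(0, 1): {"x": 0.2}, (0, 2): {"x": 0.4}, (1, 2): {"x": 9.0}}
        ratios = {(0, 1): 0.95, (0, 2): 0.92, (1, 2): 0.3}
        out = neuron_summary(metrics, ratios, th_lum_ratio=0.9)
        assert out["x"] == pytest.approx(0.3)
        assert out["n_pairs"] == 2
        assert neuron_summary(metrics, ratios, th_lum_ratio=1.0) is None
        all_pairs = neuron_summary(metrics, ratios, th_lum_ratio=0.0)
        assert all_pairs["n_pairs"] == 3
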