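"""Multilevel coupling, bias extrapolation, allocation, and the MLMC driver."""

import math

import numpy as np
import pytest

import voikit as vk
from voikit.mlmc import MlmcLevelStats, fit_level_decay


def make_stats(means, var=1e-12, n=10**9):
    return [
        MlmcLevelStats(level=l + 1, n=n, mean_diff=m, var_diff=var)
        for l, m in enumerate(means)
    ]


class TestLevelDifferences:
    def test_identical_decisions_give_zero_differences(self, identical_problem):
        for level in (1, 3):
            d = vk.level_difference_samples(identical_problem, "x", level, 200, 1)
            np.testing.assert_allclose(d, 0.0, atol=1e-12)
        # anchored level-0 stream: max_d f_d - f_{d*} vanishes as well
        d0 = vk.level_difference_samples(identical_problem, "x", 0, 200, 1, d_star=0)
        np.testing.assert_allclose(d0, 0.0, atol=1e-12)

    def test_mean_decay_is_geometric(self, toy):
        """E[d_l] shrinks like 2^(-alpha l) with alpha near 1."""
        rng = np.random.default_rng(2)
        means, ns = [], 40_000
        for level in range(1, 6):
            d = vk.level_difference_samples(toy, "x", level, ns, rng)
            means.append(abs(d.mean()))
        slope = np.polyfit(np.arange(1, 6), np.log2(means), 1)[0]
        assert -1.6 <= slope <= -0.5

    def test_coupling_reduces_variance(self, toy):
        """Coupled differences d_1 (shared inner draws) have lower variance
        than e_1 - e_0 built from independent streams."""
        rng = np.random.default_rng(3)
        n = 40_000
        coupled = vk.level_difference_samples(toy, "x", 1, n, rng)
        # independent construction: fresh inner draws for each resolution
        sampler = toy.conditional_sampler("x")
        x = sampler.marginal_x().sample(n, rng)
        z_fine = sampler.sample_full(x, 2, rng)
        z_coarse = sampler.sample_full(x, 1, rng)
        fine = toy.net_benefits(z_fine).mean(axis=1).max(axis=1)
        coarse = toy.net_benefits(z_coarse)[:, 0, :].max(axis=1)
        independent = fine - coarse
        assert coupled.var(ddof=1) < 0.8 * independent.var(ddof=1)


class TestExtrapolateBias:
    def test_all_zero_means_give_zero_bias(self):
        assert vk.extrapolate_bias(make_stats([0.0, 0.0, 0.0])) == 0.0

    def test_geometric_tail_equals_last_term_at_rate_one(self):
        bias = vk.extrapolate_bias(make_stats([-0.8, -0.4, -0.2]))
        assert bias == pytest.approx(-0.2, abs=1e-9)
        alpha, _, trend = fit_level_decay(make_stats([-0.8, -0.4, -0.2]))
        assert alpha == pytest.approx(1.0, abs=1e-9)
        assert trend == -1.0

    def test_noise_free_geometric_tail_is_exact(self):
        c, alpha = 3.0, 1.5
        means = [c * 2 ** (-alpha * l) for l in range(1, 5)]
        bias = vk.extrapolate_bias(make_stats(means))
        analytic = c * 2 ** (-alpha * 5) / (1 - 2**-alpha)
        assert bias == pytest.approx(analytic, rel=1e-9)

    def test_non_decaying_means_rejected(self):
        with pytest.raises(ValueError, match="decay"):
            vk.extrapolate_bias(make_stats([0.1, 0.2, 0.4]))

    def test_needs_three_levels(self):
        with pytest.raises(ValueError, match="levels"):
            vk.extrapolate_bias(make_stats([0.5]))


class TestOptimalAllocation:
    def test_single_level_is_variance_over_budget(self):
        stats = [MlmcLevelStats(0, 100, 1.0, 4.0)]
        alloc = vk.optimal_allocation(stats, 0.01)
        assert alloc[0] == math.ceil(4.0 / 0.01)

    def test_equal_variance_costs_one_and_two(self):
        stats = [
            MlmcLevelStats(0, 100, 0.0, 1.0),
            MlmcLevelStats(1, 100, 0.0, 1.0),
        ]
        # cost doubles per level, so N_0/N_1 = sqrt(2) before ceilings
        alloc = vk.optimal_allocation(stats, 1e-4)
        assert alloc[0] / alloc[1] == pytest.approx(math.sqrt(2.0), rel=1e-3)

    def test_achieved_variance_within_budget(self):
        stats = [
            MlmcLevelStats(0, 10, 0.0, 5.0),
            MlmcLevelStats(1, 10, 0.0, 1.2),
            MlmcLevelStats(2, 10, 0.0, 0.3),
        ]
        budget = 0.05
        alloc = vk.optimal_allocation(stats, budget)
        achieved = sum(s.var_diff / alloc[s.level] for s in stats)
        assert achieved <= budget * (1 + 1e-12)

    def test_zero_budget_rejected(self):
        with pytest.raises(ValueError, match="budget"):
            vk.optimal_allocation([MlmcLevelStats(0, 10, 0.0, 1.0)], 0.0)


class TestMlmcDriver:
    def test_matches_closed_form_within_budget(self, toy, toy_truth):
        est, stats = vk.mlmc_evppi(toy, "x", 0.02, 4)
        tol = 3 * (est.std_error + abs(est.bias_estimate or 0.0)) + 0.02
        assert est.estimate == pytest.approx(toy_truth[1], abs=tol)
        assert est.ci95[0] <= est.estimate <= est.ci95[1]

    def test_telescopes_to_nested_estimator(self, toy):
        """E[e_0] + sum d_l equals the nested estimator with M = 2^L."""
        est, _ = vk.mlmc_evppi(toy, "x", 0.03, 8)
        level = est.diagnostics["L"]
        nested = vk.evppi_nested_mc(toy, "x", 60_000, 2**level, 9)
        combined = 3 * (est.std_error + nested.std_error)
        assert est.estimate == pytest.approx(nested.estimate, abs=combined)

    def test_huge_epsilon_returns_level_zero(self, toy, toy_truth):
        est, _ = vk.mlmc_evppi(toy, "x", 10 * toy_truth[0], 10)
        assert est.diagnostics["L"] == 0
        assert est.n_inner == 1

    def test_variance_decays_across_levels(self, toy, depression):
        for problem, subset in ((toy, "x"), (depression, "costs_qalys")):
            rng = np.random.default_rng(12)
            stats = []
            for level in (1, 2, 3, 4):
                d = vk.level_difference_samples(problem, subset, level, 3000, rng)
                stats.append(MlmcLevelStats(level, d.size, d.mean(), d.var(ddof=1)))
            beta, _, _ = fit_level_decay(stats, "variance")
            assert beta > 0

    def test_bit_reproducible_given_master_seed(self, toy):
        a, _ = vk.mlmc_evppi(toy, "x", 0.05, 77)
        b, _ = vk.mlmc_evppi(toy, "x", 0.05, 77)
        assert a.estimate == b.estimate
        assert a.std_error == b.std_error
        assert a.total_nb_evaluations == b.total_nb_evaluations

    def test_unreachable_bias_bound_advises_larger_epsilon(self, depression):
        with pytest.raises(ValueError, match="epsilon"):
            vk.mlmc_evppi(depression, "cbt", 0.5, 1, max_level=4)

    def test_non_positive_epsilon_rejected(self, toy):
        with pytest.raises(ValueError, match="positive"):
            vk.mlmc_evppi(toy, "x", -1.0, 0)
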