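"""Distribution primitives: inverse-CDF maps, MVN conditioning, MVN fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import voikit as vk
from voikit.distributions import BetaBlock, MvnBlock, NormalBlock

LORREC_MEAN = np.array([0.99, 1.33])
LORREC_COV = np.array([[0.22, 0.15], [0.15, 0.20]])


def lorrec_block():
    return MvnBlock(("lorrec_2", "lorrec_3"), LORREC_MEAN, LORREC_COV)


class TestInverseCdfTransform:
    def test_normal_median_maps_to_mean(self):
        spec = vk.DistributionSpec([NormalBlock("c", 1000.0, 50.0)])
        assert vk.inverse_cdf_transform([[0.5]], spec)[0, 0] == pytest.approx(1000.0)

    def test_mvn_median_maps_to_mean_vector(self):
        spec = vk.DistributionSpec([lorrec_block()])
        out = vk.inverse_cdf_transform([[0.5, 0.5]], spec)
        np.testing.assert_allclose(out[0], LORREC_MEAN, atol=1e-12)

    def test_standard_normal_upper_quantile(self):
        spec = vk.DistributionSpec([NormalBlock("z", 0.0, 1.0)])
        assert vk.inverse_cdf_transform([[0.975]], spec)[0, 0] == pytest.approx(
            1.95996, abs=1e-4
        )

    def test_boundary_uniforms_stay_finite(self):
        spec = vk.DistributionSpec([NormalBlock("z", 0.0, 1.0), BetaBlock("p", 6, 200)])
        out = spec.transform([[0.0, 1.0], [1.0, 0.0]])
        assert np.all(np.isfinite(out))

    def test_wrong_width_rejected(self):
        spec = vk.DistributionSpec([NormalBlock("z", 0.0, 1.0)])
        with pytest.raises(ValueError, match="width"):
            spec.transform([[0.5, 0.5]])

    def test_non_positive_definite_covariance_names_block(self):
        with pytest.raises(ValueError, match="lorrec"):
            MvnBlock(("lorrec_2", "lorrec_3"), [0, 0], [[1.0, 2.0], [2.0, 1.0]])

    def test_transform_matches_direct_sampling_in_law(self, rng):
        """Pushing iid uniforms through the inverse CDF reproduces each
        marginal law (KS test) and the printed cross-covariance."""
        spec = vk.depression_spec()
        n = 100_000
        draws = spec.transform(rng.random((n, spec.dim)))
        marginals = {
            "p_rec_1": stats.beta(6, 200),
            "p_rel_1": stats.beta(2, 100),
            "lorrec_2": stats.norm(0.99, np.sqrt(0.22)),
            "c_nrec": stats.norm(2500, 125),
            "q_rec": stats.norm(26, 2),
        }
        for name, dist in marginals.items():
            col = draws[:, spec.index(name)]
            assert stats.kstest(col, dist.cdf).pvalue > 1e-3, name
        i, j = spec.index("lorrec_2"), spec.index("lorrec_3")
        cov = np.cov(draws[:, i], draws[:, j])
        np.testing.assert_allclose(cov, LORREC_COV, atol=0.01)


class TestMvnCondition:
    def test_observe_nothing_is_identity(self):
        mean, cov = vk.mvn_condition(LORREC_MEAN, LORREC_COV, [], [])
        np.testing.assert_array_equal(mean, LORREC_MEAN)
        np.testing.assert_array_equal(cov, LORREC_COV)

    def test_conditioning_at_the_mean_preserves_the_mean(self):
        mean, cov = vk.mvn_condition(LORREC_MEAN, LORREC_COV, [0], [0.99])
        assert mean[0] == pytest.approx(1.33)
        # Schur complement: 0.20 - 0.15^2 / 0.22
        assert cov[0, 0] == pytest.approx(0.20 - 0.15**2 / 0.22, abs=1e-12)
        assert cov[0, 0] == pytest.approx(0.09773, abs=1e-5)

    def test_diagonal_covariance_leaves_others_untouched(self):
        mean = np.array([1.0, 2.0, 3.0])
        cov = np.diag([1.0, 4.0, 9.0])
        cmean, ccov = vk.mvn_condition(mean, cov, [1], [10.0])
        np.testing.assert_allclose(cmean, [1.0, 3.0])
        np.testing.assert_allclose(ccov, np.diag([1.0, 9.0]))

    def test_observing_everything_rejected(self):
        with pytest.raises(ValueError, match="proper subset"):
            vk.mvn_condition(LORREC_MEAN, LORREC_COV, [0, 1], [0.9, 1.3])

    def test_against_rejection_band_oracle(self, rng):
        """Exact Gaussian conditioning agrees with brute-force conditioning
        (keep draws whose observed component falls in a narrow band)."""
        a = rng.normal(size=(3, 3))
        cov = a @ a.T + 0.5 * np.eye(3)
        mean = rng.normal(size=3)
        x_obs = mean[0] + 0.3
        cmean, ccov = vk.mvn_condition(mean, cov, [0], [x_obs])
        draws = rng.multivariate_normal(mean, cov, size=600_000)
        band = draws[np.abs(draws[:, 0] - x_obs) < 0.02 * np.sqrt(cov[0, 0])]
        assert band.shape[0] > 2000
        emp_mean = band[:, 1:].mean(axis=0)
        emp_cov = np.cov(band[:, 1:], rowvar=False)
        se = np.sqrt(np.diag(ccov) / band.shape[0])
        np.testing.assert_allclose(emp_mean, cmean, atol=4 * se.max() + 0.01)
        np.testing.assert_allclose(emp_cov, ccov, atol=0.15 * np.abs(ccov).max())

    def test_law_of_total_variance(self, rng):
        """cov(Z) = E[cond cov] + cov(cond mean) under Gaussian conditioning."""
        cov = np.array([[2.0, 0.7, 0.3], [0.7, 1.5, 0.4], [0.3, 0.4, 1.0]])
        mean = np.zeros(3)
        x = rng.normal(0.0, np.sqrt(cov[0, 0]), size=50_000)
        _, ccov = vk.mvn_condition(mean, cov, [0], [0.0])
        gain = cov[1:, 0] / cov[0, 0]
        cmeans = np.outer(x, gain)
        total = ccov + np.cov(cmeans, rowvar=False)
        np.testing.assert_allclose(total, cov[1:, 1:], atol=0.05)


class TestFitMvn:
    def test_constant_columns_zero_covariance(self):
        block = vk.fit_mvn(np.ones((50, 2)), names=("a", "b"), skew_threshold=np.inf)
        np.testing.assert_allclose(block.cov, 0.0, atol=1e-30)

    def test_recovers_known_mvn(self, rng):
        draws = rng.multivariate_normal(LORREC_MEAN, LORREC_COV, size=100_000)
        block = vk.fit_mvn(pd.DataFrame(draws, columns=["lorrec_2", "lorrec_3"]))
        se_mean = np.sqrt(np.diag(LORREC_COV) / draws.shape[0])
        np.testing.assert_allclose(block.mean, LORREC_MEAN, atol=4 * se_mean.max())
        np.testing.assert_allclose(block.cov, LORREC_COV, atol=0.01)
        assert block.names == ("lorrec_2", "lorrec_3")

    def test_exact_moment_table_reproduces_printed_posterior(self, rng):
        # whiten-and-recolor a sample so its moments match the printed
        # posterior exactly, then check the fit round-trips
        raw = rng.standard_normal((5000, 2))
        raw -= raw.mean(axis=0)
        white = raw @ np.linalg.inv(np.linalg.cholesky(np.cov(raw, rowvar=False)).T)
        table = white @ np.linalg.cholesky(LORREC_COV).T + LORREC_MEAN
        block = vk.fit_mvn(table)
        np.testing.assert_allclose(block.mean, LORREC_MEAN, atol=1e-10)
        np.testing.assert_allclose(block.cov, LORREC_COV, atol=1e-10)

    def test_skewed_marginal_warns(self, rng):
        table = np.column_stack([rng.lognormal(0, 1.5, 5000), rng.normal(0, 1, 5000)])
        with pytest.warns(UserWarning, match="skew"):
            vk.fit_mvn(table)

    @pytest.mark.parametrize(
        "table, err",
        [
            (np.ones((2, 3)), "more draws"),
            (np.array([[1.0, np.nan]] * 9 + [[0.0, 1.0]]), "non-finite"),
        ],
    )
    def test_invalid_tables_rejected(self, table, err):
        with pytest.raises(ValueError, match=err):
            vk.fit_mvn(table)


class TestConditionalSampler:
    def test_independent_blocks_keep_their_marginals(self, depression, rng):
        """Conditioning on costs/QALYs leaves the event-probability
        parameters at their unconditional marginals."""
        sampler = depression.conditional_sampler("costs_qalys")
        x = sampler.marginal_x().sample(1, rng)
        z = sampler.sample_full(np.repeat(x, 1, axis=0), 50_000, rng)[0]
        spec = depression.params
        p1 = z[:, spec.index("p_rec_1")]
        assert p1.mean() == pytest.approx(6 / 206, rel=0.05)
        lr2 = z[:, spec.index("lorrec_2")]
        assert lr2.mean() == pytest.approx(0.99, abs=4 * np.sqrt(0.22 / 50_000))
        assert lr2.std() == pytest.approx(np.sqrt(0.22), rel=0.05)

    def test_split_mvn_block_conditions_exactly(self, depression, rng):
        """Fixing the CBT log odds ratios at their means leaves the
        antidepressant components at their marginal means with the Schur
        complement variance."""
        sampler = depression.conditional_sampler("cbt")
        x = np.array([[0.99, -1.48]])  # canonical order: lorrec_2, lorrel_2
        z = sampler.sample_full(x, 200_000, rng)[0]
        spec = depression.params
        lr3 = z[:, spec.index("lorrec_3")]
        ll3 = z[:, spec.index("lorrel_3")]
        cond_var = 0.20 - 0.15**2 / 0.22
        assert lr3.mean() == pytest.approx(1.33, abs=4 * np.sqrt(cond_var / 200_000))
        assert lr3.var() == pytest.approx(cond_var, rel=0.03)
        assert ll3.mean() == pytest.approx(-0.40, abs=0.01)
        assert ll3.var() == pytest.approx(0.11 - 0.05**2 / 0.14, rel=0.03)

    def test_unknown_subset_rejected(self, depression):
        with pytest.raises(KeyError, match="unknown subset"):
            depression.conditional_sampler("nonexistent")
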