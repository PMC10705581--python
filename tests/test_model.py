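"""Contrast vectors, the mean-difference statistic, and the perturbation line."""

import numpy as np
import pytest

from postclust import (
    GaussianModel,
    TestSpec,
    contrast_vector,
    equicorrelated_sigma,
    perturb_data,
    perturbation_line,
)
from postclust import test_statistic as mean_diff_stat
from postclust.model import InvalidSpecError


class TestContrastVector:
    def test_two_against_one(self):
        c = contrast_vector(4, TestSpec({0, 1}, {2}, 0))
        assert np.allclose(c.nu, [0.5, 0.5, -1.0, 0.0])
        assert c.nu_sq_norm == pytest.approx(1.5)

    def test_singleton_clusters(self):
        c = contrast_vector(2, TestSpec({0}, {1}, 0))
        assert np.allclose(c.nu, [1.0, -1.0])
        assert c.nu_sq_norm == pytest.approx(2.0)

    def test_balanced_squared_norm_matches_explicit_vector(self):
        c = contrast_vector(150, TestSpec(range(75), range(75, 150), 0))
        assert c.nu_sq_norm == pytest.approx(2.0 / 75)
        assert float(c.nu @ c.nu) == pytest.approx(c.nu_sq_norm)
        assert c.nu.sum() == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "ga,gb",
        [({0, 1}, {1, 2}), ({0}, set()), (set(), {1})],
    )
    def test_invalid_groups_rejected(self, ga, gb):
        with pytest.raises(InvalidSpecError):
            TestSpec(ga, gb, 0)

    def test_out_of_range_indices_rejected(self):
        with pytest.raises(InvalidSpecError):
            contrast_vector(3, TestSpec({0}, {5}, 0))


class TestStatistic:
    def test_constant_column_gives_zero(self):
        x = np.ones((4, 2))
        c = contrast_vector(4, TestSpec({0, 1}, {2, 3}, 1))
        assert mean_diff_stat(x, c, 1) == pytest.approx(0.0)

    def test_hand_mean_difference(self):
        x = np.array([[1.0], [1.0], [0.0], [0.0]])
        c = contrast_vector(4, TestSpec({0, 1}, {2, 3}, 0))
        assert mean_diff_stat(x, c, 0) == pytest.approx(1.0)

    def test_matches_bruteforce_group_means(self):
        rng = np.random.default_rng(42)
        x = rng.standard_normal((10, 3))
        ga, gb = [0, 3, 7], [1, 2, 9]
        c = contrast_vector(10, TestSpec(ga, gb, 2))
        expected = x[ga, 2].mean() - x[gb, 2].mean()
        assert mean_diff_stat(x, c, 2) == pytest.approx(expected, rel=1e-12)


def _make_line(seed, n=12, q=4, rho=0.3, j=1):
    rng = np.random.default_rng(seed)
    sigma = equicorrelated_sigma(q, rho)
    x = rng.multivariate_normal(np.zeros(q), sigma, size=n)
    c = contrast_vector(n, TestSpec(range(4), range(4, 9), j))
    return x, sigma, c, perturbation_line(x, sigma, c, j)


class TestPerturbation:
    @pytest.mark.parametrize("seed", range(5))
    def test_contract_properties(self, seed):
        """Statistic pinned to phi; identity at phi_obs; zero-contrast rows
        fixed; cross-feature statistics move with slope Sigma_jj'/Sigma_jj."""
        j = 1
        x, sigma, c, line = _make_line(seed, j=j)
        assert line.direction[j] == 1.0
        assert np.allclose(perturb_data(x, line, line.phi_obs), x, rtol=1e-10, atol=1e-12)
        for phi in (-3.0, 0.0, 1.7, line.phi_obs + 5):
            xp = perturb_data(x, line, phi)
            assert mean_diff_stat(xp, c, j) == pytest.approx(phi, rel=1e-10, abs=1e-10)
            fixed = c.nu == 0
            assert np.array_equal(xp[fixed], x[fixed])
            for jp in range(x.shape[1]):
                expected = mean_diff_stat(x, c, jp) + (phi - line.phi_obs) * (
                    sigma[j, jp] / sigma[j, j]
                )
                assert mean_diff_stat(xp, c, jp) == pytest.approx(expected, rel=1e-10, abs=1e-10)

    def test_diagonal_covariance_moves_only_tested_column(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((8, 3))
        c = contrast_vector(8, TestSpec({0, 1}, {2, 3}, 0))
        line = perturbation_line(x, np.diag([2.0, 1.0, 0.5]), c, 0)
        xp = perturb_data(x, line, line.phi_obs + 4.0)
        assert np.array_equal(xp[:, 1:], x[:, 1:])
        assert not np.array_equal(xp[:, 0], x[:, 0])

    def test_correlated_feature_slope(self):
        """With Sigma_11 = Sigma_22 = 0.2 and Sigma_12 = 0.08 the companion
        feature's statistic moves with slope Sigma_12/Sigma_11 = 0.4."""
        rng = np.random.default_rng(0)
        x = rng.standard_normal((10, 2))
        sigma = np.array([[0.2, 0.08], [0.08, 0.2]])
        c = contrast_vector(10, TestSpec(range(5), range(5, 10), 0))
        line = perturbation_line(x, sigma, c, 0)
        s1 = mean_diff_stat(perturb_data(x, line, 1.0), c, 1)
        s0 = mean_diff_stat(perturb_data(x, line, 0.0), c, 1)
        assert (s1 - s0) == pytest.approx(0.08 / 0.2, abs=1e-14)

    def test_complement_is_constant_along_line(self):
        """The orthogonalized remainder (data minus its statistic-carrying
        rank-one component) does not vary with the perturbation parameter."""
        x, sigma, c, line = _make_line(9, j=2)

        def complement(xm):
            stat = mean_diff_stat(xm, c, 2)
            return xm - stat * np.outer(c.nu / c.nu_sq_norm, line.direction)

        u1 = complement(perturb_data(x, line, -4.2))
        u2 = complement(perturb_data(x, line, 3.3))
        assert np.allclose(u1, u2, rtol=1e-10, atol=1e-12)
        assert np.allclose(u1, complement(x), rtol=1e-10, atol=1e-12)


def test_statistic_uncorrelated_with_complement():
    """Under the Gaussian model the statistic and every entry of the held-fixed
    complement are uncorrelated (they are independent in theory)."""
    rng = np.random.default_rng(2024)
    n, q, j = 6, 3, 1
    sigma = equicorrelated_sigma(q, 0.4)
    c = contrast_vector(n, TestSpec({0, 1, 2}, {3, 4}, j))
    model = GaussianModel(mu=np.zeros((n, q)), sigma=sigma)
    reps = 2000
    stats = np.empty(reps)
    us = np.empty((reps, n * q))
    coef = np.outer(c.nu / c.nu_sq_norm, sigma[:, j] / sigma[j, j])
    for r in range(reps):
        xr = model.sample(rng)
        s = float(c.nu @ xr[:, j])
        stats[r] = s
        us[r] = (xr - s * coef).ravel()
    sd_u = us.std(axis=0)
    keep = sd_u > 1e-12  # complement entries of moved rows in feature j are constant
    corr = ((us[:, keep] - us[:, keep].mean(0)) * (stats - stats.mean())[:, None]).mean(0)
    corr /= sd_u[keep] * stats.std()
    assert np.max(np.abs(corr)) < 0.08


class TestGaussianModel:
    def test_rejects_asymmetric_and_non_pd(self):
        with pytest.raises(ValueError):
            GaussianModel(mu=np.zeros((2, 2)), sigma=np.array([[1.0, 0.5], [0.2, 1.0]]))
        with pytest.raises(ValueError):
            GaussianModel(mu=np.zeros((2, 2)), sigma=np.array([[1.0, 1.0], [1.0, 1.0]]))

    def test_rejects_dimension_mismatch(self):
        with pytest.raises(ValueError):
            GaussianModel(mu=np.zeros((5, 3)), sigma=np.eye(2))

    def test_sample_shape_and_seeded_determinism(self):
        m = GaussianModel(mu=np.zeros((4, 2)), sigma=np.eye(2))
        a = m.sample(np.random.default_rng(5))
        b = m.sample(np.random.default_rng(5))
        assert a.shape == (4, 2)
        assert np.array_equal(a, b)
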