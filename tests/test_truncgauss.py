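"""Truncated-Gaussian CDF and the two-sided selective p-value.

The independent oracle is adaptive quadrature of the Gaussian density with a
per-interval exponential shift, so that supports ten standard deviations into
a tail keep full relative precision.
"""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from postclust import IntervalUnion, TruncatedGaussian, selective_p, trunc_cdf
from postclust.truncgauss import DegenerateSupportError


def _interval_mass(lo, hi):
    """High-precision standard-normal mass of [lo, hi] by shifted quadrature."""
    if hi <= lo:
        return 0.0
    z0 = min(max(0.0, lo), hi)  # point of the interval nearest the mean

    def f(z):
        return math.exp(-0.5 * (z - z0) * (z + z0)) / math.sqrt(2 * math.pi)

    val, _ = quad(f, lo, hi, epsabs=1e-300, epsrel=1e-13, limit=400)
    return math.exp(-0.5 * z0 * z0) * val


def oracle_cdf(t, mean, sd, support):
    num = den = 0.0
    for lo, hi in support:
        zl, zh = (lo - mean) / sd, (hi - mean) / sd
        den += _interval_mass(zl, zh)
        num += _interval_mass(zl, min(zh, (t - mean) / sd))
    return num / den


def oracle_selective(z, sd, support):
    num = den = 0.0
    az = abs(z)
    for lo, hi in support:
        den += _interval_mass(lo / sd, hi / sd)
        num += _interval_mass(max(lo, az) / sd, hi / sd)
        num += _interval_mass(lo / sd, min(hi, -az) / sd)
    return num / den


class TestTruncCdf:
    def test_reals_reduces_to_normal_cdf(self):
        tg = TruncatedGaussian(0.7, 2.0, IntervalUnion.reals())
        for t in (-3, 0, 1.5):
            assert trunc_cdf(t, tg) == pytest.approx(norm.cdf((t - 0.7) / 2.0), abs=1e-14)

    def test_left_edge_is_zero(self):
        tg = TruncatedGaussian(0.0, 1.0, IntervalUnion([(0, np.inf)]))
        assert trunc_cdf(0.0, tg) == pytest.approx(0.0, abs=1e-300)
        assert trunc_cdf(-1.0, tg) == 0.0

    def test_symmetric_support_half_at_center(self):
        s = IntervalUnion([(-2, -1), (1, 2)])
        tg = TruncatedGaussian(0.0, 1.0, s)
        assert trunc_cdf(0.0, tg) == pytest.approx(0.5, abs=1e-14)

    def test_far_tail_support_matches_quadrature(self):
        s = IntervalUnion([(10, 11)])
        tg = TruncatedGaussian(0.0, 1.0, s)
        got = trunc_cdf(10.5, tg)
        assert got == pytest.approx(oracle_cdf(10.5, 0, 1, s), abs=1e-12)
        assert 0 < got < 1

    def test_monotone_and_clamped(self):
        s = IntervalUnion([(-1, 0.5), (2, 3)])
        tg = TruncatedGaussian(0.2, 0.7, s)
        ts = np.linspace(-2, 4, 40)
        vals = [trunc_cdf(t, tg) for t in ts]
        assert np.all(np.diff(vals) >= -1e-14)
        assert vals[0] == 0.0 and vals[-1] == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_quadrature_including_deep_tails(self, seed):
        """200 randomized (t, mean, sd, support) cases, with supports pushed
        out to +-12 null standard deviations, agree with quadrature to 1e-10."""
        rng = np.random.default_rng(seed)
        for _ in range(25):
            mean = rng.normal()
            sd = rng.uniform(0.3, 3.0)
            center = rng.uniform(-12, 12) * sd + mean
            k = int(rng.integers(1, 4))
            pts = np.sort(center + rng.uniform(-2, 2, size=2 * k) * sd)
            s = IntervalUnion([(pts[2 * i], pts[2 * i + 1]) for i in range(k)])
            if s.is_empty:
                continue
            tg = TruncatedGaussian(mean, sd, s)
            t = rng.uniform(pts[0] - sd, pts[-1] + sd)
            assert trunc_cdf(t, tg) == pytest.approx(
                oracle_cdf(t, mean, sd, s), abs=1e-10
            )

    def test_extreme_tail_support_still_resolves(self):
        # log-space masses keep ratios meaningful even when the support mass
        # itself is far below the smallest positive double
        tg = TruncatedGaussian(0.0, 1.0, IntervalUnion([(45, 46)]))
        v = trunc_cdf(45.2, tg)
        assert 0.9 < v < 1.0  # nearly all conditional mass is below 45.2

    def test_degenerate_support_raises(self):
        with pytest.raises(DegenerateSupportError):
            TruncatedGaussian(0.0, 1.0, IntervalUnion.empty())
        tg = TruncatedGaussian(0.0, 1.0, IntervalUnion([(1e200, 2e200)]))
        with pytest.raises(DegenerateSupportError):
            trunc_cdf(1.5e200, tg)


class TestSelectiveP:
    def test_unconstrained_reduces_to_two_sided_z(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            z = rng.normal(scale=3)
            sd = rng.uniform(0.2, 4)
            p = selective_p(z, sd, IntervalUnion.reals())
            assert p == pytest.approx(2 * norm.sf(abs(z) / sd), abs=1e-12)

    def test_support_entirely_as_extreme_gives_one(self):
        z = 1.3
        s = IntervalUnion([(-np.inf, -abs(z)), (abs(z), np.inf)])
        assert selective_p(z, 1.0, s) == pytest.approx(1.0, abs=1e-14)

    def test_bounded_support_matches_quadrature(self):
        s = IntervalUnion([(-3, 3)])
        assert selective_p(2.0, 1.0, s) == pytest.approx(
            oracle_selective(2.0, 1.0, s), abs=1e-12
        )

    def test_multi_interval_matches_quadrature(self):
        s = IntervalUnion([(-4, -0.5), (1, 2.5), (5, 6)])
        got = selective_p(2.0, 1.3, s)
        assert got == pytest.approx(oracle_selective(2.0, 1.3, s), abs=1e-12)
        assert 0 <= got <= 1

    def test_scale_invariance(self):
        s = IntervalUnion([(-1, 2.2), (3, 4)])
        p0 = selective_p(1.8, 0.9, s)
        for c in (1e-3, 7.0, 1e4):
            assert selective_p(c * 1.8, c * 0.9, s.scale(c)) == pytest.approx(p0, rel=1e-10)

    def test_statistic_outside_support_raises(self):
        with pytest.raises(ValueError):
            selective_p(5.0, 1.0, IntervalUnion([(-1, 1)]))

    def test_matches_rejection_sampling(self):
        """Empirical exceedance of |z| under the truncated null matches the
        p-value within 3 binomial standard errors."""
        rng = np.random.default_rng(12345)
        sd = 1.4
        s = IntervalUnion([(-1.0, 0.5), (1.0, 2.8)])
        z_obs = 1.6
        p = selective_p(z_obs, sd, s)
        draws = rng.normal(0, sd, size=400_000)
        mask = np.zeros(draws.size, dtype=bool)
        for lo, hi in s:
            mask |= (draws >= lo) & (draws <= hi)
        inside = draws[mask]
        assert inside.size > 5000
        emp = np.mean(np.abs(inside) >= abs(z_obs))
        se = math.sqrt(emp * (1 - emp) / inside.size)
        assert abs(p - emp) <= 3 * se
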