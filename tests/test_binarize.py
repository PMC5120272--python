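"""The four-step density-based threshold heuristic."""

import numpy as np
import pytest
from scipy.stats import norm

from dnflogic.binarize import (binarize, estimate_density, find_theta,
                               fit_resistant_population, threshold_from_tail,
                               upsample, ResponseBinarizer)


class TestUpsample:
    def test_point_count(self):
        cloud = upsample([0.0, 1.0, 2.0], [-.5, .5, 1.5], [.5, 1.5, 2.5],
                         draws_per_sample=1000, seed=0)
        assert len(cloud) == 3000

    def test_zero_width_ci_uses_sd_floor(self):
        cloud = upsample([5.0], [5.0], [5.0], draws_per_sample=2000, seed=0)
        assert np.std(cloud) == pytest.approx(0.1, rel=0.1)

    def test_draw_mean_recovers_value(self):
        # CLT: sample mean within 4 sd / sqrt(1000) of the measurement
        value, sd = 2.0, 0.8
        cloud = upsample([value], [value - sd], [value + sd],
                         draws_per_sample=1000, seed=1)
        assert abs(cloud.mean() - value) < 4 * sd / np.sqrt(1000)

    def test_reproducible_under_seed(self):
        a = upsample([0.0, 1.0], seed=42)
        b = upsample([0.0, 1.0], seed=42)
        np.testing.assert_array_equal(a, b)


class TestEstimateDensity:
    def test_unit_integral(self):
        rng = np.random.default_rng(2)
        grid, f = estimate_density(rng.normal(size=5000))
        assert np.trapezoid(f, grid) == pytest.approx(1.0, abs=1e-6)
        assert (f >= 0).all()

    def test_identical_points_give_single_kernel_bump(self):
        grid, f = estimate_density(np.full(100, 3.0), bandwidth=0.5)
        assert grid[np.argmax(f)] == pytest.approx(3.0, abs=0.1)
        # spread matches the kernel sd
        var = np.trapezoid(f * (grid - 3.0) ** 2, grid)
        assert np.sqrt(var) == pytest.approx(0.5, rel=0.1)

    def test_separated_clusters_yield_two_maxima(self):
        rng = np.random.default_rng(3)
        pts = np.concatenate([rng.normal(-6, 0.5, 2000), rng.normal(0, 0.5, 8000)])
        grid, f = estimate_density(pts)
        interior = (f[1:-1] > f[:-2]) & (f[1:-1] > f[2:])
        maxima = grid[1:-1][interior]
        assert len(maxima) == 2
        assert min(abs(maxima + 6)) < 0.5 and min(abs(maxima)) < 0.5

    def test_rejects_too_few_points(self):
        with pytest.raises(ValueError):
            estimate_density([1.0])


class TestFindTheta:
    def test_bimodal_density_uses_rule_i_at_antimode(self):
        grid = np.linspace(-9, 4, 2000)
        f = 0.2 * norm.pdf(grid, -5, 1) + 0.8 * norm.pdf(grid, 0, 1)
        f /= np.trapezoid(f, grid)
        mu = grid[np.argmax(f)]
        theta, rule = find_theta(grid, f, mu)
        assert rule == "i"
        # independent oracle: the inter-mode density minimum
        between = (grid > -5) & (grid < 0)
        antimode = grid[between][np.argmin(f[between])]
        assert theta == pytest.approx(antimode, abs=0.05)

    def test_monotone_shoulder_uses_rule_ii(self):
        # left component broad enough that no stationary point exists below
        # the mode, but an inflection with f'' = 0, f''' > 0 does
        grid = np.linspace(-6.8, 2.4, 4000)
        f = 0.1 * norm.pdf(grid, -2, 1.2) + 0.9 * norm.pdf(grid, 0, 0.6)
        f /= np.trapezoid(f, grid)
        mu = grid[np.argmax(f)]
        h = grid[1] - grid[0]
        d1 = np.gradient(f, h)
        assert not np.any(np.diff(np.sign(d1[grid < mu - 2 * h])) != 0)  # no f'=0
        theta, rule = find_theta(grid, f, mu)
        assert rule == "ii"
        d3 = np.gradient(np.gradient(d1, h), h)
        assert np.interp(theta, grid, np.gradient(d1, h)) == pytest.approx(0, abs=1e-3)
        assert np.interp(theta, grid, d3) > 0

    def test_unimodal_density_falls_back_to_range_minimum(self):
        grid = np.linspace(-4, 4, 1000)
        f = norm.pdf(grid)
        f /= np.trapezoid(f, grid)
        theta, rule = find_theta(grid, f, 0.0)
        assert rule == "iii"
        assert theta == grid[0]


class TestResistantPopulation:
    def test_median_distance(self):
        mu = 10.0
        assert fit_resistant_population([7.0, 8.0, 9.0], theta=6.0, mu=mu) == 2.0

    def test_single_point(self):
        assert fit_resistant_population([9.5], theta=9.0, mu=10.0) == 0.5

    def test_half_normal_median(self):
        # for symmetric N(mu, 1), the median |x - mu| over [mu-4, mu] is the
        # half-normal median Phi^-1(0.75) ~ 0.6745
        rng = np.random.default_rng(4)
        pts = rng.normal(0.0, 1.0, 100_000)
        sigma = fit_resistant_population(pts, theta=-4.0, mu=0.0)
        assert sigma == pytest.approx(norm.ppf(0.75), abs=0.02)

    def test_empty_interval_raises(self):
        with pytest.raises(ValueError, match="theta"):
            fit_resistant_population([0.0], theta=5.0, mu=6.0)


@pytest.mark.parametrize("mu, sigma, t, expected", [
    (0.0, 1.0, 0.05, -1.6449),
    (0.0, 1.0, 0.5, 0.0),
    (2.0, 0.5, 0.05, 1.1776),
])
def test_threshold_is_normal_quantile(mu, sigma, t, expected):
    assert threshold_from_tail(mu, sigma, t) == pytest.approx(expected, abs=1e-3)


def test_threshold_rejects_bad_tail():
    with pytest.raises(ValueError):
        threshold_from_tail(0.0, 1.0, 1.5)


class TestBinarizePipeline:
    def test_recovers_planted_mixture_split(self):
        rng = np.random.default_rng(5)
        comp = rng.random(400) < 0.10
        z = np.where(comp, rng.normal(-5, 1, 400), rng.normal(0, 1, 400))
        res = binarize(z, z - 0.3, z + 0.3, seed=6)
        assert -5 < res.b < 0
        assert (z[comp] < res.b).mean() > 0.95

    def test_threshold_monotone_in_t(self):
        rng = np.random.default_rng(7)
        comp = rng.random(300) < 0.12
        z = np.where(comp, rng.normal(-4, 1, 300), rng.normal(0, 1, 300))
        bs = [binarize(z, t=t, seed=8).b for t in (0.03, 0.05, 0.07)]
        assert bs[0] < bs[1] < bs[2]

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(9)
        z = np.concatenate([rng.normal(-4, 1, 40), rng.normal(0, 1, 260)])
        assert binarize(z, seed=3).b == binarize(z, seed=3).b

    def test_shift_equivariance(self):
        rng = np.random.default_rng(10)
        z = np.concatenate([rng.normal(-4, 1, 40), rng.normal(0, 1, 260)])
        b0 = binarize(z, seed=4).b
        b7 = binarize(z + 7.0, seed=4).b
        assert b7 - b0 == pytest.approx(7.0, abs=0.05)

    def test_single_draw_no_ci_still_valid(self):
        rng = np.random.default_rng(11)
        z = np.concatenate([rng.normal(-4, 1, 40), rng.normal(0, 1, 260)])
        res = binarize(z, draws_per_sample=1, seed=5)
        assert np.isfinite(res.b)

    def test_transformer_interface(self):
        rng = np.random.default_rng(12)
        z = np.concatenate([rng.normal(-5, 1, 50), rng.normal(0, 1, 250)])
        tf = ResponseBinarizer(seed=1)
        labels = tf.fit_transform(z)
        assert set(np.unique(labels)) == {0, 1}
        assert tf.get_params()["t"] == 0.05
        assert labels.sum() == (z < tf.b_).sum()
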