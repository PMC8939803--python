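"""Tests for rejection ABC and simulated-annealing ABC on tractable toys."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

import plateletabc as pa
from plateletabc.inference import (
    PriorSpec,
    rejection_from_table,
    rejection_sampler,
    sabc_sampler,
)


def toy_prior(dim=7):
    from plateletabc.inference import DEFAULT_PRIOR_BOUNDS

    return PriorSpec(bounds=DEFAULT_PRIOR_BOUNDS[:dim], names=pa.PARAM_NAMES[:dim])


class TestPriorSpec:
    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            PriorSpec(bounds=((1.0, 0.5),) * 7)

    def test_sample_and_contains(self):
        prior = toy_prior()
        draws = prior.sample(np.random.default_rng(0), 100)
        assert prior.contains(draws).all()

    def test_with_bounds_replaces_named_parameter(self):
        prior = toy_prior().with_bounds(aggregation_rate=(1.0, 2.0))
        k = pa.PARAM_NAMES.index("aggregation_rate")
        assert prior.bounds[k] == (1.0, 2.0)


class TestRejection:
    def test_epsilon_infinity_recovers_prior(self):
        """With an all-accepting tolerance the accepted draws are prior
        draws: per-coordinate KS against the uniform prior at Z = 500."""
        prior = toy_prior()
        sim = lambda theta, rng: theta  # noqa: E731 - trivial pseudo-model
        dist = lambda x: 0.0  # noqa: E731
        samples, _, n_drawn = rejection_sampler(
            sim, dist, prior, epsilon=np.inf, n_accept=500, max_draws=500,
            rng=np.random.default_rng(42),
        )
        assert n_drawn == 500
        for k in range(prior.dim):
            lo, hi = prior.bounds[k]
            p = stats.kstest(samples[:, k], stats.uniform(lo, hi - lo).cdf).pvalue
            assert p > 0.01

    def test_degenerate_prior_returns_point_mass(self):
        theta_star = 2.0
        prior = PriorSpec(bounds=((theta_star, theta_star + 1e-12),), names=("x",))
        sim = lambda theta, rng: theta  # noqa: E731
        dist = lambda x: abs(float(x[0]) - theta_star)  # noqa: E731
        samples, _, _ = rejection_sampler(
            sim, dist, prior, epsilon=1.0, n_accept=20, max_draws=100,
            rng=np.random.default_rng(0),
        )
        np.testing.assert_allclose(samples, theta_star, atol=1e-9)

    def test_indicator_kernel_concentrates_with_small_epsilon(self):
        """Toy deterministic model y = theta: accepted samples lie exactly
        in (y0 - eps, y0 + eps)."""
        prior = PriorSpec(bounds=((0.0, 10.0),), names=("x",))
        y0, eps = 4.0, 0.25
        sim = lambda theta, rng: theta  # noqa: E731
        dist = lambda x: abs(float(x[0]) - y0)  # noqa: E731
        samples, dists, _ = rejection_sampler(
            sim, dist, prior, epsilon=eps, n_accept=50, max_draws=20_000,
            rng=np.random.default_rng(1),
        )
        assert np.all(np.abs(samples[:, 0] - y0) < eps)
        assert np.all(dists < eps)

    def test_zero_acceptances_raise_with_advice(self):
        prior = PriorSpec(bounds=((0.0, 1.0),), names=("x",))
        sim = lambda theta, rng: theta  # noqa: E731
        dist = lambda x: 10.0  # noqa: E731
        with pytest.raises(RuntimeError, match="epsilon"):
            rejection_sampler(sim, dist, prior, epsilon=1.0, n_accept=5,
                              max_draws=50, rng=np.random.default_rng(0))

    def test_acceptance_rate_monotone_in_epsilon(self):
        """On a fixed stream of (theta, distance) pairs the acceptance rate
        is non-decreasing in epsilon."""
        rng = np.random.default_rng(3)
        dists = rng.random(1000)
        rates = [(dists < eps).mean() for eps in (0.1, 0.3, 0.5, 0.9)]
        assert all(a <= b for a, b in zip(rates, rates[1:]))


class TestSABC:
    def _gaussian_toy(self, n_particles, n_generations, seed, sigma=1.0, y0=5.0):
        prior = PriorSpec(bounds=((0.0, 10.0),), names=("mu",))
        rng = np.random.default_rng(seed)

        def sim(theta, rng_):
            return np.array([theta[0] + sigma * rng_.standard_normal()])

        def dist(x):
            return abs(float(x[0]) - y0)

        return sabc_sampler(sim, dist, prior, n_particles, n_generations, rng)

    def test_gaussian_conjugate_posterior_mean(self):
        """Gaussian location model with known variance and a flat prior:
        the posterior is symmetric about the observation, so the SABC
        population mean must match it within 3 Monte-Carlo SEs."""
        samples, dists, _ = self._gaussian_toy(510, 20, seed=0)
        post_mean = samples.mean()
        se = samples.std() / np.sqrt(len(samples))
        assert abs(post_mean - 5.0) < 3 * se + 0.05

    def test_median_distance_anneals(self):
        """The generation-median distance decreases from start to finish
        and the schedule is strictly decreasing."""
        samples, dists, schedule = self._gaussian_toy(128, 10, seed=1)
        assert np.all(np.diff(schedule) < 0)
        # final population distances sit well below the prior-draw scale
        prior_scale = 10.0 / 4  # mean |u - y0| for u ~ U(0,10), y0 = 5
        assert np.median(dists) < prior_scale

    def test_same_seed_same_population(self):
        s1, d1, _ = self._gaussian_toy(64, 6, seed=7)
        s2, d2, _ = self._gaussian_toy(64, 6, seed=7)
        np.testing.assert_array_equal(s1, s2)
        np.testing.assert_array_equal(d1, d2)

    def test_samples_stay_in_prior_support(self):
        samples, _, _ = self._gaussian_toy(64, 8, seed=2)
        assert np.all(samples >= 0.0)
        assert np.all(samples <= 10.0)

    def test_population_collapse_warns(self):
        prior = PriorSpec(bounds=((0.0, 1e-12),), names=("x",))
        sim = lambda theta, rng: theta  # noqa: E731
        dist = lambda x: float(x[0])  # noqa: E731
        with pytest.warns(RuntimeWarning, match="collapsed"):
            sabc_sampler(sim, dist, prior, 8, 2, np.random.default_rng(0))


class TestPlateletFrontEnds:
    def test_abc_rejection_on_simulator(self, fast_config, study_prior):
        """Online rejection ABC against the deposition model returns valid
        in-support samples with provenance."""
        observed = pa.simulate(
            pa.DepositionParams(0.5, 1.0, 0.2, 3e-3, 3e-4, 1.5e-3, 6e-4),
            fast_config, seed=5,
        )
        post = pa.abc_rejection(
            observed, study_prior, None, fast_config,
            epsilon=np.inf, n_accept=15, max_draws=15, seed=0,
        )
        assert len(post) == 15
        assert study_prior.contains(post.samples).all()
        assert post.acceptance_rate == 1.0

    def test_table_rejection_matches_explicit_quantile(self, fast_table, fast_config):
        observed = pa.simulate(
            pa.DepositionParams(0.5, 1.0, 0.2, 3e-3, 3e-4, 1.5e-3, 6e-4),
            fast_config, seed=6,
        )
        fdd = pa.FullDataDistance.from_table(fast_table)
        post = rejection_from_table(observed, fast_table, fdd, n_accept=30)
        assert len(post) == 30
        # the implied epsilon equals the worst accepted distance
        assert post.epsilon_schedule[0] == pytest.approx(post.distances.max())
        # and an epsilon-based call with that tolerance accepts a superset
        post_eps = rejection_from_table(
            observed, fast_table, fdd, epsilon=float(post.epsilon_schedule[0] + 1e-9)
        )
        assert len(post_eps) >= 30

    def test_sabc_from_table_improves_distances(self, fast_table, fast_config):
        """Annealing from the table population must not worsen the median
        distance, and usually improves it."""
        observed = pa.simulate(
            pa.DepositionParams(0.5, 1.0, 0.2, 3e-3, 3e-4, 1.5e-3, 6e-4),
            fast_config, seed=8,
        )
        fdd = pa.FullDataDistance.from_table(fast_table)
        post0 = rejection_from_table(observed, fast_table, fdd, n_accept=32)
        post1 = pa.sabc_from_table(
            observed, fast_table, fdd, fast_config,
            n_particles=32, n_generations=4, seed=0,
        )
        assert np.median(post1.distances) <= np.median(post0.distances) + 1e-9
        assert fast_table.prior.contains(post1.samples).all()
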