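"""Tests for the sequential Poisson-intensity machinery and the APO rule."""

import math

import numpy as np
import pytest
from scipy import integrate, optimize

from linexest.core import (GammaDist, LinexParams, bayes_estimate_gamma,
                           numeric_bayes_oracle, posterior_linex_risk_gamma)
from linexest import poisson


@pytest.fixture
def two_event_path():
    return poisson.PoissonPath(event_times=np.array([0.5, 2.0]), horizon=10.0)


class TestPath:
    def test_validation(self):
        with pytest.raises(ValueError):
            poisson.PoissonPath(np.array([2.0, 1.0]), horizon=5.0)
        with pytest.raises(ValueError):
            poisson.PoissonPath(np.array([6.0]), horizon=5.0)

    def test_count(self, two_event_path):
        assert two_event_path.count_at(0.0) == 0
        assert two_event_path.count_at(0.5) == 1  # right-continuous
        assert two_event_path.count_at(9.0) == 2


class TestSimulatePath:
    def test_deterministic_under_seed(self):
        p1 = poisson.simulate_path(2.0, 10.0, seed=42)
        p2 = poisson.simulate_path(2.0, 10.0, seed=42)
        np.testing.assert_array_equal(p1.event_times, p2.event_times)

    def test_tiny_intensity_gives_empty_path(self):
        p = poisson.simulate_path(1e-12, 1.0, seed=0)
        assert p.event_times.size == 0

    def test_mean_rate(self, rng):
        theta, horizon, reps = 1.5, 20.0, 2000
        counts = np.array([poisson.simulate_path(theta, horizon, rng)
                           .event_times.size for _ in range(reps)])
        rate = counts / horizon
        se = rate.std(ddof=1) / math.sqrt(reps)
        assert abs(rate.mean() - theta) < 3 * se

    def test_interevent_gaps_exponential_moments(self, rng):
        theta = 2.0
        path = poisson.simulate_path(theta, 5000.0, rng)
        gaps = np.diff(np.concatenate(([0.0], path.event_times)))
        n = gaps.size
        assert abs(gaps.mean() - 1 / theta) < 3 * gaps.std(ddof=1) / math.sqrt(n)
        # exponential: sd == mean
        assert gaps.std(ddof=1) == pytest.approx(gaps.mean(), rel=0.05)


class TestPosteriorAt:
    def test_prior_at_time_zero(self, two_event_path):
        post = poisson.posterior_at(1.0, 1.0, two_event_path, 0.0)
        assert (post.k, post.r) == (1.0, 1.0)

    def test_conjugate_update(self, two_event_path):
        post = poisson.posterior_at(1.0, 1.0, two_event_path, 1.0)
        assert post.k == pytest.approx(2.0)
        assert post.r == pytest.approx(2.0)  # rate t + 1/beta

    def test_outside_horizon_rejected(self, two_event_path):
        with pytest.raises(ValueError):
            poisson.posterior_at(1.0, 1.0, two_event_path, 11.0)

    def test_matches_quadrature_normalised_product(self, two_event_path):
        alpha, beta, t = 1.7, 0.6, 3.0
        post = poisson.posterior_at(alpha, beta, two_event_path, t)
        prior = GammaDist.from_shape_scale(alpha, beta)
        r = two_event_path.count_at(t)

        def unnorm(th):
            return th**r * np.exp(-th * t) * prior.pdf(th)

        z, _ = integrate.quad(unnorm, 0, np.inf)
        l1, _ = integrate.quad(lambda th: abs(unnorm(th) / z - post.pdf(th)),
                               0, np.inf)
        assert l1 < 1e-8


class TestThetaTilde:
    def test_prior_value(self):
        path = poisson.PoissonPath(np.array([]), horizon=1.0)
        est = poisson.theta_tilde(1.0, 1.0, path, 0.0, LinexParams(1.0))
        assert est == pytest.approx(math.log(2))

    def test_squared_error_limit(self, two_event_path):
        est = poisson.theta_tilde(1.0, 1.0, two_event_path, 1.0,
                                  LinexParams(1e-8))
        post = poisson.posterior_at(1.0, 1.0, two_event_path, 1.0)
        assert est == pytest.approx(post.mean, rel=1e-6)

    def test_equals_gamma_closed_form_and_oracle(self, two_event_path):
        p = LinexParams(0.8)
        est = poisson.theta_tilde(1.5, 0.7, two_event_path, 3.0, p)
        post = poisson.posterior_at(1.5, 0.7, two_event_path, 3.0)
        assert est == pytest.approx(bayes_estimate_gamma(post, p), rel=1e-12)
        assert est == pytest.approx(numeric_bayes_oracle(post.pdf, p),
                                    rel=1e-6)


class TestPosteriorRiskU:
    def test_prior_value(self):
        path = poisson.PoissonPath(np.array([]), horizon=1.0)
        u0 = poisson.posterior_risk_u(1.0, 1.0, path, 0.0, LinexParams(1.0))
        assert u0 == pytest.approx(1 - math.log(2))

    def test_algebraic_identity_with_gamma_risk(self, rng):
        """U_t equals the generic gamma posterior risk, to 1e-12."""
        for _ in range(25):
            alpha = rng.uniform(0.5, 5)
            beta = rng.uniform(0.2, 3)
            theta = rng.uniform(0.5, 3)
            path = poisson.simulate_path(theta, 10.0, rng)
            t = rng.uniform(0, 10.0)
            a = rng.choice([-0.3, 0.5, 1.0, 2.0])
            if a * beta <= -1:
                continue
            p = LinexParams(float(a))
            u = poisson.posterior_risk_u(alpha, beta, path, t, p)
            ref = posterior_linex_risk_gamma(
                poisson.posterior_at(alpha, beta, path, t), p)
            assert u == pytest.approx(ref, rel=1e-12, abs=1e-14)

    def test_squared_error_limit_is_posterior_variance(self, two_event_path):
        a = 1e-7
        u = poisson.posterior_risk_u(1.0, 1.0, two_event_path, 1.0,
                                     LinexParams(a))
        post = poisson.posterior_at(1.0, 1.0, two_event_path, 1.0)
        assert u / (a * a / 2) == pytest.approx(post.var, rel=1e-4)

    def test_decreasing_between_events_jumping_at_events(self, two_event_path):
        p = LinexParams(1.0)
        grid = np.linspace(0.0, 0.499, 50)
        us = [poisson.posterior_risk_u(1.0, 1.0, two_event_path, t, p)
              for t in grid]
        assert np.all(np.diff(us) < 0)
        before = poisson.posterior_risk_u(1.0, 1.0, two_event_path, 0.4999, p)
        after = poisson.posterior_risk_u(1.0, 1.0, two_event_path, 0.5, p)
        assert after > before


class TestScaledRiskC:
    def test_nonnegative(self, two_event_path):
        c = poisson.scaled_risk_c(1.0, 1.0, two_event_path, 2.5,
                                  LinexParams(1.0))
        assert c >= 0

    @pytest.mark.parametrize("a, limit", [(1.0, 0.5), (0.5, 0.125)])
    def test_long_run_limit(self, rng, a, limit):
        """C_t -> a^2*theta/2 along long paths (theta = 1)."""
        t_end, reps = 2000.0, 60
        vals = [poisson.scaled_risk_c(1.0, 1.0,
                                      poisson.simulate_path(1.0, t_end, rng),
                                      t_end, LinexParams(a))
                for _ in range(reps)]
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / math.sqrt(reps)
        assert abs(vals.mean() - limit) < 3 * se + 1e-3

    def test_convergence_trend_over_scales(self, rng):
        errs = []
        for t_end in (100.0, 1000.0, 10_000.0):
            vals = [poisson.scaled_risk_c(
                1.0, 1.0, poisson.simulate_path(1.0, t_end, rng), t_end,
                LinexParams(1.0)) for _ in range(40)]
            errs.append(abs(np.mean(vals) - 0.5))
        assert errs[-1] < errs[0]


class TestApoStop:
    def test_empty_path_against_bisection_oracle(self):
        """tau solves U_t = c*t; independent bisection on the same equation."""
        path = poisson.PoissonPath(np.array([]), horizon=50.0)
        dec = poisson.apo_stop(path, 1.0, 1.0, LinexParams(1.0), c=0.1)

        def f(t):
            s = 1.0 / (t + 1.0)
            return (s - math.log1p(s)) - 0.1 * t

        lo, hi = 1e-9, 50.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if f(mid) > 0:
                lo = mid
            else:
                hi = mid
        assert dec.tau == pytest.approx(0.5 * (lo + hi), abs=1e-9)
        assert dec.tau == pytest.approx(0.970, abs=1e-3)
        assert not dec.truncated

    def test_root_condition_at_interior_stop(self, rng):
        for _ in range(10):
            theta = rng.uniform(0.5, 4.0)
            path = poisson.simulate_path(theta, 200.0, rng)
            dec = poisson.apo_stop(path, 2.0, 1.0, LinexParams(1.0), c=0.01)
            if dec.truncated or dec.tau in path.event_times or dec.tau == 0.0:
                continue
            assert abs(dec.posterior_risk - 0.01 * dec.tau) <= 1e-9

    def test_tau_nonincreasing_in_cost(self, rng):
        path = poisson.simulate_path(2.0, 500.0, seed=9)
        taus = [poisson.apo_stop(path, 2.0, 1.0, LinexParams(1.0), c=c).tau
                for c in (0.2, 0.05, 0.01, 0.002)]
        assert taus == sorted(taus)

    def test_sign_change_at_most_once_per_interval(self, rng):
        """Dense scan: U_t - c*t crosses zero at most once between events."""
        path = poisson.simulate_path(1.5, 30.0, seed=21)
        p, c = LinexParams(1.0), 0.05
        edges = np.concatenate(([0.0], path.event_times, [path.horizon]))
        for lo, hi in zip(edges[:-1], edges[1:]):
            ts = np.linspace(lo, hi - 1e-9 * (hi - lo), 60)
            g = np.array([poisson.posterior_risk_u(2.0, 1.0, path, t, p)
                          - c * t for t in ts])
            assert (np.diff(np.sign(g)) != 0).sum() <= 1

    def test_truncation_flagged(self):
        path = poisson.PoissonPath(np.array([]), horizon=0.5)
        dec = poisson.apo_stop(path, 1.0, 1.0, LinexParams(1.0), c=0.01)
        assert dec.truncated
        assert dec.tau == 0.5

    def test_stop_at_interval_start_when_already_below(self):
        # enormous cost: U_0 > 0 = c*0 fails only at t=0; crossing immediate
        path = poisson.PoissonPath(np.array([]), horizon=10.0)
        dec = poisson.apo_stop(path, 1.0, 1.0, LinexParams(1.0), c=100.0)
        assert dec.tau < 0.01


class TestSequentialBayesRisk:
    def test_risk_positive_and_decreasing_in_cost(self):
        risks = []
        for i, c in enumerate((0.1, 0.01, 0.001)):
            risk, mean_tau, se = poisson.sequential_bayes_risk(
                2.0, 1.0, LinexParams(1.0), c, reps=150, seed=100 + i)
            assert risk > 0
            risks.append(risk)
        assert risks == sorted(risks, reverse=True)

    def test_mean_tau_small_cost_asymptote(self):
        """mean tau* ~ a*sqrt(prior_mean/(2c)) for small c."""
        a, c = 1.0, 1e-3
        prior_shape, prior_scale = 4.0, 0.5
        risk, mean_tau, _ = poisson.sequential_bayes_risk(
            prior_shape, prior_scale, LinexParams(a), c, reps=200, seed=17)
        approx = a * math.sqrt(prior_shape * prior_scale / (2 * c))
        assert mean_tau == pytest.approx(approx, rel=0.15)

    def test_negative_shape_regime_warning(self):
        with pytest.warns(UserWarning, match="alpha > 1"):
            poisson.posterior_risk_u(
                0.5, 1.0, poisson.PoissonPath(np.array([]), 1.0), 0.5,
                LinexParams(-0.5))
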