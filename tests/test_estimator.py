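"""Streaming Bayesian estimator: posterior, updates, credible intervals.

The single-step oracle used here evaluates the posterior and all six
update equations independently of the implementation (plain arithmetic on
scipy's normal pdf), so the estimator is checked against a second route.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from fetalbiom import (
    CredibleInterval,
    EstimatorState,
    MixtureModel,
    PriorConfig,
    credible_interval,
    init_state,
    posterior_true_prob,
    run_stream,
    update,
)


def oracle_step(state, x):
    """Independent hand-coded evaluation of one posterior + update step."""
    g = norm.pdf(x, loc=state.mu, scale=math.sqrt(state.sigma2))
    u = 1.0 / (state.b - state.a)
    p = g * state.P_t / (g * state.P_t + u * (1.0 - state.P_t))
    P_t = (p + state.W * state.P_t) / (state.W + 1.0)
    mu = (x * p + state.W_mu * state.mu) / (p + state.W_mu)
    sigma2 = ((x - state.mu) ** 2 * p + state.W_sigma2 * state.sigma2) / (
        p + state.W_sigma2
    )
    return p, P_t, mu, sigma2, state.W + 1, state.W_mu + p, state.W_sigma2 + p


STATE = EstimatorState(P_t=0.75, mu=33.0, sigma2=4.0, W=10.0, W_mu=1.0,
                       W_sigma2=1.0, a=20.0, b=46.0)


class TestPosterior:
    def test_symmetric_likelihoods_give_half(self):
        # choose sigma2 so the normal density at mu equals the uniform density
        u = 1.0 / 26.0
        sigma = 1.0 / (u * math.sqrt(2 * math.pi))
        st_ = EstimatorState(P_t=0.5, mu=33.0, sigma2=sigma**2, W=10.0,
                             W_mu=1.0, W_sigma2=1.0, a=20.0, b=46.0)
        assert posterior_true_prob(st_, 33.0) == pytest.approx(0.5, abs=1e-12)

    def test_at_mean_matches_direct_bayes_evaluation(self):
        st_ = EstimatorState(P_t=0.75, mu=33.0, sigma2=4.0, W=10.0, W_mu=1.0,
                             W_sigma2=1.0, a=20.0, b=46.0)
        g = norm.pdf(33.0, 33.0, 2.0)
        expected = g * 0.75 / (g * 0.75 + (1 / 26) * 0.25)
        assert posterior_true_prob(st_, 33.0) == pytest.approx(expected, rel=1e-12)
        # frozen value of the oracle evaluation
        assert posterior_true_prob(st_, 33.0) == pytest.approx(0.93960896, abs=1e-7)

    def test_far_tail_has_negligible_posterior(self):
        # sigma = 1.5 so an 8-sigma point stays inside the nuisance bounds
        for P_t in (0.5, 0.9, 0.99):
            st_ = EstimatorState(P_t=P_t, mu=33.0, sigma2=1.5**2, W=10.0,
                                 W_mu=1.0, W_sigma2=1.0, a=20.0, b=46.0)
            for x in (33.0 - 8 * 1.5, 33.0 + 8 * 1.5):
                assert posterior_true_prob(st_, x) < 1e-3

    @given(x=st.floats(min_value=20.0, max_value=46.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_posterior_strictly_inside_unit_interval(self, x):
        assert 0.0 < posterior_true_prob(STATE, x) < 1.0


class TestUpdate:
    def test_single_step_matches_independent_oracle(self):
        x = 35.0
        p, P_t, mu, sigma2, W, W_mu, W_sigma2 = oracle_step(STATE, x)
        out = update(STATE, x)
        # 12-significant-digit agreement with the hand-coded evaluation
        assert out.P_t == pytest.approx(P_t, rel=1e-12)
        assert out.mu == pytest.approx(mu, rel=1e-12)
        assert out.sigma2 == pytest.approx(sigma2, rel=1e-12)
        assert out.W == pytest.approx(W, rel=1e-12)
        assert out.W_mu == pytest.approx(W_mu, rel=1e-12)
        assert out.W_sigma2 == pytest.approx(W_sigma2, rel=1e-12)

    def test_variance_update_uses_previous_mean(self):
        # with the previous mean mu_{i-1}=33 the squared deviation for x=35
        # is 4; using the new mean would give a smaller value
        out = update(STATE, 35.0)
        p = posterior_true_prob(STATE, 35.0)
        expected = (4.0 * p + 1.0 * 4.0) / (p + 1.0)
        assert out.sigma2 == pytest.approx(expected, rel=1e-12)

    def test_vanishing_prior_mean_weight_limit(self):
        st_ = EstimatorState(P_t=0.75, mu=33.0, sigma2=4.0, W=10.0, W_mu=1e-12,
                             W_sigma2=1.0, a=20.0, b=46.0)
        out = update(st_, 39.0)
        assert out.mu == pytest.approx(39.0, abs=1e-9)

    def test_nuisance_bounds_unchanged(self):
        out = update(STATE, 35.0)
        assert (out.a, out.b) == (STATE.a, STATE.b)

    @given(xs=st.lists(st.floats(min_value=20.0, max_value=46.0), min_size=1,
                       max_size=50))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_P_t_stays_strictly_inside_unit_interval(self, xs):
        state = STATE
        for x in xs:
            state = update(state, x)
            assert 0.0 < state.P_t < 1.0
            assert state.sigma2 > 0


class TestInitState:
    def test_prior_mean_is_p50_at_ga(self, ref):
        st_ = init_state(ref, "FL", 20.0)
        assert st_.mu == pytest.approx(ref.p50("FL", 20.0))
        assert st_.P_t == pytest.approx(0.75)

    def test_prior_sigma_spans_centile_band(self, ref):
        st_ = init_state(ref, "FL", 20.0)
        p3, _, p97 = ref.centiles("FL", 20.0)
        assert math.sqrt(st_.sigma2) == pytest.approx((p97 - p3) / 4.0)

    def test_nuisance_bounds_are_plausibility_window(self, ref, fl_window):
        st_ = init_state(ref, "FL", 20.0)
        assert (st_.a, st_.b) == pytest.approx(fl_window)

    @pytest.mark.parametrize("p0", [0.0, 1.0])
    def test_boundary_prior_rejected(self, p0):
        with pytest.raises(ValueError):
            PriorConfig(P_t0=p0)

    def test_unknown_biometric_rejected(self, ref):
        with pytest.raises(Exception):
            init_state(ref, "CRL", 20.0)


class TestCredibleInterval:
    def test_interval_arithmetic(self):
        st_ = EstimatorState(P_t=0.75, mu=33.0, sigma2=4.0, W=10.0, W_mu=1.0,
                             W_sigma2=4.0, a=20.0, b=46.0)
        ci = credible_interval(st_)
        assert ci.sigma_hat == pytest.approx(1.0)
        assert (ci.low, ci.high) == pytest.approx((31.0, 35.0))

    def test_sigma_hat_non_increasing_in_weight(self):
        prev = math.inf
        for w in (1.0, 2.0, 10.0, 100.0):
            st_ = EstimatorState(P_t=0.75, mu=33.0, sigma2=4.0, W=10.0,
                                 W_mu=1.0, W_sigma2=w, a=20.0, b=46.0)
            sh = credible_interval(st_).sigma_hat
            assert sh < prev
            prev = sh

    def test_sigma_hat_tracks_standard_error_of_mean(self, ref):
        # after many pure-Gaussian updates the reported standard error
        # should approximate sigma / sqrt(effective weight)
        rng = np.random.default_rng(11)
        sigma = 1.8
        state = init_state(ref, "FL", 20.0)
        state, _ = run_stream(rng.normal(34.0, sigma, 500), state,
                              record_trajectory=False)
        ci = credible_interval(state)
        closed_form = sigma / math.sqrt(state.W_sigma2)
        assert ci.sigma_hat == pytest.approx(closed_form, rel=0.20)


class TestRunStream:
    def test_empty_stream_returns_prior(self, fl_state):
        final, traj = run_stream([], fl_state)
        assert final == fl_state
        assert traj.empty

    def test_identical_values_collapse_to_point(self, fl_state):
        xs = [36.0] * 3000
        final, _ = run_stream(xs, fl_state, record_trajectory=False)
        assert final.mu == pytest.approx(36.0, abs=0.01)
        assert credible_interval(final).sigma_hat < 0.05

    def test_mixture_stream_converges_to_gaussian_mean(self, fl_state):
        # property replicated over 20 seeds: |mu_final - truth| < 0.3 mm
        a, b = fl_state.a, fl_state.b
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 1000
            inlier = rng.random(n) < 0.8
            xs = np.where(inlier, rng.normal(33.0, 1.8, n), rng.uniform(a, b, n))
            final, _ = run_stream(xs, fl_state, record_trajectory=False)
            assert abs(final.mu - 33.0) < 0.3

    def test_trajectory_columns_and_length(self, fl_state):
        rng = np.random.default_rng(0)
        final, traj = run_stream(rng.normal(33.0, 1.8, 50), fl_state)
        assert list(traj.columns) == ["i", "x", "p_true", "P_t", "mu", "sigma2",
                                      "sigma_hat"]
        assert len(traj) == 50
        assert traj["sigma_hat"].iloc[-1] == pytest.approx(
            credible_interval(final).sigma_hat
        )

    def test_order_insensitive_in_expectation(self, fl_state):
        rng = np.random.default_rng(21)
        a, b = fl_state.a, fl_state.b
        n = 800
        inlier = rng.random(n) < 0.8
        xs = np.where(inlier, rng.normal(33.0, 1.8, n), rng.uniform(a, b, n))
        mus, ses = [], []
        for _ in range(5):
            rng.shuffle(xs)
            final, _ = run_stream(xs, fl_state, record_trajectory=False)
            ci = credible_interval(final)
            mus.append(ci.mu)
            ses.append(ci.sigma_hat)
        pooled = np.sqrt(np.mean(np.square(ses)))
        assert max(mus) - min(mus) < 3.0 * pooled

    def test_P_t_converges_from_any_interior_start(self, ref):
        a = ref.p3("FL", 17.0)
        b = ref.p97("FL", 23.0)
        rng = np.random.default_rng(5)
        n = 2000
        inlier = rng.random(n) < 0.8
        xs = np.where(inlier, rng.normal(34.0, 1.8, n), rng.uniform(a, b, n))
        for p0 in (0.1, 0.5, 0.9):
            st_ = init_state(ref, "FL", 20.0, PriorConfig(P_t0=p0))
            final, _ = run_stream(xs, st_, record_trajectory=False)
            assert 0.7 <= final.P_t <= 0.9


class TestMixtureModel:
    def test_density_integrates_to_one(self):
        m = MixtureModel(P_t=0.79, mu=33.0, sigma2=1.8**2, a=20.0, b=46.0)
        xs = np.linspace(0.0, 70.0, 200001)
        integral = np.trapezoid(m.pdf(xs), xs)
        assert integral == pytest.approx(1.0, abs=1e-4)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"P_t": 1.2},
            {"sigma2": 0.0},
            {"a": 46.0, "b": 20.0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        base = dict(P_t=0.75, mu=33.0, sigma2=4.0, a=20.0, b=46.0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            MixtureModel(**base)
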