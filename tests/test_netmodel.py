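"""Hazard network forward pass, penalized likelihood and analytic gradient."""

import numpy as np
import pytest
from scipy.stats import poisson

from peann.netmodel import (
    Ensemble,
    HazardNet,
    gradient,
    hazard_forward,
    neg_log_lik,
    objective,
    objective_and_gradient,
)
from peann.survdata import build_interval_grid, expand_person_period

from conftest import make_cohort


def random_net(p, H, rng, lam=0.1, scale=0.5, time_scale=72.0):
    return HazardNet(
        H,
        rng.uniform(-scale, scale, (p + 2, H)),
        rng.uniform(-scale, scale, H + 1),
        lam,
        time_scale,
    )


def random_pp(n, rng, covs=1):
    times = rng.exponential(25, n) + 0.1
    events = rng.integers(0, 2, n)
    cov_dict = {
        f"c{j}": rng.choice(["a", "b", "c"], n).tolist() for j in range(covs)
    }
    cohort = make_cohort(times, events, cov_dict)
    return expand_person_period(cohort, build_interval_grid(6.0, 72.0))


class TestForward:
    def test_zero_net_is_unit_hazard(self):
        net = HazardNet(3, np.zeros((4, 3)), np.zeros(4), 0.0, 72.0)
        h = hazard_forward(net, np.zeros((1, 2)), np.array([0.3]))
        assert h[0] == pytest.approx(1.0)

    def test_output_bias_only_gives_constant_hazard(self):
        W2 = np.zeros(4)
        W2[0] = -2.3
        rng = np.random.default_rng(0)
        net = HazardNet(3, rng.normal(size=(4, 3)), W2, 0.0, 72.0)
        t = np.linspace(0.01, 1, 7)
        h = hazard_forward(net, rng.normal(size=(7, 2)), t)
        np.testing.assert_allclose(h, np.exp(-2.3))

    def test_matches_hand_coded_forward(self):
        # independent two-line implementation of the same algebra
        rng = np.random.default_rng(5)
        net = random_net(p=1, H=2, rng=rng)
        x, t = np.array([[0.7]]), np.array([0.4])
        z = 1 / (1 + np.exp(-(net.W1[0] + x[0, 0] * net.W1[1] + t[0] * net.W1[2])))
        expected = np.exp(net.W2[0] + z @ net.W2[1:])
        assert hazard_forward(net, x, t)[0] == pytest.approx(expected, abs=1e-12)

    def test_positivity(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            net = random_net(p=3, H=4, rng=rng, scale=3.0)
            h = hazard_forward(net, rng.normal(size=(20, 3)), rng.uniform(0, 1, 20))
            assert np.all(h > 0)

    def test_dimension_mismatch(self):
        net = HazardNet(2, np.zeros((4, 2)), np.zeros(3), 0.0, 72.0)
        with pytest.raises(ValueError):
            hazard_forward(net, np.zeros((1, 5)), np.array([0.1]))

    def test_hidden_unit_permutation_invariance(self):
        rng = np.random.default_rng(12)
        net = random_net(p=2, H=4, rng=rng)
        perm = [2, 0, 3, 1]
        net2 = HazardNet(
            4,
            net.W1[:, perm],
            np.concatenate([[net.W2[0]], net.W2[1:][perm]]),
            net.lam,
            net.time_scale,
        )
        X = rng.normal(size=(6, 2))
        t = rng.uniform(0, 1, 6)
        np.testing.assert_allclose(
            hazard_forward(net, X, t), hazard_forward(net2, X, t), rtol=1e-14
        )


class TestLikelihood:
    def test_forced_arithmetic_single_rows(self, grid72):
        # h == 1 net; one event row with tau=2 and one censored row with tau=5
        net = HazardNet(1, np.zeros((2, 1)), np.zeros(2), 0.0, 72.0)
        pp_event = expand_person_period(make_cohort([2.0], [1]), build_interval_grid(2, 2))
        assert neg_log_lik(net, pp_event) == pytest.approx(2.0)
        pp_cens = expand_person_period(make_cohort([5.0], [0]), build_interval_grid(5, 5))
        assert neg_log_lik(net, pp_cens) == pytest.approx(5.0)

    def test_poisson_equivalence(self):
        """neg_log_lik == Poisson NLL with offset log tau, up to sum(d log tau)."""
        rng = np.random.default_rng(21)
        for _ in range(5):
            pp = random_pp(30, rng, covs=2)
            net = random_net(pp.p, 3, rng)
            h = hazard_forward(net, pp.X, pp.t_scaled)
            pois_nll = -poisson.logpmf(pp.d, h * pp.tau).sum()
            const = pp.d @ np.log(pp.tau)
            assert neg_log_lik(net, pp) == pytest.approx(pois_nll + const, abs=1e-10)

    def test_objective_penalty(self):
        rng = np.random.default_rng(2)
        pp = random_pp(20, rng)
        net = random_net(pp.p, 2, rng, lam=0.0)
        assert objective(net, pp) == pytest.approx(neg_log_lik(net, pp))
        # single nonzero coefficient 2.0, lambda 0.1 -> penalty 0.4
        W1 = np.zeros((pp.p + 2, 2))
        W2 = np.zeros(3)
        W1[0, 0] = 2.0
        net2 = HazardNet(2, W1, W2, 0.1, 72.0)
        assert objective(net2, pp) - neg_log_lik(net2, pp) == pytest.approx(0.4)

    def test_zero_net_penalty_zero(self):
        rng = np.random.default_rng(2)
        pp = random_pp(20, rng)
        net = HazardNet(2, np.zeros((pp.p + 2, 2)), np.zeros(3), 5.0, 72.0)
        assert objective(net, pp) == pytest.approx(neg_log_lik(net, pp))


class TestGradient:
    def test_closed_form_at_zero_weights(self):
        rng = np.random.default_rng(4)
        pp = random_pp(25, rng)
        net = HazardNet(3, np.zeros((pp.p + 2, 3)), np.zeros(4), 0.0, 72.0)
        g = gradient(net, pp)
        s = float(np.sum(pp.tau - pp.d))
        # packed layout: W1 (columns per hidden unit) then W2 (bias first)
        n1 = (pp.p + 2) * 3
        assert g[n1] == pytest.approx(s)  # d/d b2_0
        np.testing.assert_allclose(g[n1 + 1 :], 0.5 * s)  # d/d b2_k, z == 0.5

    def test_penalty_only_gradient(self):
        """With an empty data term the gradient is 2*lambda*beta elementwise."""
        rng = np.random.default_rng(8)
        pp = random_pp(10, rng)
        empty = type(pp)(
            subject=np.zeros(0, int),
            interval=np.zeros(0, int),
            d=np.zeros(0, int),
            tau=np.zeros(0),
            t_mid=np.zeros(0),
            t_scaled=np.zeros(0),
            X=np.zeros((0, pp.p)),
            encoding=pp.encoding,
            grid=pp.grid,
            n_subjects=0,
        )
        theta = rng.normal(size=(pp.p + 2) * 2 + 3)
        _, g = objective_and_gradient(theta, empty, pp.p, 2, 0.7)
        np.testing.assert_allclose(g, 2 * 0.7 * theta, atol=1e-14)

    def test_finite_difference_agreement(self):
        rng = np.random.default_rng(77)
        worst = 0.0
        for _ in range(5):
            pp = random_pp(15, rng, covs=1)
            H = int(rng.integers(1, 4))
            lam = float(rng.uniform(0, 0.2))
            theta = rng.uniform(-0.5, 0.5, (pp.p + 2) * H + H + 1)
            _, g = objective_and_gradient(theta, pp, pp.p, H, lam)
            eps = 1e-6
            for i in range(theta.size):
                e = np.zeros_like(theta)
                e[i] = eps
                fp = objective_and_gradient(theta + e, pp, pp.p, H, lam)[0]
                fm = objective_and_gradient(theta - e, pp, pp.p, H, lam)[0]
                gn = (fp - fm) / (2 * eps)
                worst = max(worst, abs(g[i] - gn) / max(abs(gn), 1.0))
        assert worst < 1e-6

    def test_guard_never_binds_at_moderate_weights(self):
        rng = np.random.default_rng(13)
        pp = random_pp(30, rng)
        net = random_net(pp.p, 3, rng)
        from peann.netmodel import _forward_parts

        _, eta, _ = _forward_parts(net.W1, net.W2, pp.X, pp.t_scaled)
        assert np.max(np.abs(eta)) < 50


class TestSerialization:
    def test_json_round_trip_bit_exact(self):
        rng = np.random.default_rng(31)
        pp = random_pp(10, rng)
        net = random_net(pp.p, 2, rng)
        net.encoding = pp.encoding
        net.grid = pp.grid
        net2 = HazardNet.from_dict(net.to_dict())
        np.testing.assert_array_equal(net.W1, net2.W1)
        np.testing.assert_array_equal(net.W2, net2.W2)
        assert net2.encoding.columns == pp.encoding.columns

    def test_ensemble_requires_shared_hyperparameters(self):
        rng = np.random.default_rng(6)
        a = random_net(1, 2, rng, lam=0.1)
        b = random_net(1, 2, rng, lam=0.5)
        with pytest.raises(ValueError):
            Ensemble([a, b])
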