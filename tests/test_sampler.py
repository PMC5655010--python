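"""Tailored Metropolis-within-Gibbs machinery, RWM baselines, diagnostics."""

import numpy as np
import pytest

from ricianreg import (
    MCMCConfig,
    NoiseModel,
    SimulationDesign,
    inefficiency_factor,
    newton_tailored_proposal,
    run_gibbs,
    run_rwm,
    simulate_regression,
)
from ricianreg.sampler import CondTarget, tailored_exchange


def quadratic_target(mean, prec):
    mean = np.asarray(mean, dtype=float)
    prec = np.atleast_2d(prec)

    def eval_all(theta):
        dev = theta - mean
        g = -prec @ dev
        return -0.5 * float(dev @ prec @ dev), g, -prec

    return CondTarget(eval_all, len(mean))


class TestNewtonProposal:
    def test_one_step_exact_on_quadratic(self):
        # Newton is exact on quadratics: any start lands on the mode
        mean = np.array([1.0, -2.0])
        prec = np.array([[2.0, 0.3], [0.3, 1.0]])
        tgt = quadratic_target(mean, prec)
        mode, cov = newton_tailored_proposal(np.array([10.0, 5.0]), tgt, newton_steps=1)
        np.testing.assert_allclose(mode, mean, atol=1e-10)
        np.testing.assert_allclose(cov, np.linalg.inv(prec), atol=1e-10)

    def test_mode_is_fixed_point(self):
        mean = np.array([0.5])
        tgt = quadratic_target(mean, [[4.0]])
        for steps in (1, 2, 5):
            mode, _ = newton_tailored_proposal(mean.copy(), tgt, newton_steps=steps)
            np.testing.assert_allclose(mode, mean, atol=1e-12)

    def test_two_steps_reach_full_optimum_on_rician_toy(self):
        # a couple of Newton steps from the current draw get within 1e-3 of
        # the fully optimized conditional mode
        from scipy.optimize import minimize

        from ricianreg import PriorSpec
        from ricianreg.regression import CoefState
        from ricianreg.sampler import _make_block_target, _PriorCache

        design = SimulationDesign(n=50, beta=np.array([0.5, -0.3]), alpha=np.array([]),
                                  beta0=1.2, alpha0=-1.0, seed=0)
        data, truth = simulate_regression(design)
        prior = PriorSpec(m_beta0=1.0, s2_beta0=4.0, m_alpha0=-1.0, s2_alpha0=4.0,
                          Sigma_beta=np.eye(2), Sigma_alpha=np.empty((0, 0)), c=50.0)
        state = CoefState(1.0, np.zeros(2), -1.0, np.zeros(0))
        cache = _PriorCache(prior.Sigma_beta, prior.c)
        tgt = _make_block_target("mean", state, data, NoiseModel("rician"),
                                 prior, np.ones(2, dtype=int), cache)
        res = minimize(lambda t: -tgt.value(t), np.array([1.0, 0.0, 0.0]),
                       method="BFGS", jac=lambda t: -tgt.grad_hess(t)[0])
        _, cov = newton_tailored_proposal(res.x, tgt, newton_steps=1)
        # start where a chain would: a couple of posterior sds from the mode
        start = res.x + 2.0 * np.sqrt(np.diag(cov))
        mode2, _ = newton_tailored_proposal(start, tgt, newton_steps=2)
        assert np.max(np.abs(mode2 - res.x)) < 1e-3

    def test_nonconcave_hessian_is_regularized(self):
        # an indefinite Hessian still yields a valid SPD proposal covariance
        def eval_all(theta):
            return float(theta[0] ** 3), np.array([3 * theta[0] ** 2]), np.array([[6 * theta[0]]])

        tgt = CondTarget(eval_all, 1)
        _, cov = newton_tailored_proposal(np.array([1.0]), tgt, newton_steps=1)
        assert cov[0, 0] > 0


class TestTailoredExchange:
    def test_acceptance_is_one_on_gaussian_target_with_normal_proposal(self):
        # with a quadratic (conjugate-Gaussian) conditional, one Newton step
        # makes the proposal equal the target, so every draw is accepted
        mean = np.array([0.3, -1.2, 2.0])
        A = np.array([[3.0, 0.4, 0.0], [0.4, 2.0, 0.2], [0.0, 0.2, 1.0]])
        tgt = quadratic_target(mean, A)
        cfg = MCMCConfig(n_iter=10, n_burnin=1, proposal="normal")
        rng = np.random.default_rng(0)
        theta = np.array([5.0, 5.0, 5.0])
        n_acc = 0
        for _ in range(300):
            acc, theta_p = tailored_exchange(theta, tgt, tgt, theta, lambda t: t,
                                             0.0, cfg, rng)
            n_acc += acc
            if acc:
                theta = theta_p
        assert n_acc == 300

    def test_t_proposal_acceptance_high_on_gaussian_target(self):
        tgt = quadratic_target([0.0], [[1.0]])
        cfg = MCMCConfig(n_iter=10, n_burnin=1, proposal="t", t_dof=10.0)
        rng = np.random.default_rng(1)
        theta = np.array([3.0])
        accs = []
        for _ in range(400):
            acc, theta_p = tailored_exchange(theta, tgt, tgt, theta, lambda t: t,
                                             0.0, cfg, rng)
            accs.append(acc)
            if acc:
                theta = theta_p
        assert np.mean(accs) > 0.9


class TestRunGibbs:
    def test_deterministic_under_seed(self, small_dataset, flat_prior):
        data, _ = small_dataset
        prior = flat_prior(2, 1)
        cfg = MCMCConfig(n_iter=120, n_burnin=40, seed=5, vs_mu=True, vs_phi=True)
        a = run_gibbs(data, NoiseModel("rician"), prior, cfg)
        b = run_gibbs(data, NoiseModel("rician"), prior, cfg)
        np.testing.assert_array_equal(a.beta, b.beta)
        np.testing.assert_array_equal(a.Ialpha, b.Ialpha)
        np.testing.assert_array_equal(a.accept_mean, b.accept_mean)

    def test_zero_pattern_integrity(self, small_dataset, flat_prior):
        data, _ = small_dataset
        cfg = MCMCConfig(n_iter=200, n_burnin=50, seed=2, vs_mu=True, vs_phi=True)
        draws = run_gibbs(data, NoiseModel("rician"), flat_prior(2, 1), cfg)
        assert np.all((draws.beta == 0.0) == (draws.Ibeta == 0))
        assert np.all((draws.alpha == 0.0) == (draws.Ialpha == 0))

    def test_homoscedastic_empty_variance_design(self, flat_prior):
        design = SimulationDesign(n=40, beta=np.array([0.4]), alpha=np.array([]),
                                  beta0=1.0, alpha0=-0.5, seed=1)
        data, _ = simulate_regression(design)
        cfg = MCMCConfig(n_iter=150, n_burnin=50, seed=3)
        draws = run_gibbs(data, NoiseModel("rician"), flat_prior(1, 0), cfg)
        assert draws.alpha.shape == (100, 0)
        assert np.std(draws.alpha0) > 0  # the intercept still updates

    def test_draws_save_round_trip(self, tmp_path, small_dataset, flat_prior):
        import json

        import pandas as pd

        data, _ = small_dataset
        cfg = MCMCConfig(n_iter=120, n_burnin=20, seed=4)
        draws = run_gibbs(data, NoiseModel("rician"), flat_prior(2, 1), cfg)
        path = tmp_path / "draws.csv"
        draws.save(path)
        df = pd.read_csv(path)
        assert len(df) == 100 and "beta1" in df.columns
        meta = json.loads((tmp_path / "draws.csv.meta.json").read_text())
        assert meta["config"]["seed"] == 4


class TestRWM:
    def test_baselines_agree_with_tailored_sampler(self, flat_prior):
        # all three samplers target the same posterior
        design = SimulationDesign(n=120, beta=np.array([0.5]), alpha=np.array([]),
                                  beta0=1.2, alpha0=-1.0, seed=6)
        data, _ = simulate_regression(design)
        prior = flat_prior(1, 0)
        model = NoiseModel("rician")
        dT = run_gibbs(data, model, prior, MCMCConfig(n_iter=1500, n_burnin=300, seed=1))
        dR = run_rwm(data, model, prior,
                     MCMCConfig(n_iter=6000, n_burnin=1500, seed=1, sampler="rwm_identity"))
        for name in ("beta0", "alpha0"):
            a, b = getattr(dT, name), getattr(dR, name)
            se = np.sqrt(a.var() * inefficiency_factor(a) / len(a)
                         + b.var() * inefficiency_factor(b) / len(b))
            assert abs(a.mean() - b.mean()) < 4 * se, name

    def test_requires_rwm_sampler_tag(self, small_dataset, flat_prior):
        data, _ = small_dataset
        with pytest.raises(ValueError):
            run_rwm(data, NoiseModel("rician"), flat_prior(2, 1),
                    MCMCConfig(n_iter=100, n_burnin=10, sampler="tailored"))

    def test_adaptation_reaches_target_band(self, small_dataset, flat_prior):
        data, _ = small_dataset
        cfg = MCMCConfig(n_iter=4000, n_burnin=2000, seed=9, sampler="rwm_identity")
        draws = run_rwm(data, NoiseModel("rician"), flat_prior(2, 1), cfg)
        assert 0.1 < draws.acceptance_rate_mean < 0.45


class TestInefficiencyFactor:
    @pytest.mark.parametrize("phi,expected", [(0.5, 3.0), (0.9, 19.0)])
    def test_ar1_closed_form(self, phi, expected):
        rng = np.random.default_rng(10)
        n = 60_000
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.standard_normal(n)
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
        assert inefficiency_factor(x) == pytest.approx(expected, rel=0.12)

    def test_iid_chain_is_near_one(self):
        x = np.random.default_rng(11).standard_normal(100_000)
        assert inefficiency_factor(x) == pytest.approx(1.0, abs=0.1)

    def test_constant_chain_rejected(self):
        with pytest.raises(ValueError):
            inefficiency_factor(np.ones(500))

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError):
            inefficiency_factor(np.arange(50.0))
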