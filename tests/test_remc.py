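"""Replica-exchange sampler tests: moves, exchanges, determinism, targets."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import gammaln

import sasbayes as sb
from sasbayes.likelihood import ScatteringCurve
from sasbayes.remc import (
    TemperatureLadder,
    exchange_step,
    geometric_ladder,
    init_state,
    metropolis_sweep,
    run_remc,
    tune_step_sizes,
)


class TestLadder:
    def test_geometric_ladder_shape(self):
        lad = geometric_ladder(16, N=400)
        assert lad.L == 16
        assert lad.betas[0] == 0.0
        assert lad.betas[-1] == 1.0
        ratios = lad.betas[2:] / lad.betas[1:-1]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-9)

    def test_invalid_ladders_rejected(self):
        with pytest.raises(ValueError):
            TemperatureLadder(np.array([0.1, 1.0]))  # no zero anchor
        with pytest.raises(ValueError):
            TemperatureLadder(np.array([0.0, 0.5]))  # does not reach 1
        with pytest.raises(ValueError):
            TemperatureLadder(np.array([0.0, 0.5, 0.5, 1.0]))


class TestMetropolis:
    def test_zero_step_never_moves(self, small_curve, priors):
        lad = geometric_ladder(4, N=small_curve.N)
        rng = np.random.default_rng(0)
        st_ = init_state(small_curve, 2, priors, lad, rng)
        st_.steps[:] = 0.0
        R0, S0, B0 = st_.R.copy(), st_.S.copy(), st_.Bv.copy()
        for _ in range(10):
            metropolis_sweep(st_, rng)
        np.testing.assert_array_equal(st_.R, R0)
        np.testing.assert_array_equal(st_.S, S0)
        np.testing.assert_array_equal(st_.Bv, B0)

    def test_prior_replica_samples_prior(self, priors):
        # beta = 0 chain marginals must match the Gamma priors
        curve = ScatteringCurve(q=np.linspace(0.1, 3, 30),
                                y=np.zeros(30), T=1.0)
        lad = geometric_ladder(3, N=30)
        chain = run_remc(curve, 1, priors, lad, n_burn=500, n_samples=8000, rng_seed=11)
        thin = chain.prior_theta[::10]
        for col, prior in ((0, priors.prior_R), (1, priors.prior_S), (2, priors.prior_B)):
            p = stats.kstest(thin[:, col], prior.cdf).pvalue
            assert p > 0.01, f"column {col} KS p={p}"

    def test_conjugate_posterior_mean(self):
        # background-only model: Gamma prior is conjugate to the Poisson
        # likelihood, so the beta=1 marginal has a known closed form
        rng = np.random.default_rng(5)
        N, T, a, s = 40, 1.0, 2.0, 2.0
        y = rng.poisson(3.0, size=N).astype(float)
        curve = ScatteringCurve(q=np.linspace(0.1, 3, N), y=y, T=T)
        priors = sb.PriorSet(prior_B=sb.GammaPrior(a, s))
        chain = run_remc(curve, 0, priors, geometric_ladder(8, N=N),
                         n_burn=2000, n_samples=6000, rng_seed=2)
        post = chain.posterior_theta[:, 0]
        a_post = a + y.sum()
        scale_post = 1.0 / (N * T + 1.0 / s)
        exact_mean = a_post * scale_post
        exact_sd = np.sqrt(a_post) * scale_post
        # MC error with autocorrelation margin
        assert abs(post.mean() - exact_mean) < 6 * exact_sd / np.sqrt(len(post) / 20)


class TestExchange:
    def test_equal_costs_always_swap(self, small_curve, priors):
        lad = geometric_ladder(4, N=small_curve.N)
        rng = np.random.default_rng(0)
        st_ = init_state(small_curve, 1, priors, lad, rng)
        st_.E[:] = 1.2345  # degenerate: exponent is exactly 0 -> p = 1
        before = st_.R.copy()
        exchange_step(st_, rng, parity=0)
        assert st_.eacc.sum() == st_.eatt.sum() > 0
        # pairs (0,1) and (2,3) swapped
        np.testing.assert_array_equal(st_.R[0], before[1])
        np.testing.assert_array_equal(st_.R[2], before[3])

    def test_acceptance_exponent_value(self):
        # direct substitution: N=400, dbeta=0.1, dE=-0.01 -> p = exp(-0.4)
        p = np.exp(400 * 0.1 * (-0.01))
        assert p == pytest.approx(0.6703, abs=1e-4)

    def test_detailed_balance_antisymmetry(self):
        # log acceptance ratio changes sign under swapping the pair roles
        rng = np.random.default_rng(3)
        for _ in range(100):
            b1, b2 = np.sort(rng.uniform(0, 1, 2))
            E1, E2 = rng.normal(size=2)
            N = int(rng.integers(1, 500))
            fwd = N * (b2 - b1) * (E2 - E1)
            rev = N * (b2 - b1) * (E1 - E2)
            assert fwd == pytest.approx(-rev, rel=1e-12)

    def test_exchange_preserves_state_consistency(self, small_curve, priors):
        lad = geometric_ladder(6, N=small_curve.N)
        rng = np.random.default_rng(8)
        st_ = init_state(small_curve, 2, priors, lad, rng)
        for _ in range(20):
            metropolis_sweep(st_, rng)
            exchange_step(st_, rng, parity=rng.integers(0, 2))
        for l in range(st_.L):
            # table-accelerated kernel cost vs exact evaluation: agreement
            # limited by the ~1e-9 form-factor table error times the scales
            assert sb.poisson_cost(st_.params(l), small_curve) == pytest.approx(
                st_.E[l], abs=1e-5
            )
            assert sb.log_prior(st_.params(l), priors) == pytest.approx(
                st_.LPRI[l], abs=1e-8
            )


class TestRunRemc:
    def test_seed_determinism(self, small_curve, priors):
        lad = geometric_ladder(4, N=small_curve.N)
        c1 = run_remc(small_curve, 2, priors, lad, n_burn=200, n_samples=300, rng_seed=9)
        c2 = run_remc(small_curve, 2, priors, lad, n_burn=200, n_samples=300, rng_seed=9)
        np.testing.assert_array_equal(c1.theta, c2.theta)
        np.testing.assert_array_equal(c1.energy, c2.energy)
        np.testing.assert_array_equal(c1.chi2, c2.chi2)

    def test_mean_cost_nonincreasing_in_beta(self, small_chain):
        # thermodynamic identity: <E>_beta decreases as beta rises
        meanE = small_chain.energy.mean(axis=0)
        # allow small MC wiggle between neighbors; require overall descent
        assert meanE[0] > meanE[-1]
        assert np.sum(np.diff(meanE) > 0.05 * np.abs(meanE[0] - meanE[-1])) == 0

    def test_exchange_rates_healthy(self, small_chain):
        # every pair swaps sometimes; the data-coupled top pairs are not
        # degenerate (the near-prior bottom pairs may legitimately always
        # swap on a small curve where beta * N * dE ~ 0)
        rates = small_chain.exchange_rates
        assert np.all(rates > 0.0)
        assert rates[-1] < 1.0

    def test_validation(self, small_curve, priors):
        lad = geometric_ladder(4, N=small_curve.N)
        with pytest.raises(ValueError):
            run_remc(small_curve, 1, priors, lad, n_burn=0, n_samples=10)


class TestStepTuning:
    def test_controller_direction(self):
        steps = np.full((2, 3), 0.5)
        acc = np.array([[30, 3, 15]] * 2)
        att = np.full((2, 3), 100)
        new = tune_step_sizes(steps, acc, att, target=0.3)
        assert new[0, 0] == pytest.approx(0.5)          # at target: unchanged
        assert new[0, 1] < 0.5                           # too few accepts: shrink
        assert new[0, 2] < 0.5                           # below target: shrink
        grown = tune_step_sizes(steps, np.full((2, 3), 80), att, target=0.3)
        assert np.all(grown > 0.5)

    def test_adaptation_disabled_keeps_steps(self, small_curve, priors):
        lad = geometric_ladder(4, N=small_curve.N)
        chain = run_remc(small_curve, 1, priors, lad, n_burn=100, n_samples=100,
                         rng_seed=0, adapt=False, initial_step=0.37)
        np.testing.assert_allclose(chain.step_sizes, 0.37)

    def test_post_freeze_acceptance_reasonable(self, small_chain):
        rates = small_chain.acceptance_rates
        assert 0.05 < rates.mean() < 0.7
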