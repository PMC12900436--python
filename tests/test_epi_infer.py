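"""Event series, SIR ODE, likelihood, priors, tau_T, RAM, and the sampler."""

import numpy as np
import pytest
from scipy import integrate, stats

import crnlogit as cl
from crnlogit.epi_infer import (
    Demography,
    EpiEventSeries,
    EpiTheta,
    MCMCConfig,
    PosteriorChain,
    PRIOR_GAMMA,
    _log_jac,
    _phi_from_theta,
    _theta_from_phi,
    expand_multi_steps,
    ram_step,
)
import pandas as pd


class TestEventSeries:
    def test_infection_and_removal_indicators(self):
        ev = cl.events_from_prevalence([0.0, 1.0], [1, 2])
        assert ev.y.tolist() == [1]
        ev = cl.events_from_prevalence([0.0, 1.0], [2, 1])
        assert ev.y.tolist() == [0]

    def test_non_unit_step_rejected_with_index(self):
        with pytest.raises(ValueError, match="index 1"):
            cl.events_from_prevalence([0.0, 1.0], [1, 3])

    def test_expand_multi_steps_flagged_helper(self):
        with pytest.warns(UserWarning, match="expanded"):
            t, c = expand_multi_steps([0.0, 1.0, 2.0], [1, 4, 3])
        assert c.tolist() == [1, 2, 3, 4, 3]
        ev = cl.events_from_prevalence(t, c)
        assert ev.n_infections == 3

    def test_n_infections_and_prevalence_replay(self):
        ev = cl.events_from_prevalence(
            [0.0, 0.5, 1.0, 2.0, 3.5], [2, 3, 4, 3, 4])
        assert ev.n_infections == 3
        assert ev.prevalence().tolist() == [3, 4, 3, 4]
        assert ev.pre_times.tolist() == [0.0, 0.5, 1.0, 2.0]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            cl.events_from_prevalence([0.0, 1.0], [-1, 0])


class TestODE:
    def test_no_transmission_keeps_s_constant(self):
        sol = cl.solve_sir(EpiTheta(1e-300, 0.2, 0.01), Demography.none(), 1e4, 10.0)
        np.testing.assert_allclose(sol.s, 1.0, atol=1e-9)

    def test_conservation_without_demography(self):
        th = EpiTheta(0.36, 0.28, 1.2e-3)
        sol = cl.solve_sir(th, Demography.none(), 3e4, 100.0)
        total = sol.s + sol.i + sol.r
        np.testing.assert_allclose(total, 1.0 + th.rho, atol=1e-8)

    def test_linear_decay_closed_form_when_beta_zero(self):
        th = EpiTheta(1e-300, 0.3, 0.01)
        dg = Demography.none()
        sol = cl.solve_sir(th, dg, 1e4, 10.0)
        expected = 0.01 * np.exp(-0.3 * 1.0)
        assert sol.i_at([1.0])[0] == pytest.approx(expected, rel=1e-6)


class TestLikelihood:
    class _UnitS:
        def s_at(self, t):
            return np.ones(len(np.atleast_1d(t)))

    def test_worked_log_odds_at_posterior_means(self):
        """At beta=0.3636, gamma=0.2824 and s=1 the infection log-odds are
        log(beta/gamma) ~ 0.2527, i.e. p ~ 0.5628."""
        th = EpiTheta(0.3636, 0.2824, 1.2e-3)
        ev = EpiEventSeries(times=[1.0], y=[1], I0=5, T=2.0)
        ll = cl.log_likelihood(th, 3e4, ev, self._UnitS())
        p = 1.0 / (1.0 + np.exp(-np.log(0.3636 / 0.2824)))
        assert p == pytest.approx(0.56285, abs=5e-5)
        assert ll == pytest.approx(np.log(p))

    def test_balanced_rates_give_half(self):
        th = EpiTheta(0.3, 0.3, 0.01)
        ev = EpiEventSeries(times=[1.0], y=[1], I0=5, T=2.0)
        assert cl.log_likelihood(th, 1e4, ev, self._UnitS()) == pytest.approx(np.log(0.5))

    def test_odds_identity_at_event_times(self):
        """exp(logit p_t) must equal (beta/gamma) * s_t at every event."""
        th = EpiTheta(0.36, 0.28, 1.2e-3)
        dg = Demography.none()
        sol = cl.solve_sir(th, dg, 3e4, 50.0)
        times = np.array([5.0, 20.0, 40.0])
        ev = EpiEventSeries(times=times, y=[1, 0, 1], I0=36, T=50.0)
        s_pre = sol.s_at(ev.pre_times)
        ll_1 = [cl.log_likelihood(th, 3e4,
                                  EpiEventSeries(times=times[:k + 1], y=[1] * (k + 1),
                                                 I0=36, T=50.0), sol, dg)
                for k in range(3)]
        # reconstruct per-event log p and check the odds identity
        log_p = np.diff(np.concatenate([[0.0], ll_1]))
        odds = np.exp(log_p) / (1 - np.exp(log_p))
        np.testing.assert_allclose(odds, th.beta / th.gamma * s_pre, rtol=1e-9)

    def test_nonpositive_s_rejected(self):
        th = EpiTheta(0.36, 0.28, 1.2e-3)

        class _BadS:
            def s_at(self, t):
                return np.zeros(len(np.atleast_1d(t)))

        ev = EpiEventSeries(times=[1.0], y=[1], I0=5, T=2.0)
        with pytest.raises(ValueError):
            cl.log_likelihood(th, 1e4, ev, _BadS())


class TestPrior:
    def test_gamma_prior_mean_is_mean_infectious_rate(self):
        a, b = PRIOR_GAMMA
        assert a / b == pytest.approx(0.282)

    def test_flat_beta_prior_contributes_zero(self):
        lp_mid = cl.log_prior(EpiTheta(0.282, 0.282, 0.5))
        lp_other = cl.log_prior(EpiTheta(0.282, 0.282, 0.9))
        assert lp_mid == pytest.approx(lp_other)  # rho density is uniform

    def test_out_of_support_rejected_at_construction(self):
        with pytest.raises(ValueError):
            EpiTheta(-0.1, 0.2, 0.5)
        with pytest.raises(ValueError):
            EpiTheta(0.1, 0.2, 1.5)


class TestTau:
    def test_zero_demography_collapses_to_final_size(self):
        th = EpiTheta(0.36, 0.28, 1.2e-3)
        dg = Demography.none()
        sol = cl.solve_sir(th, dg, 3e4, 100.0)
        assert cl.tau_T(sol, dg, 3e4) == pytest.approx(1.0 - sol.s[-1], abs=1e-10)

    def test_no_epidemic_clamps_at_epsilon(self):
        th = EpiTheta(1e-300, 0.3, 0.01)
        dg = Demography.none()
        sol = cl.solve_sir(th, dg, 1e4, 10.0)
        tau = cl.tau_T(sol, dg, 1e4)
        assert 0 < tau < 1e-8

    def test_matches_refined_quadrature(self):
        """tau_T with the trapezoid integral must agree with an independent
        adaptive quadrature of nu * s_u to 1e-6."""
        th = EpiTheta(0.4, 0.25, 2e-3)
        dg = Demography(census_in_rate=0.5, census_out_rate=0.6,
                        total_population=1e2)  # exaggerated turnover
        n, T = 1e4, 80.0
        sol = cl.solve_sir(th, dg, n, T)
        mu, nu = dg.mu(n), dg.nu(n)
        integral, _ = integrate.quad(lambda u: nu * sol.s_at([u])[0], 0, T,
                                     limit=200)
        sT = sol.s_at([T])[0]
        expected = (1 - sT + mu * T - integral) / (1 + mu * T - integral)
        assert cl.tau_T(sol, dg, n) == pytest.approx(expected, abs=1e-6)


class TestSampleN:
    def test_mean_is_n_I_over_tau(self):
        rng = np.random.default_rng(0)
        draws = np.array([cl.sample_n(100, 0.5, rng) for _ in range(100_000)])
        assert draws.mean() == pytest.approx(200, rel=0.01)
        assert np.all(draws >= 100)

    def test_tau_one_is_degenerate_at_n_I(self):
        rng = np.random.default_rng(0)
        assert cl.sample_n(50, 1.0 - 1e-13, rng) == 50


class TestRAM:
    def test_gaussian_target_acceptance_converges_to_0234(self):
        """On a standard 3-D Gaussian the long-run acceptance rate must
        settle at the 0.234 target within 0.03."""
        rng = np.random.default_rng(1)
        logp = lambda x: -0.5 * float(x @ x)
        phi = np.zeros(3)
        lp = logp(phi)
        S = np.eye(3) * 3.0  # deliberately poor initial scale
        acc = []
        for it in range(1, 50_001):
            phi, lp, accepted, S, _ = ram_step(phi, lp, logp, S, it, rng)
            acc.append(accepted)
        assert abs(np.mean(acc[-20_000:]) - 0.234) < 0.03

    def test_cholesky_factor_stays_lower_triangular_positive(self):
        rng = np.random.default_rng(2)
        logp = lambda x: -0.5 * float(x @ x)
        phi, lp, S = np.zeros(2), 0.0, np.eye(2)
        for it in range(1, 500):
            phi, lp, _, S, _ = ram_step(phi, lp, logp, S, it, rng)
            assert np.allclose(S, np.tril(S))
            assert np.all(np.diag(S) > 0)

    def test_zero_adaptation_leaves_factor_unchanged(self):
        rng = np.random.default_rng(3)
        logp = lambda x: -0.5 * float(x @ x)
        S0 = np.eye(2) * 0.7
        _, _, _, S, _ = ram_step(np.zeros(2), 0.0, logp, S0, 0, rng)
        np.testing.assert_array_equal(S, S0)

    def test_nonfinite_proposal_is_rejected(self):
        rng = np.random.default_rng(4)
        logp = lambda x: -np.inf if np.any(np.abs(x) > 0) else 0.0
        phi, lp, _, _, alpha = ram_step(np.zeros(2), 0.0, logp,
                                        np.eye(2), 1, rng)
        assert alpha == 0.0
        np.testing.assert_array_equal(phi, np.zeros(2))

    def test_posterior_matches_quadrature_on_logistic_surrogate(self):
        """With the offset fixed at s = 1 the intercept posterior is a 1-D
        Bernoulli-logit posterior; RAM sampling must match grid
        integration of the same density to Monte-Carlo precision."""
        rng = np.random.default_rng(5)
        y = np.concatenate([np.ones(60), np.zeros(40)])

        def loglik(alpha):
            return float(np.sum(y * (-np.logaddexp(0, -alpha))
                                + (1 - y) * (-np.logaddexp(0, alpha))))

        grid = np.linspace(-2, 3, 4001)
        dens = np.exp([loglik(a) - loglik(0.405) for a in grid])
        dens /= np.trapezoid(dens, grid)
        mean_quad = np.trapezoid(grid * dens, grid)
        var_quad = np.trapezoid((grid - mean_quad) ** 2 * dens, grid)

        logp = lambda x: loglik(float(x[0]))
        phi, lp, S = np.array([0.0]), logp(np.zeros(1)), np.eye(1)
        draws = []
        for it in range(1, 20_001):
            phi, lp, _, S, _ = ram_step(phi, lp, logp, S, it, rng)
            draws.append(phi[0])
        draws = np.array(draws[5000:])
        assert draws.mean() == pytest.approx(mean_quad, abs=0.02)
        assert draws.var() == pytest.approx(var_quad, rel=0.15)


class TestTransforms:
    def test_phi_theta_round_trip_with_jacobian_finite(self):
        th = EpiTheta(0.36, 0.28, 1.2e-3)
        phi = _phi_from_theta(th)
        back = _theta_from_phi(phi)
        assert back.beta == pytest.approx(th.beta)
        assert back.gamma == pytest.approx(th.gamma)
        assert back.rho == pytest.approx(th.rho)
        assert np.isfinite(_log_jac(phi))


class TestRunMCMC:
    def test_no_infections_is_unidentifiable(self):
        ev = EpiEventSeries(times=[1.0, 2.0], y=[0, 0], I0=5, T=3.0)
        with pytest.raises(ValueError, match="unidentifiable"):
            cl.run_mcmc(ev, config=MCMCConfig(n_iter=10, burn_in=5))

    def test_near_empty_data_posterior_tracks_gamma_prior(self):
        """With two events the informative Gamma(2820, 1e4) prior dominates:
        the posterior mean of gamma stays within 2 prior SDs of 0.282."""
        ev = EpiEventSeries(times=[1.0, 2.0], y=[1, 0], I0=3, T=5.0)
        chain = cl.run_mcmc(ev, config=MCMCConfig(n_iter=600, burn_in=300,
                                                  seed=8, n_init=1e3))
        post_mean = chain.posterior()["gamma"].mean()
        prior_sd = np.sqrt(PRIOR_GAMMA[0]) / PRIOR_GAMMA[1]
        assert abs(post_mean - 0.282) < 2 * prior_sd

    def test_defaults_match_published_protocol(self):
        cfg = MCMCConfig()
        assert cfg.n_iter == 4000 and cfg.burn_in == 2000
        assert cfg.n_init == 3e4
        assert cfg.target_rate == 0.234


class TestSummaries:
    def _constant_chain(self, beta, gamma, rho, n, n_draws=300):
        draws = pd.DataFrame({
            "iter": np.arange(1, 2 * n_draws + 1),
            "beta": beta, "gamma": gamma, "rho": rho, "n": n,
            "accepted": True, "alpha": 1.0,
        })
        cfg = MCMCConfig(n_iter=2 * n_draws, burn_in=n_draws)
        return PosteriorChain(draws=draws, burn_in=n_draws, config=cfg)

    def test_constant_chain_has_equal_six_numbers(self):
        chain = self._constant_chain(0.3, 0.2, 0.001, 30000)
        stats_df, r0 = cl.summarize(chain)
        for col in stats_df.columns:
            np.testing.assert_allclose(stats_df[col], stats_df[col].iloc[0],
                                       rtol=1e-12)
        assert r0["r0_mean_of_ratios"] == pytest.approx(1.5)

    def test_summaries_exclude_burn_in(self):
        n_draws = 200
        draws = pd.DataFrame({
            "iter": np.arange(1, 2 * n_draws + 1),
            "beta": np.concatenate([np.full(n_draws, 99.0), np.full(n_draws, 0.3)]),
            "gamma": 0.2, "rho": 0.001, "n": 1000.0,
            "accepted": True, "alpha": 1.0,
        })
        chain = PosteriorChain(draws=draws, burn_in=n_draws,
                               config=MCMCConfig(n_iter=2 * n_draws, burn_in=n_draws))
        stats_df, _ = cl.summarize(chain)
        assert stats_df.loc["Max.", "beta"] == pytest.approx(0.3)

    def test_fitted_prevalence_single_draw_and_band(self):
        chain = self._constant_chain(0.36, 0.28, 1.2e-3, 30000.0)
        grid = np.linspace(0.0, 50.0, 51)
        fit = cl.fitted_prevalence(chain, Demography.none(), grid=grid)
        # constant chain: mean curve equals the posterior-mean curve
        np.testing.assert_allclose(fit.mean_curve, fit.posterior_mean_curve,
                                   rtol=1e-8)
        assert np.all(fit.lower <= fit.mean_curve + 1e-9)
        assert np.all(fit.mean_curve <= fit.upper + 1e-9)
        # prevalence at t=0 is rho * n
        assert fit.mean_curve[0] == pytest.approx(1.2e-3 * 30000.0)
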