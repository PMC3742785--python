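import numpy as np
import pandas as pd
import pytest

import dielmetab as dm
from dielmetab.metabolism import DegenerateLikelihoodError, MetabolismPosterior

from _oracles import quadrature_loglik
from conftest import make_simple_day


class TestStepO2:
    def test_respiration_only_step(self):
        p = dm.MetabParams(I=0.0, rho20=0.3, K20=0.0, o2_init=5.0)
        assert dm.step_o2(p, 5.0, 0.0, 20.0) == pytest.approx(5.0 - 0.3, rel=1e-12)

    def test_equilibrium_without_metabolism(self):
        p = dm.MetabParams(I=0.0, rho20=0.0, K20=1.0, o2_init=5.0)
        sat = dm.o2_saturation(28.0)
        assert dm.step_o2(p, sat, 0.0, 28.0) == pytest.approx(sat, rel=1e-12)

    def test_dark_fixed_point_is_fixed(self):
        p = dm.MetabParams(I=0.0, rho20=0.25, K20=0.8, o2_init=5.0)
        x_star = dm.dark_fixed_point(p, temp=30.0)
        assert dm.step_o2(p, x_star, 0.0, 30.0) == pytest.approx(x_star, abs=1e-12)


class TestDailyRates:
    def test_gpp_arithmetic(self):
        qp = np.zeros(48)
        qp[:24] = 1.0
        day = make_simple_day(qp=qp, temp=20.0)
        gpp, _ = dm.daily_rates(np.array([[0.01, 0.0]]), day)
        assert gpp[0] == pytest.approx(0.24, rel=1e-12)

    def test_er_arithmetic_at_reference_temperature(self):
        day = make_simple_day(temp=20.0)
        _, er = dm.daily_rates(np.array([[0.0, 0.2]]), day)
        assert er[0] == pytest.approx(9.6, rel=1e-12)

    def test_er_arrhenius_closed_form_matches_step_loop(self):
        day = make_simple_day(temp=30.0)
        rho20 = 0.13
        _, er = dm.daily_rates(np.array([[0.0, rho20]]), day, theta=1.047)
        closed = 48 * rho20 * 1.047**10
        loop = sum(rho20 * 1.047 ** (t - 20.0) for t in day.temp)
        assert er[0] == pytest.approx(closed, rel=1e-12)
        assert er[0] == pytest.approx(loop, rel=1e-12)


def test_conservation_without_gas_exchange():
    """With K20 = 0 and no noise, the day's net DO change equals
    GPP_day - ER_day exactly (discrete sum identity)."""
    rng = np.random.default_rng(42)
    for _ in range(100):
        n = 48
        qp = np.maximum(0.0, rng.normal(500, 400, n))
        qp[rng.random(n) < 0.5] = 0.0
        temp = rng.uniform(22, 34, n)
        p = dm.MetabParams(I=rng.uniform(0, 5e-4), rho20=rng.uniform(0, 0.8),
                           K20=0.0, o2_init=rng.uniform(2, 9))
        day = dm.StateSpaceDay(y=np.full(n, 5.0), qp=qp, temp=temp)
        path = dm.simulate_path(p, qp, temp)
        gpp, er = dm.daily_rates(np.array([[p.I, p.rho20]]), day, theta=p.theta)
        assert path[-1] - path[0] == pytest.approx(gpp[0] - er[0], abs=1e-9)


def test_dark_equilibrium_forward_simulation_constant():
    """Dark constant-temperature simulation started at the analytic fixed
    point stays there to 1e-10."""
    p = dm.MetabParams(I=0.0, rho20=0.2, K20=0.6, o2_init=0.0)
    x_star = dm.dark_fixed_point(p, temp=29.0)
    p = dm.MetabParams(I=0.0, rho20=0.2, K20=0.6, o2_init=x_star)
    path = dm.simulate_path(p, np.zeros(48), np.full(48, 29.0))
    assert np.max(np.abs(path - x_star)) < 1e-10


class TestLoglik:
    def test_zero_process_noise_collapses_to_regression(self):
        n = 6
        qp = np.array([0.0, 100.0, 400.0, 300.0, 50.0, 0.0])
        temp = np.full(n, 27.0)
        p = dm.MetabParams(I=2e-4, rho20=0.2, K20=0.4, o2_init=5.0)
        noise = dm.NoiseParams(sigma_p=0.0, sigma_o=0.25)
        path = dm.simulate_path(p, qp[:-1], temp[:-1])
        rng = np.random.default_rng(1)
        y = path + rng.normal(0, 0.25, n)
        day = dm.StateSpaceDay(y=y, qp=qp, temp=temp)
        expected = np.sum(
            -0.5 * (np.log(2 * np.pi * 0.25**2) + ((y - path) / 0.25) ** 2))
        assert dm.loglik_day(day, p, noise) == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("missing", [None, 1])
    def test_matches_quadrature_on_three_step_day(self, missing):
        qp = np.array([0.0, 300.0, 600.0])
        temp = np.array([28.0, 28.5, 29.0])
        p = dm.MetabParams(I=3e-4, rho20=0.3, K20=0.5, o2_init=5.0)
        noise = dm.NoiseParams(sigma_p=0.08, sigma_o=0.2)
        y = np.array([5.1, 4.9, 5.3])
        if missing is not None:
            y[missing] = np.nan
        day = dm.StateSpaceDay(y=y, qp=qp, temp=temp)
        got = dm.loglik_day(day, p, noise)
        want = quadrature_loglik(p, noise, y, temp, qp)
        assert got == pytest.approx(want, rel=1e-6)

    def test_degenerate_noise(self):
        qp = np.array([0.0, 200.0, 100.0])
        temp = np.full(3, 26.0)
        p = dm.MetabParams(I=1e-4, rho20=0.1, K20=0.2, o2_init=6.0)
        path = dm.simulate_path(p, qp[:-1], temp[:-1])
        ok_day = dm.StateSpaceDay(y=path, qp=qp, temp=temp)
        assert dm.loglik_day(ok_day, p, dm.NoiseParams(0.0, 0.0)) == 0.0
        bad = path.copy()
        bad[2] += 0.5
        bad_day = dm.StateSpaceDay(y=bad, qp=qp, temp=temp)
        with pytest.raises(DegenerateLikelihoodError):
            dm.loglik_day(bad_day, p, dm.NoiseParams(0.0, 0.0))


class TestFitDay:
    def test_near_noise_free_recovery(self, site):
        """With tiny noise the posterior pins the generating daily GPP to <5%."""
        import dataclasses
        spec = dataclasses.replace(
            dm.tonle_sap_preset("net_heterotrophic", n_days=2, seed=5),
            noise=dm.NoiseParams(sigma_p=0.01, sigma_o=0.01))
        series, winds, truth = dm.simulate_campaign(spec)
        segs = [s for s in dm.segment_days(series, site) if s.usable]
        seg = dm.attach_k20_prior(segs[0], {w.date: w.u10_ms for w in winds}, site)
        post = dm.fit_day(dm.StateSpaceDay.from_segment(seg),
                          mcmc=dm.FAST_CHAINS, seed=9)
        s = dm.summarize_posterior(post)
        tr = truth.loc[seg.date]
        assert s["gpp_med"] == pytest.approx(tr["gpp"], rel=0.05)
        assert s["er_med"] == pytest.approx(tr["er"], rel=0.05)

    def test_seed_contract(self, fitted_day):
        day, post, _ = fitted_day
        again = dm.fit_day(day, mcmc=dm.FAST_CHAINS, seed=11)
        pd.testing.assert_frame_equal(post.draws, again.draws)
        other = dm.fit_day(day, mcmc=dm.FAST_CHAINS, seed=12)
        sd = post.draws["gpp"].std()
        assert abs(post.draws["gpp"].median() - other.draws["gpp"].median()) < 0.5 * sd

    def test_flat_day_is_insufficient(self):
        rng = np.random.default_rng(3)
        day = make_simple_day(do=5.0 + rng.normal(0, 0.05, 48), temp=30.0)
        post = dm.fit_day(day, mcmc=dm.FAST_CHAINS, seed=2)
        assert not dm.sufficiency_filter(post, day)
        # no diel signal: the GPP posterior is diffuse and reaches near zero
        assert post.draws["gpp"].quantile(0.025) < 0.5

    def test_matches_independent_ensemble_sampler(self, fitted_day):
        """Same log-posterior sampled with emcee gives the same posterior."""
        emcee = pytest.importorskip("emcee")
        from dielmetab import _sampler
        from dielmetab.metabolism import PriorSet, _prior_bounds, _initial_guess

        day, post, _ = fitted_day
        obs, y, qp, resp, osat, scfac = day.driver_arrays(1.047)
        lo, hi, k20n, mu, sd = _prior_bounds(PriorSet(), day.k20_prior)

        def logp(t):
            return _sampler._log_post(t, y, obs, qp, resp, osat, scfac,
                                      day.step_h, lo, hi, k20n, mu, sd)

        x0 = _initial_guess(day, lo, hi, k20n, mu, sd, 1.047, None)
        rng = np.random.default_rng(0)
        p0 = np.clip(x0 * np.exp(rng.normal(0, 0.05, (32, 6))), lo + 1e-9, hi - 1e-9)
        sampler = emcee.EnsembleSampler(32, 6, logp)
        sampler.run_mcmc(p0, 3000, progress=False)
        chain = sampler.get_chain(discard=1500, thin=10, flat=True)
        gpp_emcee = np.median(chain[:, 0]) * day.qp.sum()
        gpp_mine = post.draws["gpp"].median()
        assert gpp_mine == pytest.approx(gpp_emcee, rel=0.08)

    def test_scale_invariance_of_gpp(self, fitted_day):
        """Rescaling photon flux by c and the I prior by 1/c leaves the
        daily-GPP posterior unchanged up to Monte-Carlo error."""
        day, post, _ = fitted_day
        c = 10.0
        scaled = dm.StateSpaceDay(y=day.y, qp=day.qp * c, temp=day.temp,
                                  step_h=day.step_h, k20_prior=day.k20_prior)
        priors = dm.PriorSet(I=dm.Prior.uniform(0.0, 0.05 / c))
        post2 = dm.fit_day(scaled, priors=priors, mcmc=dm.FAST_CHAINS, seed=11)
        m1, m2 = post.draws["gpp"].median(), post2.draws["gpp"].median()
        assert m2 == pytest.approx(m1, rel=0.1)


class TestPosteriorSummaries:
    def test_degenerate_draws(self):
        draws = pd.DataFrame({
            "I": 1e-4, "rho20": 0.2, "K20": 0.3, "o2_init": 5.0,
            "sigma_p": 0.05, "sigma_o": 0.2, "chain": 0,
            "gpp": 4.0, "er": 10.0,
        }, index=range(50))
        post = MetabolismPosterior(draws=draws, diagnostics={"converged": True})
        s = dm.summarize_posterior(post)
        assert s["gpp_med"] == 4.0
        assert s["gpp_lo"] == s["gpp_hi"] == 4.0
        assert s["er_gpp_ratio"] == pytest.approx(2.5)

    def test_symmetric_draws_median_near_mean(self, fitted_day):
        _, post, _ = fitted_day
        g = post.draws["gpp"]
        assert abs(g.median() - g.mean()) < 0.5 * g.std()

    def test_saved_draw_count_follows_protocol(self, fitted_day):
        _, post, _ = fitted_day
        assert len(post.draws) == dm.FAST_CHAINS.n_saved
        assert dm.ChainConfig().n_saved == 7500
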