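"""Gibbs sampler conditionals, GELF estimation, HPD intervals, diagnostics."""

import numpy as np
import pytest
from scipy import stats

from raycens.bayes import (
    GibbsConfig,
    PriorSpec,
    _printed_f3,
    convergence_diagnostics,
    draw_invgamma,
    gamma2_conditional,
    gelf_estimate,
    gelf_risk,
    gibbs_sample,
    hpd_interval,
    mu_inverse_cdf,
    sigma2_conditional,
)
from raycens.model import CensoredSample, CensoringModel, sample_censored


class TestConditionals:
    def test_sigma2_conditional_matches_invgamma(self, medium_sample):
        """With mu fixed, the sigma^2 update is exactly InvGamma(a1+w1, b+S(mu)/2)."""
        prior = PriorSpec(2.0, 1.5, 1.0, 1.5)
        mu = 0.3
        shape, scale = sigma2_conditional(medium_sample, mu, prior)
        assert shape == prior.a1 + medium_sample.w1
        assert scale == pytest.approx(prior.b1 + 0.5 * medium_sample.w2(mu), rel=1e-12)
        rng = np.random.default_rng(41)
        draws = draw_invgamma(rng, shape, scale, size=100_000)
        res = stats.kstest(draws, stats.invgamma(shape, scale=scale).cdf)
        assert res.pvalue > 0.01

    def test_gamma2_conditional_shape(self, medium_sample):
        prior = PriorSpec.noninformative()
        shape, scale = gamma2_conditional(medium_sample, 0.2, prior)
        assert shape == medium_sample.n - medium_sample.w1
        assert scale == pytest.approx(0.5 * medium_sample.w2(0.2), rel=1e-12)

    def test_invgamma_moment_oracle(self):
        # InvGamma(alpha, b') mean b'/(alpha - 1): alpha = a1 + w1 = 5, b' = 5
        rng = np.random.default_rng(43)
        draws = draw_invgamma(rng, 5.0, 5.0, size=100_000)
        assert abs(draws.mean() - 5.0 / 4.0) < 0.02


class TestMuInverseCDF:
    def test_u_one_returns_minimum(self, medium_sample):
        prior = PriorSpec.noninformative()
        assert mu_inverse_cdf(1.0, medium_sample, prior) == pytest.approx(
            medium_sample.y_min, abs=1e-10
        )

    def test_two_point_hand_inversion(self):
        # y = {1, 2}, a1 = a2 = b = 0: exponent 1, F3(mu) = 1/((1-mu)^2 + (2-mu)^2)
        s = CensoredSample(y=np.array([1.0, 2.0]), d=np.array([1, 0]))
        prior = PriorSpec.noninformative()
        mu = mu_inverse_cdf(0.5, s, prior)
        assert mu == pytest.approx((3.0 - np.sqrt(3.0)) / 2.0, rel=1e-10)
        assert mu == pytest.approx(0.63397, abs=1e-5)

    def test_round_trip(self, medium_sample):
        prior = PriorSpec(1.0, 2.0, 1.5, 2.0)
        for u in (0.05, 0.3, 0.7, 0.99):
            mu = mu_inverse_cdf(u, medium_sample, prior)
            assert _printed_f3(mu, medium_sample, prior) == pytest.approx(u, abs=1e-10)

    def test_monotone_in_u(self, medium_sample):
        prior = PriorSpec.noninformative()
        us = np.linspace(0.01, 1.0, 50)
        mus = mu_inverse_cdf(us, medium_sample, prior)
        assert np.all(np.diff(mus) > 0)

    def test_rejects_bad_u(self, medium_sample):
        with pytest.raises(ValueError):
            mu_inverse_cdf(0.0, medium_sample, PriorSpec.noninformative())


class TestGibbs:
    def test_invariants_and_reproducibility(self, medium_sample):
        cfg = GibbsConfig(iterations=500, burn_in=100, chains=2, seed=5)
        prior = PriorSpec.noninformative()
        d1 = gibbs_sample(medium_sample, prior, cfg)
        d2 = gibbs_sample(medium_sample, prior, cfg)
        assert np.array_equal(d1.mu, d2.mu)
        assert np.all(d1.sigma2 > 0) and np.all(d1.gamma2 > 0)
        assert np.all((d1.mu >= 0) & (d1.mu < medium_sample.y_min))

    def test_printed_mode_requires_common_b(self, medium_sample):
        cfg = GibbsConfig(iterations=200, burn_in=50, chains=1, seed=1, mu_sampler="printed")
        with pytest.raises(ValueError, match="b1 != b2"):
            gibbs_sample(medium_sample, PriorSpec(1.0, 1.0, 1.0, 2.0), cfg)

    def test_printed_mode_concentrates_near_minimum(self, medium_sample):
        """The closed-form mu conditional omits the product term and hence
        piles up just below y_(1); the exact sampler sits lower."""
        prior = PriorSpec.noninformative()
        exact = gibbs_sample(
            medium_sample, prior, GibbsConfig(iterations=2000, burn_in=500, chains=1, seed=2)
        )
        printed = gibbs_sample(
            medium_sample,
            prior,
            GibbsConfig(iterations=2000, burn_in=500, chains=1, seed=2, mu_sampler="printed"),
        )
        assert printed.posterior("mu").mean() > exact.posterior("mu").mean()

    def test_posterior_propriety_grid(self, medium_sample):
        """Unnormalised posterior integrates finitely under flat priors."""
        from raycens.classical import loglik_censored

        mus = np.linspace(0.0, medium_sample.y_min * 0.999, 40)
        sigmas = np.linspace(0.3, 3.0, 40)
        gammas = np.linspace(0.3, 3.0, 40)
        lls = np.array(
            [
                loglik_censored(medium_sample, m, s, g)
                for m in mus
                for s in sigmas
                for g in gammas
            ]
        )
        total = np.exp(lls - lls.max()).sum()
        assert np.isfinite(total) and total > 0

    def test_parameter_recovery_n200(self):
        """Posterior concentrates near the truth for a large sample."""
        s = sample_censored(CensoringModel(0.5, 1.0, 1.0), 200, seed=47)
        draws = gibbs_sample(
            s,
            PriorSpec.noninformative(),
            GibbsConfig(iterations=4000, burn_in=1000, chains=1, seed=8),
        )
        for name, truth in (("mu", 0.5), ("sigma2", 1.0), ("gamma2", 1.0)):
            post = draws.posterior(name)
            assert abs(post.mean() - truth) < 4 * post.std()


class TestGELF:
    def test_constant_draws(self):
        for delta in (-2.0, -1.0, 1.0, 2.0):
            assert gelf_estimate(np.full(100, 3.2), delta) == pytest.approx(3.2, rel=1e-12)
            assert gelf_risk(np.full(100, 3.2), delta) == pytest.approx(0.0, abs=1e-12)

    def test_two_point_hand_value(self):
        draws = np.array([1.0, 2.0])
        est = gelf_estimate(draws, 2.0)
        assert est == pytest.approx(0.625**-0.5, rel=1e-12)
        assert est == pytest.approx(1.26491, abs=1e-5)
        risk = gelf_risk(draws, 2.0)
        assert risk == pytest.approx(np.log(2.0) - 2.0 * np.log(0.625**-0.5), rel=1e-9)
        assert risk == pytest.approx(0.22314, abs=1e-4)

    def test_delta_minus_one_is_mean(self):
        rng = np.random.default_rng(3)
        draws = rng.gamma(4.0, size=1000)
        assert gelf_estimate(draws, -1.0) == pytest.approx(draws.mean(), rel=1e-12)

    def test_risk_decreases_with_concentration(self):
        rng = np.random.default_rng(7)
        wide = 2.0 + rng.normal(0, 0.4, 50_000)
        narrow = 2.0 + rng.normal(0, 0.2, 50_000)
        assert gelf_risk(narrow, 1.0) < gelf_risk(wide, 1.0)

    def test_risk_nonnegative(self):
        rng = np.random.default_rng(11)
        draws = rng.lognormal(0.0, 1.0, 10_000)
        for delta in (-2.0, -1.0, 1.0, 2.0):
            assert gelf_risk(draws, delta) >= 0.0

    def test_fractional_power_guard(self):
        with pytest.raises(ValueError):
            gelf_estimate(np.array([-1.0, 2.0]), 0.5)


class TestHPD:
    def test_enumeration_tie_break(self):
        res = hpd_interval(np.arange(1, 101, dtype=float), alpha=0.05)
        assert res.k == 95
        assert (res.low, res.up) == (1.0, 96.0)

    def test_width_at_most_equal_tailed(self):
        rng = np.random.default_rng(19)
        draws = rng.gamma(3.0, size=20_000)
        res = hpd_interval(draws, 0.05)
        lo, up = np.quantile(draws, [0.025, 0.975])
        assert res.width <= (up - lo) + 1e-12

    def test_normal_symmetry(self):
        rng = np.random.default_rng(23)
        draws = rng.standard_normal(100_000)
        res = hpd_interval(draws, 0.05)
        assert res.low == pytest.approx(-1.96, abs=0.05)
        assert res.up == pytest.approx(1.96, abs=0.05)

    def test_too_few_draws(self):
        with pytest.raises(ValueError):
            hpd_interval(np.arange(5, dtype=float), 0.05)


class TestDiagnostics:
    def test_iid_chains_converged(self):
        rng = np.random.default_rng(29)
        from raycens.bayes import PosteriorDraws

        arr = lambda: rng.standard_normal((3, 4000)) + 5.0
        draws = PosteriorDraws(mu=np.abs(arr()), sigma2=np.abs(arr()), gamma2=np.abs(arr()), burn_in=0)
        diag = convergence_diagnostics(draws)
        for name in ("mu", "sigma2", "gamma2"):
            assert diag[name]["rhat"] < 1.01
            assert diag[name]["ess"] > 1000
            assert diag[name]["ok"]

    def test_disjoint_chains_flagged(self):
        from raycens.bayes import PosteriorDraws

        rng = np.random.default_rng(31)
        a = rng.standard_normal((1, 2000)) + 100.0
        b = rng.standard_normal((1, 2000)) + 1.0
        chains = np.vstack([a, b])
        draws = PosteriorDraws(mu=chains, sigma2=np.abs(chains), gamma2=np.abs(chains), burn_in=0)
        diag = convergence_diagnostics(draws)
        assert diag["mu"]["rhat"] > 1.1
        assert not diag["mu"]["ok"]

    def test_single_chain_reports_no_rhat(self):
        from raycens.bayes import PosteriorDraws

        rng = np.random.default_rng(37)
        one = np.abs(rng.standard_normal((1, 12_000))) + 1.0
        draws = PosteriorDraws(mu=one, sigma2=one.copy(), gamma2=one.copy(), burn_in=0)
        diag = convergence_diagnostics(draws)
        assert diag["mu"]["rhat"] is None
        # iid draws: ESS approximately equals the number of draws
        assert diag["mu"]["ess"] == pytest.approx(12_000, rel=0.15)
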