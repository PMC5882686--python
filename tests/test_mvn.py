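import numpy as np
import pytest
from scipy import integrate, stats

import steppingstone as ss
from steppingstone.ladder import make_ladder
from steppingstone.mvn import MVNModelSpec, posterior_moments
from steppingstone.tempering import run_power_posteriors


def _spec_1d(lam, log_peak=0.0):
    return MVNModelSpec(
        mean_lik=np.zeros(1), Sigma=np.eye(1), mean_prior=np.zeros(1),
        Omega=np.array([[lam**2]]), log_peak=log_peak,
    )


class TestAnalyticEvidence:
    def test_one_dimensional_closed_form(self):
        # common means, unit likelihood curvature: -2 log P(y) = log(1 + lam^2)
        for lam in (0.3, 1.0, 2.5):
            assert ss.analytic_minus2_log_evidence(_spec_1d(lam)) == pytest.approx(
                np.log(1 + lam**2)
            )

    def test_delta_prior_limit_recovers_likelihood_peak(self):
        spec = MVNModelSpec(
            mean_lik=np.zeros(2), Sigma=np.eye(2), mean_prior=np.zeros(2),
            Omega=1e-12 * np.eye(2), log_peak=-3.7,
        )
        assert ss.analytic_minus2_log_evidence(spec) == pytest.approx(7.4, abs=1e-6)

    def test_diffuse_prior_sends_evidence_to_infinity(self):
        vals = [
            ss.analytic_minus2_log_evidence(_spec_1d(lam)) for lam in (1, 10, 100)
        ]
        assert vals[0] < vals[1] < vals[2]
        assert vals[2] > 9.0

    def test_monotone_in_prior_sd_common_mean_scenario(self):
        lams = np.linspace(0.1, 20, 40)
        vals = [ss.analytic_minus2_log_evidence(_spec_1d(l)) for l in lams]
        assert np.all(np.diff(vals) > 0)

    def test_quadrature_agreement_1d(self):
        spec = _spec_1d(1.7, log_peak=-0.3)

        def integrand(t):
            return np.exp(spec.log_peak - 0.5 * t**2) * stats.norm.pdf(t, 0, 1.7)

        val, _ = integrate.quad(integrand, -30, 30, epsabs=1e-13, epsrel=1e-13)
        assert ss.analytic_minus2_log_evidence(spec) == pytest.approx(
            -2 * np.log(val), rel=1e-8
        )

    def test_quadrature_agreement_2d(self):
        Sigma = np.array([[1.0, 0.2], [0.2, 1.5]])
        Omega = np.array([[0.8, -0.1], [-0.1, 1.2]])
        mu_l = np.array([0.3, -0.2])
        mu_p = np.array([-0.1, 0.4])
        spec = MVNModelSpec(mu_l, Sigma, mu_p, Omega, log_peak=0.0)
        Sinv = np.linalg.inv(Sigma)
        prior = stats.multivariate_normal(mu_p, Omega)

        def integrand(y, x):
            z = np.array([x, y]) - mu_l
            return np.exp(-0.5 * z @ Sinv @ z) * prior.pdf([x, y])

        val, _ = integrate.dblquad(
            integrand, -8, 8, -8, 8, epsabs=1e-12, epsrel=1e-12
        )
        assert ss.analytic_minus2_log_evidence(spec) == pytest.approx(
            -2 * np.log(val), rel=1e-8
        )

    def test_non_positive_definite_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError):
            ss.analytic_minus2_log_evidence(
                MVNModelSpec(np.zeros(2), bad, np.zeros(2), np.eye(2))
            )


class TestAnalyticDIC:
    def test_flat_prior_penalties_reach_twice_parameter_count(self):
        for d in (1, 3, 10):
            spec = MVNModelSpec(
                np.zeros(d), np.eye(d), np.zeros(d), 1e12 * np.eye(d)
            )
            res = ss.analytic_dic(spec)
            assert res.penalty1 == pytest.approx(2 * d, abs=1e-6)
            assert res.penalty2 == pytest.approx(2 * d, abs=1e-6)

    def test_concentrated_prior_kills_both_penalties(self):
        spec = MVNModelSpec(
            np.zeros(3), np.eye(3), np.zeros(3), 1e-12 * np.eye(3), log_peak=1.0
        )
        res = ss.analytic_dic(spec)
        assert res.penalty1 == pytest.approx(0.0, abs=1e-6)
        assert res.dic1 == pytest.approx(-2.0, abs=1e-6)

    def test_unit_scalar_case_by_hand(self):
        # Sigma = Omega = 1: psi = 1/2, so DIC1 penalty = 2 * 1/2 = 1 and
        # DIC2 penalty = 1/2 + 1/4 = 3/4 (common means, Delta-theta = 0)
        res = ss.analytic_dic(_spec_1d(1.0))
        assert res.penalty1 == pytest.approx(1.0)
        assert res.penalty2 == pytest.approx(0.75)

    @pytest.mark.parametrize("d", [1, 3])
    def test_monte_carlo_from_exact_posterior_converges(self, d, rng):
        spec = ss.mvn_scenario(d=d, lam=1.3, seed=4)
        post = posterior_moments(spec)
        n = 200000
        chol = np.linalg.cholesky(post.psi)
        theta = post.mu + rng.standard_normal((n, d)) @ chol.T
        Sinv = np.linalg.inv(spec.Sigma)
        z = theta - spec.mean_lik
        logl = spec.log_peak - 0.5 * np.einsum("ij,jk,ik->i", z, Sinv, z)
        zb = theta.mean(axis=0) - spec.mean_lik
        plugin = spec.log_peak - 0.5 * zb @ Sinv @ zb
        mc1 = ss.dic1(logl, plugin).value
        mc2 = ss.dic2(logl).value
        exact = ss.analytic_dic(spec)
        assert mc1 == pytest.approx(exact.dic1, abs=0.05)
        assert mc2 == pytest.approx(exact.dic2, abs=0.1)


class TestScenarioAndSampling:
    def test_scenario_factory_reproducible_and_valid(self):
        a = ss.mvn_scenario(10, 1.0, seed=3)
        b = ss.mvn_scenario(10, 1.0, seed=3)
        c = ss.mvn_scenario(10, 1.0, seed=4)
        assert np.array_equal(a.Sigma, b.Sigma)
        assert not np.array_equal(a.Sigma, c.Sigma)
        assert np.all(np.diag(a.Sigma) == 1.0)
        off = a.Sigma[~np.eye(10, dtype=bool)]
        assert np.all(np.abs(off) <= 0.1)
        assert np.all(np.linalg.eigvalsh(a.Sigma) > 0)
        with pytest.raises(ValueError):
            ss.mvn_scenario(10, lam=0.0)

    def test_likelihood_peak_normalized_to_one(self):
        spec = ss.mvn_scenario(5, 1.0, seed=2)
        model = ss.mvn_model_interface(spec)
        assert model.log_obs(spec.mean_lik, None) == pytest.approx(0.0)

    def test_generic_sampler_recovers_posterior_moments(self):
        spec = ss.mvn_scenario(3, 1.0, seed=6)
        post = posterior_moments(spec)
        model = ss.mvn_model_interface(spec)
        trace = run_power_posteriors(
            model, make_ladder(4), 500, 6000, seed=8, record_summaries=True
        )
        draws = trace.posterior_summaries
        se_mean = np.sqrt(np.diag(post.psi) / draws.shape[0])
        # single-site walk: allow generous autocorrelation inflation
        assert np.all(np.abs(draws.mean(axis=0) - post.mu) < 12 * se_mean)
        assert np.allclose(np.cov(draws.T), post.psi, atol=0.15)

    def test_vectorized_evidence_matches_analytic(self):
        spec = ss.mvn_scenario(10, 1.0, seed=3)
        exact = ss.analytic_minus2_log_evidence(spec)
        est, extras = ss.mvn_evidence(spec, K=20, n_burnin=1000, n_samples=10000, seed=1)
        assert abs(est.minus_two_log_evidence - exact) < 3 * (2 * est.se)
        exact_dic = ss.analytic_dic(spec)
        assert extras["dic"]["DIC1"].value == pytest.approx(exact_dic.dic1, abs=0.5)
        assert extras["dic"]["DIC2"].value == pytest.approx(exact_dic.dic2, abs=0.5)
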