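import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import kstest, norm

import steppingstone as ss
from steppingstone.ladder import make_ladder
from steppingstone.scan import lm_evidence, nested_model_scan, scan_argmin
from steppingstone.tempering import run_power_posteriors, stepping_stone_log_evidence


class TestSimulators:
    def test_design_intercept_and_balance(self):
        X = ss.simulate_design(10000, 5, 3)
        assert np.all(X[:, 0] == 1.0)
        assert set(np.unique(X[:, 1:])) == {0.0, 1.0}
        assert np.all(np.abs(X[:, 1:].mean(axis=0) - 0.5) < 0.015)

    def test_design_seed_determinism(self):
        assert np.array_equal(ss.simulate_design(50, 4, 9), ss.simulate_design(50, 4, 9))

    def test_noise_free_simulation_is_exact(self):
        X = ss.simulate_design(20, 3, 1)
        beta = np.array([1.0, -0.5, 0.25])
        data = ss.simulate_lm(X, beta, eta2_true=0.0, seed=5)
        assert np.allclose(data.y, X @ beta)

    def test_residual_variance_matches_truth(self):
        X = ss.simulate_design(10000, 10, 1)
        beta = ss.default_lm_truth()
        data = ss.simulate_lm(X, beta, eta2_true=1.0, seed=2)
        resid = data.y - X @ beta
        assert resid.var() == pytest.approx(1.0, rel=0.05)

    def test_csv_round_trip(self, tmp_path, lm_small):
        path = tmp_path / "reg.csv"
        lm_small.to_csv(path)
        back = ss.RegressionData.from_csv(path)
        assert np.allclose(back.y, lm_small.y)
        assert np.allclose(back.X, lm_small.X)


class TestLikelihood:
    def test_standard_normal_point(self):
        data = ss.RegressionData(y=np.zeros(1), X=np.ones((1, 1)))
        assert ss.lm_log_obs(data, np.zeros(1), 1.0) == pytest.approx(
            -0.5 * np.log(2 * np.pi)
        )

    def test_zero_residuals(self):
        X = ss.simulate_design(7, 2, 1)
        beta = np.array([0.3, -0.1])
        data = ss.RegressionData(y=X @ beta, X=X)
        assert ss.lm_log_obs(data, beta, 1.0) == pytest.approx(-3.5 * np.log(2 * np.pi))

    def test_against_per_observation_product(self, lm_small, rng):
        beta = rng.uniform(-1, 1, size=3)
        eta2 = 0.7
        direct = sum(
            norm.logpdf(y_r, x_r @ beta, np.sqrt(eta2))
            for y_r, x_r in zip(lm_small.y, lm_small.X)
        )
        assert ss.lm_log_obs(lm_small, beta, eta2) == pytest.approx(direct, abs=1e-10)

    def test_invalid_variance_rejected(self, lm_small):
        with pytest.raises(ValueError):
            ss.lm_log_obs(lm_small, np.zeros(3), 0.0)


class TestInference:
    def test_prior_chain_samples_eta2_uniform(self, lm_small):
        # phi = 0 chain ignores the data: eta^2 marginal is its U(0.1, 2) prior
        _, extras = lm_evidence(lm_small, 2, K=6, n_burnin=1000, n_samples=40000, seed=3)
        eta2 = extras["prior_chain_eta2"][::40]  # thin to ~independent draws
        pval = kstest(eta2, "uniform", args=(0.1, 1.9)).pvalue
        assert pval > 0.01

    def test_kernel_and_generic_sampler_agree(self, lm_small):
        lad = make_ladder(10)
        est_k, _ = lm_evidence(
            lm_small, 3, n_burnin=1000, n_samples=15000, seed=3, ladder=lad
        )
        model = ss.lm_model_interface(lm_small, 3)
        trace = run_power_posteriors(model, lad, 800, 5000, seed=4)
        est_g = stepping_stone_log_evidence(trace, lad)
        tol = 4 * np.hypot(est_k.se, est_g.se)
        assert abs(est_k.log_evidence - est_g.log_evidence) < max(tol, 0.15)

    def test_evidence_matches_brute_force_prior_integration(self):
        # tiny instance: evidence by direct prior Monte Carlo integration
        X = ss.simulate_design(5, 2, 1)
        data = ss.simulate_lm(X, np.array([0.5, 0.5]), 1.0, 2)
        est, _ = lm_evidence(data, 2, K=12, n_burnin=1000, n_samples=10000, seed=3)
        rng = np.random.default_rng(0)
        n = 2_000_000
        beta = rng.uniform(-2, 2, size=(n, 2))
        eta2 = rng.uniform(0.1, 2, size=n)
        resid = data.y[None, :] - beta @ data.X.T
        ll = -0.5 * 5 * np.log(2 * np.pi * eta2) - np.einsum(
            "ij,ij->i", resid, resid
        ) / (2 * eta2)
        brute = logsumexp(ll) - np.log(n)
        assert abs(est.log_evidence - brute) < 0.1

    def test_parameter_recovery_on_benchmark_data(self):
        from steppingstone.benchmarks import lm_benchmark

        data = lm_benchmark()
        model = ss.lm_model_interface(data)
        lad = ss.TemperatureLadder(np.array([1.0, 0.0]))
        trace = run_power_posteriors(model, lad, 1000, 4000, seed=2, record_summaries=True)
        draws = trace.posterior_summaries
        means = draws.mean(axis=0)
        sds = draws.std(axis=0, ddof=1)
        truth = np.concatenate([ss.default_lm_truth(), [1.0]])
        assert np.all(np.abs(means - truth) < 5 * sds)

    def test_out_of_range_jsel_rejected(self, lm_small):
        with pytest.raises(ValueError):
            lm_evidence(lm_small, 7)
        with pytest.raises(ValueError):
            ss.lm_model_interface(lm_small, -1)


class TestScan:
    def test_scan_table_structure_and_argmin(self, lm_small):
        table = nested_model_scan(
            lm_small, "lm", jsels=range(4), K=6, n_burnin=500, n_samples=3000, seed=1
        )
        assert set(table.measure_name) == {"minus2_log_evidence", "DIC1", "DIC2"}
        assert sorted(table[table.measure_name == "DIC1"].J_sel) == [0, 1, 2, 3]
        j = scan_argmin(table)
        assert 0 <= j <= 3

    def test_empty_scan_rejected(self, lm_small):
        with pytest.raises(ValueError):
            nested_model_scan(lm_small, "lm", jsels=[])
        with pytest.raises(ValueError):
            nested_model_scan(lm_small, "gam")
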