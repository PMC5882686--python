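import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chisquare

import steppingstone as ss
from steppingstone.interface import ModelInterface, TemperedChainState
from steppingstone.ladder import TemperatureLadder
from steppingstone.tempering import (
    log_bayes_factor,
    run_power_posteriors,
    stepping_stone_log_evidence,
    swap_adjacent,
    tempered_log_accept,
)


def _state(log_obs, log_latent=0.0, log_prior=0.0, phi=1.0):
    return TemperedChainState(
        theta=None, x=None, log_obs=log_obs, log_latent=log_latent,
        log_prior=log_prior, phi=phi,
    )


class TestTemperedAcceptance:
    def test_prior_chain_ignores_data(self):
        cur = _state(log_obs=-100.0, phi=0.0)
        prop = _state(log_obs=-5.0, phi=0.0)
        assert tempered_log_accept(cur, prop) == 0.0

    def test_posterior_chain_is_metropolis_hastings(self):
        cur = _state(log_obs=-10.0, log_prior=-1.0, phi=1.0)
        prop = _state(log_obs=-12.0, log_prior=-0.5, phi=1.0)
        expected = min(0.0, (-12.0 - -10.0) + (-0.5 - -1.0))
        assert tempered_log_accept(cur, prop) == pytest.approx(expected)

    def test_identity_proposal_accepted(self):
        cur = _state(log_obs=-3.0, log_latent=-1.0, log_prior=-2.0, phi=0.7)
        assert tempered_log_accept(cur, cur) == 0.0

    def test_out_of_support_proposal_rejected_not_raised(self):
        cur = _state(log_obs=-3.0, phi=1.0)
        prop = _state(log_obs=-2.0, log_prior=-np.inf, phi=1.0)
        assert tempered_log_accept(cur, prop) == -np.inf

    def test_intermediate_temperature_scales_likelihood_term(self):
        cur = _state(log_obs=-10.0, phi=0.25)
        prop = _state(log_obs=-6.0, phi=0.25)
        assert tempered_log_accept(cur, prop) == 0.0  # improvement: accept
        back = tempered_log_accept(prop, cur)
        assert back == pytest.approx(0.25 * (-4.0))


class TestSwap:
    def test_equal_likelihoods_always_swap(self, rng):
        a, b = _state(-7.0, phi=0.8), _state(-7.0, phi=0.5)
        _, _, accepted = swap_adjacent(a, b, 0.8, 0.5, rng)
        assert accepted

    def test_equal_temperatures_always_swap(self, rng):
        a, b = _state(-3.0, phi=0.5), _state(-40.0, phi=0.5)
        _, _, accepted = swap_adjacent(a, b, 0.5, 0.5, rng)
        assert accepted

    def test_swap_probability_matches_exponent(self):
        # log_obs gap -2 at phi gap 0.5: acceptance probability e^-1
        rng = np.random.default_rng(11)
        n, hits = 4000, 0
        for _ in range(n):
            a, b = _state(-5.0, phi=1.0), _state(-7.0, phi=0.5)
            _, _, accepted = swap_adjacent(a, b, 1.0, 0.5, rng)
            hits += accepted
        p_hat = hits / n
        assert abs(p_hat - np.exp(-1)) < 3 * np.sqrt(0.368 * 0.632 / n)

    def test_swap_exchanges_states(self, rng):
        a, b = _state(-7.0, phi=0.8), _state(-7.0, phi=0.5)
        sa, sb, _ = swap_adjacent(a, b, 0.8, 0.5, rng)
        assert sa is b and sb is a
        assert sa.phi == 0.8 and sb.phi == 0.5


def _constant_model(log_c):
    class Walk:
        def propose(self, theta, x, rng):
            return theta + rng.standard_normal(), x, 0.0, 0.0

    return ModelInterface(
        log_prior=lambda theta: -0.5 * theta**2 - 0.5 * np.log(2 * np.pi),
        log_obs=lambda theta, x: log_c,
        parameter_kernels=[Walk()],
        init_state=lambda rng: (rng.standard_normal(), None),
    )


@given(
    K=st.integers(min_value=2, max_value=8),
    n=st.integers(min_value=1, max_value=30),
    seed=st.integers(min_value=0, max_value=2**20),
    log_c=st.floats(min_value=-800.0, max_value=50.0),
)
@settings(deadline=None, max_examples=15)
def test_constant_likelihood_evidence_is_exact(K, n, seed, log_c):
    """With P(y|theta,x) = c the telescoping product collapses to c itself."""
    lad = ss.make_ladder(K)
    trace = run_power_posteriors(_constant_model(log_c), lad, 0, n, seed=seed)
    assert np.all(trace.log_obs == log_c)
    est = stepping_stone_log_evidence(trace, lad)
    assert est.log_evidence == pytest.approx(log_c, abs=1e-9)
    assert est.se == pytest.approx(0.0, abs=1e-12)


def test_seed_determinism_bit_identical(lm_small):
    lad = ss.make_ladder(4)
    model = ss.lm_model_interface(lm_small, 2)
    t1 = run_power_posteriors(model, lad, 50, 200, seed=42)
    t2 = run_power_posteriors(model, lad, 50, 200, seed=42)
    t3 = run_power_posteriors(model, lad, 50, 200, seed=43)
    assert np.array_equal(t1.log_obs, t2.log_obs)
    assert not np.array_equal(t1.log_obs, t3.log_obs)
    e1 = stepping_stone_log_evidence(t1)
    e2 = stepping_stone_log_evidence(t2)
    assert e1.log_evidence == e2.log_evidence


class _DiscreteHop:
    """Uniform proposal among the other two states of a 3-state model."""

    def propose(self, theta, x, rng):
        return (theta + 1 + rng.integers(2)) % 3, x, 0.0, 0.0


def test_three_state_tempered_chain_matches_invariant_density():
    """Empirical chain occupancy converges to pi_i L_i^phi on every chain."""
    prior = np.array([0.5, 0.3, 0.2])
    lik = np.array([1.0, 2.0, 5.0])
    model = ModelInterface(
        log_prior=lambda theta: np.log(prior[theta]),
        log_obs=lambda theta, x: np.log(lik[theta]),
        parameter_kernels=[_DiscreteHop()],
        init_state=lambda rng: (int(rng.integers(3)), None),
    )
    lad = TemperatureLadder(np.array([1.0, 0.5, 0.0]))
    n = 100000
    trace = run_power_posteriors(model, lad, 500, n, seed=7)
    for k, phi in enumerate(lad.phis):
        target = prior * lik**phi
        target /= target.sum()
        counts = np.array(
            [np.sum(np.isclose(trace.log_obs[k], np.log(L))) for L in lik]
        )
        assert counts.sum() == n
        stat, pval = chisquare(counts, n * target)
        assert pval > 0.01, f"chain {k + 1}: occupancy {counts / n} vs {target}"
    # evidence against the exact finite sum
    est = stepping_stone_log_evidence(trace, lad)
    exact = np.log(np.dot(prior, lik))
    assert abs(est.log_evidence - exact) < 4 * est.se


def test_two_chain_estimator_is_prior_arithmetic_mean():
    """K=2 reduces to the log of the prior-sample mean of the likelihood."""
    prior = np.array([0.5, 0.3, 0.2])
    lik = np.array([1.0, 2.0, 5.0])
    model = ModelInterface(
        log_prior=lambda theta: np.log(prior[theta]),
        log_obs=lambda theta, x: np.log(lik[theta]),
        parameter_kernels=[_DiscreteHop()],
        init_state=lambda rng: (int(rng.integers(3)), None),
    )
    lad = TemperatureLadder(np.array([1.0, 0.0]))
    trace = run_power_posteriors(model, lad, 200, 20000, seed=3)
    est = stepping_stone_log_evidence(trace, lad)
    by_hand = np.log(np.mean(np.exp(trace.log_obs[1])))
    assert est.log_evidence == pytest.approx(by_hand)


def test_evidence_error_shrinks_with_sample_size():
    """On the Gaussian-surface scenario the SS error decays like 1/sqrt(N)."""
    spec = ss.mvn_scenario(d=2, lam=1.0, seed=9)
    exact = ss.analytic_minus2_log_evidence(spec)
    ses = []
    for n in (1000, 10000, 100000):
        est, _ = ss.mvn_evidence(spec, K=10, n_burnin=500, n_samples=n, seed=5)
        ses.append(est.se)
        assert abs(est.minus_two_log_evidence - exact) < 5 * (2 * est.se)
    assert ses[0] / ses[1] == pytest.approx(np.sqrt(10), rel=0.5)
    assert ses[1] / ses[2] == pytest.approx(np.sqrt(10), rel=0.5)


def test_log_bayes_factor_identities():
    e1 = ss.EvidenceEstimate(log_evidence=-4.0, se=0.1, K=2, N=10)
    e2 = ss.EvidenceEstimate(log_evidence=-6.3, se=0.1, K=2, N=10)
    assert log_bayes_factor(e1, e1) == 0.0
    assert log_bayes_factor(e1, e2) == pytest.approx(2.3)
    assert log_bayes_factor(e1, e2) == -log_bayes_factor(e2, e1)
    assert e1.minus_two_log_evidence == pytest.approx(8.0)


def test_trace_csv_round_trip(tmp_path, lm_small):
    lad = ss.make_ladder(3)
    model = ss.lm_model_interface(lm_small, 1)
    trace = run_power_posteriors(model, lad, 20, 50, seed=1)
    path = tmp_path / "trace.csv"
    trace.to_csv(path)
    back = ss.ChainTrace.from_csv(path)
    assert np.allclose(back.phis, trace.phis)
    assert np.allclose(back.log_obs, trace.log_obs)
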