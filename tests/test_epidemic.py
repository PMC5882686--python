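import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import kstest

import steppingstone as ss
from steppingstone.epidemic import (
    CompartmentalSpec,
    EventSequence,
    TestPanel as Panel,
    epi_evidence,
    epi_model_interface,
    four_model_tournament,
    tournament_argmins,
    tournament_truth,
)
from steppingstone.ladder import TemperatureLadder, make_ladder
from steppingstone.tempering import run_power_posteriors, stepping_stone_log_evidence


class TestSpecValidation:
    def test_rates_required_per_model(self):
        with pytest.raises(ValueError):
            CompartmentalSpec("SEI", beta=0.01)  # nu missing
        with pytest.raises(ValueError):
            CompartmentalSpec("SIR", beta=0.01)  # gamma missing
        with pytest.raises(ValueError):
            CompartmentalSpec("XYZ", beta=0.01)
        with pytest.raises(ValueError):
            CompartmentalSpec("SI", beta=-1.0)

    def test_benchmark_truths_match_stated_rates(self):
        t = tournament_truth()
        assert t["SI"].beta == 0.002
        assert (t["SEI"].beta, t["SEI"].nu) == (0.003, 0.1)
        assert (t["SIR"].beta, t["SIR"].gamma) == (0.004, 0.05)
        assert (t["SEIR"].beta, t["SEIR"].nu, t["SEIR"].gamma) == (0.004, 0.1, 0.05)
        assert all(s.p == 50 for s in t.values())


class TestGillespie:
    def test_si_runs_to_absorption(self):
        spec = CompartmentalSpec("SI", beta=0.002, p=50, T=1e7)
        ev = ss.gillespie_simulate(spec, 1)
        assert int((ev.types == 0).sum()) == 49  # everyone ends infected
        assert ev.n_events == 49

    def test_mean_time_to_first_event(self):
        # initial total rate 49 * beta * 1: mean waiting time 1/(49*0.002) = 10.2
        spec = CompartmentalSpec("SI", beta=0.002, p=50, T=1e6)
        rng = np.random.default_rng(0)
        first = [ss.gillespie_simulate(spec, rng).times[0] for _ in range(2000)]
        expected = 1.0 / (49 * 0.002)
        assert np.mean(first) == pytest.approx(expected, abs=3 * expected / np.sqrt(2000))

    def test_seir_compartment_conservation(self):
        spec = CompartmentalSpec("SEIR", beta=0.004, nu=0.1, gamma=0.05, p=50, T=100)
        ev = ss.gillespie_simulate(spec, 2)
        for t in np.linspace(0, 100, 23):
            S, E, I, R = ev.counts_at(t)
            assert S + E + I + R == 50
            assert min(S, E, I, R) >= 0

    def test_seed_determinism(self):
        spec = CompartmentalSpec("SEIR", beta=0.004, nu=0.1, gamma=0.05)
        a = ss.gillespie_simulate(spec, 9)
        b = ss.gillespie_simulate(spec, 9)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.individuals, b.individuals)


class TestLatentLikelihood:
    def test_single_exposure_hand_calculation(self):
        # p=2, one exposure at t=3: log(beta * 1) - beta*3; afterwards S=0 so W=0
        spec = CompartmentalSpec("SI", beta=0.002, p=2, T=10.0)
        ev = EventSequence(np.array([3.0]), np.array([0]), np.array([1]), p=2, T=10.0)
        assert ss.epi_log_latent(ev, spec) == pytest.approx(np.log(0.002) - 0.002 * 3)

    def test_no_event_tail_term(self):
        spec = CompartmentalSpec("SI", beta=0.01, p=3, T=20.0)
        empty = EventSequence(np.empty(0), np.empty(0), np.empty(0), p=3, T=20.0)
        # two susceptibles at risk over the whole horizon
        assert ss.epi_log_latent(empty, spec) == pytest.approx(-2 * 0.01 * 20.0)

    def test_inconsistent_sequences_rejected_with_event_index(self):
        spec = CompartmentalSpec("SIR", beta=0.01, gamma=0.1, p=3, T=20.0)
        bad = EventSequence(np.array([5.0]), np.array([2]), np.array([2]), p=3, T=20.0)
        with pytest.raises(ValueError, match="event 0"):
            ss.epi_log_latent(bad, spec)
        bad2 = EventSequence(
            np.array([2.0, 4.0]), np.array([0, 1]), np.array([1, 1]), p=3, T=20.0
        )
        with pytest.raises(ValueError, match="event 1"):
            ss.epi_log_latent(bad2, CompartmentalSpec("SI", beta=0.01, p=3, T=20.0))

    def test_simulator_and_likelihood_are_consistent(self):
        """Empirical first-exposure times match exp(log latent density)."""
        beta, T = 0.05, 30.0
        spec = CompartmentalSpec("SI", beta=beta, p=2, T=T)
        rng = np.random.default_rng(4)
        times = []
        none = 0
        n = 40000
        for _ in range(n):
            ev = ss.gillespie_simulate(spec, rng)
            if ev.n_events:
                times.append(ev.times[0])
            else:
                none += 1
        # no-event probability: exp of the empty-sequence latent likelihood
        empty = EventSequence(np.empty(0), np.empty(0), np.empty(0), p=2, T=T)
        p_none = np.exp(ss.epi_log_latent(empty, spec))
        assert none / n == pytest.approx(p_none, abs=3 * np.sqrt(p_none / n))
        # binned density of the single event time vs the likelihood
        edges = np.linspace(0, T, 7)
        hist, _ = np.histogram(times, bins=edges)
        for b in range(6):
            mid = 0.5 * (edges[b] + edges[b + 1])
            ev_mid = EventSequence(
                np.array([mid]), np.array([0]), np.array([1]), p=2, T=T
            )
            p_bin = np.exp(ss.epi_log_latent(ev_mid, spec)) * (edges[1] - edges[0])
            assert hist[b] / n == pytest.approx(p_bin, abs=4 * np.sqrt(p_bin / n) + 1e-3)

    def test_simulated_paths_have_finite_reproducible_likelihood(self):
        spec = CompartmentalSpec("SEIR", beta=0.004, nu=0.1, gamma=0.05)
        ev = ss.gillespie_simulate(spec, 5)
        ll = ss.epi_log_latent(ev, spec)
        assert np.isfinite(ll)
        assert ss.epi_log_latent(ev, spec) == ll


class TestObservationModel:
    def test_perfect_tests_reflect_true_status(self):
        spec = CompartmentalSpec("SEIR", beta=0.004, nu=0.1, gamma=0.05)
        ev = ss.gillespie_simulate(spec, 3)
        sched = np.array([20.0, 60.0])
        panel = ss.simulate_tests(ev, sched, Se=1.0, Sp=1.0, seed=1)
        win = ev.infected_windows()
        truth = (win[:, 0:1] <= sched[None, :]) & (sched[None, :] < win[:, 1:2])
        assert np.array_equal(panel.results.astype(bool), truth)
        # concordant perfect panel has probability one
        assert ss.epi_log_obs(panel, ev) == 0.0

    def test_false_positive_rate_in_naive_population(self):
        empty = EventSequence(np.empty(0), np.empty(0), np.empty(0), p=400, T=50.0)
        sched = np.array([10.0, 20.0, 30.0])
        rng = np.random.default_rng(8)
        fracs = [
            ss.simulate_tests(empty, sched, 0.8, 0.95, rng).results[1:].mean()
            for _ in range(30)
        ]
        assert np.mean(fracs) == pytest.approx(0.05, abs=0.005)

    def test_recovered_individuals_test_as_uninfected(self):
        # individual 1 infected at 2, recovered at 5; tested at 10
        ev = EventSequence(
            np.array([2.0, 5.0]), np.array([0, 2]), np.array([1, 1]), p=2, T=20.0
        )
        panel = ss.simulate_tests(ev, np.array([10.0]), Se=1.0, Sp=1.0, seed=0)
        assert panel.results[1, 0] == 0

    def test_log_obs_direct_count_example(self):
        # 2 true-positives, 1 false-negative, 3 true-negatives, 0 false-positives:
        # the index case (infected throughout) tests +,+,-; the remaining
        # susceptible tests -,-,-
        ev = EventSequence(np.empty(0), np.empty(0), np.empty(0), p=2, T=40.0)
        sched = np.array([5.0, 15.0, 25.0])
        results = np.zeros((2, 3), dtype=np.int8)
        results[0] = [1, 1, 0]
        panel = Panel(sched, results, Se=0.8, Sp=0.95, p=2, T=40.0)
        expected = 2 * np.log(0.8) + 1 * np.log(0.2) + 3 * np.log(0.95)
        assert ss.epi_log_obs(panel, ev) == pytest.approx(expected)

    def test_empty_panel_is_certain(self):
        ev = EventSequence(np.empty(0), np.empty(0), np.empty(0), p=3, T=10.0)
        panel = Panel(np.empty(0), np.zeros((3, 0), dtype=np.int8), 0.8, 0.95, 3, 10.0)
        assert ss.epi_log_obs(panel, ev) == 0.0

    def test_contradiction_under_perfect_test_is_minus_inf(self):
        ev = EventSequence(np.empty(0), np.empty(0), np.empty(0), p=2, T=10.0)
        results = np.zeros((2, 1), dtype=np.int8)
        results[1, 0] = 1  # positive while provably susceptible
        panel = Panel(np.array([5.0]), results, Se=1.0, Sp=1.0, p=2, T=10.0)
        assert ss.epi_log_obs(panel, ev) == -np.inf

    def test_panel_csv_round_trip(self, tmp_path, si_small_panel):
        _, _, panel = si_small_panel
        path = tmp_path / "panel.csv"
        panel.to_csv(path)
        back = Panel.from_csv(path)
        assert np.array_equal(back.results, panel.results)
        assert np.allclose(back.times, panel.times)
        assert back.Se == panel.Se

    def test_event_csv_round_trip(self, tmp_path):
        spec = CompartmentalSpec("SEIR", beta=0.004, nu=0.1, gamma=0.05)
        ev = ss.gillespie_simulate(spec, 3)
        path = tmp_path / "events.csv"
        ev.to_csv(path)
        back = EventSequence.from_csv(path, p=spec.p, T=spec.T)
        assert np.allclose(back.times, ev.times)
        assert np.array_equal(back.types, ev.types)


class TestAugmentationInference:
    def test_evidence_matches_brute_force_forward_simulation(self, si_small_panel):
        spec, _, panel = si_small_panel
        est, _ = epi_evidence(
            "SI", panel, n_burnin=1000, n_samples=15000, seed=9, ladder=make_ladder(8)
        )
        rng = np.random.default_rng(0)
        n = 120000
        lls = np.empty(n)
        for i in range(n):
            b = rng.uniform(1e-5, 0.1)
            e = ss.gillespie_simulate(
                CompartmentalSpec("SI", beta=b, p=spec.p, T=spec.T), rng
            )
            lls[i] = ss.epi_log_obs(panel, e)
        brute = logsumexp(lls) - np.log(n)
        assert abs(est.log_evidence - brute) < 0.15

    def test_kernel_and_generic_sampler_agree(self, si_small_panel):
        _, _, panel = si_small_panel
        lad = make_ladder(6)
        est_k, _ = epi_evidence(
            "SI", panel, n_burnin=1000, n_samples=15000, seed=11, ladder=lad
        )
        model = epi_model_interface("SI", panel)
        trace = run_power_posteriors(model, lad, 800, 5000, seed=12)
        est_g = stepping_stone_log_evidence(trace, lad)
        tol = 4 * np.hypot(est_k.se, est_g.se)
        assert abs(est_k.log_evidence - est_g.log_evidence) < max(tol, 0.2)

    def test_prior_chain_recovers_rate_prior(self):
        # phi=0 chain: the joint (theta, x) prior has U(1e-5, 0.1) beta marginal
        panel = Panel(
            np.array([50.0]), np.zeros((2, 1), dtype=np.int8), 0.8, 0.95, 2, 100.0
        )
        lad = TemperatureLadder(np.array([1.0, 0.0]))
        _, extras = epi_evidence(
            "SI", panel, n_burnin=500, n_samples=40000, seed=4, ladder=lad
        )
        beta = extras["prior_chain_rates"][::50, 0]
        assert kstest(beta, "uniform", args=(1e-5, 0.1 - 1e-5)).pvalue > 0.01

    def test_parameter_recovery_si(self):
        spec = tournament_truth()["SI"]
        ev = ss.gillespie_simulate(spec, 1)
        panel = ss.simulate_tests(ev, ss.default_schedule(), 0.8, 0.95, 101)
        _, extras = epi_evidence(
            "SI", panel, K=10, n_burnin=1000, n_samples=5000, seed=5
        )
        beta_hat = extras["posterior_mean_rates"]["beta"]
        assert 0.001 < beta_hat < 0.004  # truth 0.002

    def test_panel_binary_and_individual_validation(self, si_small_panel):
        _, _, panel = si_small_panel
        with pytest.raises(ValueError):
            epi_evidence("SXR", panel)
        bad = Panel(
            panel.times, np.abs(panel.results), panel.Se, panel.Sp, panel.p, panel.T
        )
        bad.results = bad.results.copy()
        bad.results[0, 0] = 2
        with pytest.raises(ValueError):
            epi_model_interface("SI", bad)

    def test_tournament_smoke_structure(self, si_small_panel):
        _, _, panel = si_small_panel
        table = four_model_tournament(
            {"SI": panel}, K=3, n_burnin=200, n_samples=400, seed=1
        )
        assert set(table.candidate) == {"SI", "SEI", "SIR", "SEIR"}
        assert set(table.measure_name) == {
            "minus2_log_evidence", "DIC3", "DIC4", "DIC5", "DIC6",
        }
        winners = tournament_argmins(table)
        assert set(winners) == {"SI"}
        assert winners["SI"] in {"SI", "SEI", "SIR", "SEIR"}
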