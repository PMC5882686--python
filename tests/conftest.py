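import numpy as np
import pytest

import steppingstone as ss


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240817)


@pytest.fixture(scope="session")
def small_ladder():
    return ss.make_ladder(6)


@pytest.fixture(scope="session")
def lm_small():
    """Small regression dataset (R=12, J'=3) with two active regressors."""
    X = ss.simulate_design(12, 3, 1)
    return ss.simulate_lm(X, np.array([0.5, 0.5, 0.0]), 1.0, 2)


@pytest.fixture(scope="session")
def mixed_small():
    """Small pedigree mixed-model dataset (16 individuals, 2 generations)."""
    ped = ss.simulate_pedigree(8, 2, 5)
    A = ss.relationship_matrix(ped)
    X = ss.simulate_design(ped.n, 3, 6)
    data, u = ss.simulate_mixed(A, X, np.array([0.5, 0.5, 0.0]), 0.5, 0.5, 7)
    return data, A, u


@pytest.fixture(scope="session")
def si_small_panel():
    """Tiny SI epidemic (p=4) with a 3-time test panel."""
    spec = ss.CompartmentalSpec("SI", beta=0.02, p=4, T=20.0)
    events = ss.gillespie_simulate(spec, 3)
    panel = ss.simulate_tests(events, np.array([5.0, 10.0, 15.0]), 0.8, 0.95, 7)
    return spec, events, panel
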