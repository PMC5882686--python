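"""Individual-based SI/SEI/SIR/SEIR models with imperfect diagnostic testing.

Forward simulation uses the Doob–Gillespie algorithm.  Transitions are per
capita: a susceptible becomes infected at rate beta*I, an exposed individual
becomes infectious at rate nu, an infectious one recovers at rate gamma.  The
latent state x is the ordered sequence of transition events; the data y are
periodic whole-population diagnostic tests with sensitivity Se (an individual
in E or I tests positive with probability Se) and specificity Sp.

Inference augments the unobserved event sequence: the posterior over (rates,
events) is explored by Metropolis–Hastings moves that shift event times and
reversibly add/remove per-individual transitions.  A numba kernel
(:mod:`steppingstone._kernels`) runs the tempered ladder at benchmark scale;
the pure-Python ModelInterface here mirrors it move for move and serves as
its small-scale cross-check.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import dic as dic_mod
from ._kernels import epi_ss_kernel
from .interface import ModelInterface
from .ladder import TemperatureLadder, make_ladder
from .tempering import ChainTrace, EvidenceEstimate, stepping_stone_log_evidence

__all__ = [
    "CompartmentalSpec",
    "EventSequence",
    "TestPanel",
    "EPI_PRIORS",
    "gillespie_simulate",
    "epi_log_latent",
    "epi_log_obs",
    "simulate_tests",
    "default_schedule",
    "epi_model_interface",
    "epi_evidence",
    "four_model_tournament",
    "tournament_truth",
]

MODEL_TYPES = ("SI", "SEI", "SIR", "SEIR")
_TYPE_NAMES = {0: "exposure", 1: "infection", 2: "recovery"}
_TYPE_CODES = {v: k for k, v in _TYPE_NAMES.items()}

#: default uniform prior bounds on the rates: proper and diffuse relative to
#: the benchmark truths (all of which lie well inside)
EPI_PRIORS = {"beta": (1e-5, 0.1), "nu": (1e-3, 1.0), "gamma": (1e-3, 1.0)}


@dataclass(frozen=True)
class CompartmentalSpec:
    """Model family, rates, population size and time horizon."""

    model_type: str
    beta: float
    nu: float | None = None
    gamma: float | None = None
    p: int = 50
    T: float = 100.0

    def __post_init__(self) -> None:
        if self.model_type not in MODEL_TYPES:
            raise ValueError(f"model_type must be one of {MODEL_TYPES}")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.has_E and (self.nu is None or self.nu <= 0):
            raise ValueError(f"{self.model_type} needs nu > 0")
        if self.has_R and (self.gamma is None or self.gamma <= 0):
            raise ValueError(f"{self.model_type} needs gamma > 0")

    @property
    def has_E(self) -> bool:
        return "E" in self.model_type

    @property
    def has_R(self) -> bool:
        return self.model_type.endswith("R")


@dataclass
class EventSequence:
    """Ordered epidemic events (time, type, individual) on (0, T).

    Types: "exposure" (leaving S), "infection" (E -> I onset) and "recovery".
    Individual 0 is the index case, infectious from t = 0.  The compartment of
    any individual at any time is recovered by replaying the sequence.
    """

    times: np.ndarray
    types: np.ndarray  # int codes 0/1/2
    individuals: np.ndarray
    p: int
    T: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.types = np.asarray(self.types, dtype=np.int8)
        self.individuals = np.asarray(self.individuals, dtype=np.int64)
        if np.any(np.diff(self.times) < 0):
            raise ValueError("event times must be nondecreasing")

    @property
    def n_events(self) -> int:
        return int(self.times.size)

    def type_names(self) -> list[str]:
        return [_TYPE_NAMES[int(t)] for t in self.types]

    def counts_at(self, t: float, has_E: bool = True) -> tuple[int, int, int, int]:
        """(S, E, I, R) immediately after replaying events up to time t.

        ``has_E`` tells the replay whether type-0 events enter the exposed
        class or (for SI/SIR models) go straight to infectious.
        """
        S, E, I, R = self.p - 1, 0, 1, 0
        for te, ty in zip(self.times, self.types):
            if te > t:
                break
            if ty == 0:
                S -= 1
                if has_E:
                    E += 1
                else:
                    I += 1
            elif ty == 1:
                E -= 1
                I += 1
            else:
                I -= 1
                R += 1
        return S, E, I, R

    def infected_windows(self) -> np.ndarray:
        """Per individual: [t_enter_infected, t_recover] (inf where absent)."""
        enter = np.full(self.p, np.inf)
        leave = np.full(self.p, np.inf)
        enter[0] = 0.0
        for te, ty, j in zip(self.times, self.types, self.individuals):
            if ty == 0:
                enter[j] = te
            elif ty == 2:
                leave[j] = te
        return np.column_stack([enter, leave])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "time": self.times,
                "type": self.type_names(),
                "individual": self.individuals,
            }
        ).to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path, p: int, T: float) -> "EventSequence":
        df = pd.read_csv(path)
        return cls(
            times=df["time"].to_numpy(float),
            types=np.array([_TYPE_CODES[t] for t in df["type"]]),
            individuals=df["individual"].to_numpy(),
            p=p,
            T=T,
        )


@dataclass
class TestPanel:
    """Whole-population diagnostic test results on a fixed schedule."""

    times: np.ndarray
    results: np.ndarray  # (p, n_times), 1 = positive
    Se: float
    Sp: float
    p: int
    T: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.results = np.asarray(self.results, dtype=np.int8)
        if self.results.shape != (self.p, self.times.size):
            raise ValueError("results must have shape (p, n_times)")
        if not (0.0 < self.Se <= 1.0 and 0.0 < self.Sp <= 1.0):
            raise ValueError("Se and Sp must lie in (0, 1]")

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        nt = self.times.size
        pd.DataFrame(
            {
                "individual": np.repeat(np.arange(self.p), nt),
                "time": np.tile(self.times, self.p),
                "result": self.results.ravel(),
            }
        ).to_csv(path, index=False, float_format="%.17g")
        sidecar = path.with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {
                    "Se": self.Se,
                    "Sp": self.Sp,
                    "schedule": list(map(float, self.times)),
                    "p": self.p,
                    "T": self.T,
                }
            )
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "TestPanel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        df = pd.read_csv(path)
        times = np.array(meta["schedule"], dtype=float)
        p = int(meta["p"])
        results = np.zeros((p, times.size), dtype=np.int8)
        tidx = {t: m for m, t in enumerate(times)}
        for _, row in df.iterrows():
            results[int(row["individual"]), tidx[float(row["time"])]] = int(row["result"])
        return cls(times=times, results=results, Se=meta["Se"], Sp=meta["Sp"], p=p, T=meta["T"])


def default_schedule(T: float = 100.0, n_panels: int = 24) -> np.ndarray:
    """Equally spaced whole-population test times over (0, T].

    The default of 24 panels keeps the observation design dense enough that
    the four compartmental models are mutually identifiable from one epidemic;
    sparser schedules leave infection windows so loosely pinned that nested
    pairs (notably SI inside SEI) become statistically indistinguishable.
    """
    return T * np.arange(1, n_panels + 1) / n_panels


def gillespie_simulate(spec: CompartmentalSpec, seed: int | np.random.Generator = 0) -> EventSequence:
    """Exact stochastic simulation of the epidemic up to the horizon T.

    Waiting times are exponential in the total event rate W; the event type is
    categorical in the compartment-total rates and the individual uniform
    within the chosen compartment.  Stops at T or when W = 0.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    sus = list(range(1, spec.p))
    exposed: list[int] = []
    infectious = [0]
    times: list[float] = []
    types: list[int] = []
    inds: list[int] = []
    t = 0.0
    nu = spec.nu or 0.0
    gamma = spec.gamma or 0.0
    while True:
        r_exp = spec.beta * len(infectious) * len(sus)
        r_inf = nu * len(exposed) if spec.has_E else 0.0
        r_rec = gamma * len(infectious) if spec.has_R else 0.0
        W = r_exp + r_inf + r_rec
        if W <= 0.0:
            break
        t += rng.exponential(1.0 / W)
        if t >= spec.T:
            break
        u = rng.random() * W
        if u < r_exp:
            j = sus.pop(int(rng.integers(len(sus))))
            if spec.has_E:
                exposed.append(j)
            else:
                infectious.append(j)
            times.append(t)
            types.append(0)
            inds.append(j)
        elif u < r_exp + r_inf:
            j = exposed.pop(int(rng.integers(len(exposed))))
            infectious.append(j)
            times.append(t)
            types.append(1)
            inds.append(j)
        else:
            j = infectious.pop(int(rng.integers(len(infectious))))
            times.append(t)
            types.append(2)
            inds.append(j)
    return EventSequence(
        times=np.array(times),
        types=np.array(types, dtype=np.int8),
        individuals=np.array(inds),
        p=spec.p,
        T=spec.T,
    )


def epi_log_latent(events: EventSequence, spec: CompartmentalSpec) -> float:
    """log pi(x|theta): sum of log event rates minus the survival integral.

    Each event e contributes log rho_{xi_e} - W (t_e - t_{e-1}) with rates
    evaluated in the state immediately before the event, plus a final no-event
    term -W (T - t_E).  Inconsistent sequences raise with the event index.
    """
    S, E, I = spec.p - 1, 0, 1
    status = np.zeros(spec.p, dtype=np.int8)  # 0 S, 1 E, 2 I, 3 R
    status[0] = 2
    nu = spec.nu or 0.0
    gamma = spec.gamma or 0.0
    ll = 0.0
    tprev = 0.0
    for e in range(events.n_events):
        t = float(events.times[e])
        ty = int(events.types[e])
        j = int(events.individuals[e])
        if not 0.0 < t < spec.T:
            raise ValueError(f"event {e}: time {t} outside (0, T)")
        W = spec.beta * I * S + (nu * E if spec.has_E else 0.0) + (
            gamma * I if spec.has_R else 0.0
        )
        ll -= W * (t - tprev)
        if ty == 0:
            if status[j] != 0:
                raise ValueError(f"event {e}: exposure of non-susceptible individual {j}")
            rate = spec.beta * I
            S -= 1
            if spec.has_E:
                E += 1
                status[j] = 1
            else:
                I += 1
                status[j] = 2
        elif ty == 1:
            if not spec.has_E or status[j] != 1:
                raise ValueError(f"event {e}: infection onset of non-exposed individual {j}")
            rate = nu
            E -= 1
            I += 1
            status[j] = 2
        else:
            if not spec.has_R or status[j] != 2:
                raise ValueError(f"event {e}: recovery of non-infectious individual {j}")
            rate = gamma
            I -= 1
            status[j] = 3
        if rate <= 0.0:
            return -np.inf
        ll += np.log(rate)
        tprev = t
    W = spec.beta * I * S + (nu * E if spec.has_E else 0.0) + (
        gamma * I if spec.has_R else 0.0
    )
    ll -= W * (spec.T - tprev)
    return float(ll)


def simulate_tests(
    events: EventSequence,
    schedule: np.ndarray,
    Se: float = 0.8,
    Sp: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> TestPanel:
    """Imperfect diagnostic tests of every individual at each scheduled time.

    Truly infected means in compartment E or I at the test time; such
    individuals test positive with probability Se, all others (S or R) test
    positive with probability 1 - Sp.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    schedule = np.asarray(schedule, dtype=float)
    win = events.infected_windows()
    infected = (win[:, 0:1] <= schedule[None, :]) & (schedule[None, :] < win[:, 1:2])
    prob_pos = np.where(infected, Se, 1.0 - Sp)
    results = (rng.random(prob_pos.shape) < prob_pos).astype(np.int8)
    return TestPanel(times=schedule, results=results, Se=Se, Sp=Sp, p=events.p, T=events.T)


def epi_log_obs(panel: TestPanel, events: EventSequence) -> float:
    """log P(y|theta,x) = N++ log Se + N-+ log(1-Se) + N-- log Sp + N+- log(1-Sp)."""
    win = events.infected_windows()
    infected = (win[:, 0:1] <= panel.times[None, :]) & (panel.times[None, :] < win[:, 1:2])
    pos = panel.results == 1
    n_pp = int(np.sum(pos & infected))
    n_mp = int(np.sum(~pos & infected))
    n_mm = int(np.sum(~pos & ~infected))
    n_pm = int(np.sum(pos & ~infected))
    ll = 0.0
    for n, prob in ((n_pp, panel.Se), (n_mp, 1.0 - panel.Se), (n_mm, panel.Sp), (n_pm, 1.0 - panel.Sp)):
        if n:
            if prob <= 0.0:
                return -np.inf
            ll += n * np.log(prob)
    return float(ll)


def tournament_truth() -> dict[str, CompartmentalSpec]:
    """The four benchmark generating models (p=50, one index case, T=100)."""
    return {
        "SI": CompartmentalSpec("SI", beta=0.002),
        "SEI": CompartmentalSpec("SEI", beta=0.003, nu=0.1),
        "SIR": CompartmentalSpec("SIR", beta=0.004, gamma=0.05),
        "SEIR": CompartmentalSpec("SEIR", beta=0.004, nu=0.1, gamma=0.05),
    }


# ---------------------------------------------------------------------------
# pure-Python data-augmentation interface (small-scale reference)
# ---------------------------------------------------------------------------


def _triples_to_events(tE, tI, tR, p, T, has_E) -> EventSequence:
    times, types, inds = [], [], []
    for j in range(p):
        if j != 0 and np.isfinite(tE[j]):
            times.append(tE[j])
            types.append(0)
            inds.append(j)
        if has_E and j != 0 and np.isfinite(tI[j]):
            times.append(tI[j])
            types.append(1)
            inds.append(j)
        if np.isfinite(tR[j]):
            times.append(tR[j])
            types.append(2)
            inds.append(j)
    order = np.argsort(times) if times else []
    return EventSequence(
        times=np.array(times)[order] if len(times) else np.empty(0),
        types=np.array(types, dtype=np.int8)[order] if len(times) else np.empty(0, np.int8),
        individuals=np.array(inds)[order] if len(times) else np.empty(0, np.int64),
        p=p,
        T=T,
    )


class _EpiLatentState:
    """Latent state as per-individual (tE, tI, tR) triples; +inf = absent."""

    __slots__ = ("tE", "tI", "tR")

    def __init__(self, tE, tI, tR):
        self.tE, self.tI, self.tR = tE, tI, tR

    def copy(self):
        return _EpiLatentState(self.tE.copy(), self.tI.copy(), self.tR.copy())


class _EpiMove:
    """One latent MH move (shift or add/remove toggle) for one individual."""

    def __init__(self, j, kind, has_E, has_R, T, shift_scale):
        self.j, self.kind = j, kind
        self.has_E, self.has_R, self.T = has_E, has_R, T
        self.shift_scale = shift_scale

    def propose(self, theta, x, rng):
        j, T, has_E, has_R = self.j, self.T, self.has_E, self.has_R
        xp = x.copy()
        tE, tI, tR = xp.tE, xp.tI, xp.tR
        ej, ij, rj = tE[j], tI[j], tR[j]
        logq = 0.0
        if self.kind == "shift":
            movable = []
            if j != 0 and np.isfinite(ej):
                movable.append("E")
            if j != 0 and has_E and np.isfinite(ij):
                movable.append("I")
            if has_R and np.isfinite(rj):
                movable.append("R")
            if not movable:
                return theta, x, 0.0, 0.0
            which = movable[rng.integers(len(movable))]
            dt = self.shift_scale * rng.standard_normal()
            if which == "E":
                upper = min(T, ij) if has_E else min(T, rj)
                tnew = ej + dt
                if not 0.0 < tnew < upper:
                    return theta, x, 0.0, -np.inf  # certain rejection
                tE[j] = tnew
                if not has_E:
                    tI[j] = tnew
            elif which == "I":
                tnew = ij + dt
                if not ej < tnew < min(T, rj):
                    return theta, x, 0.0, -np.inf
                tI[j] = tnew
            else:
                tstart = 0.0 if j == 0 else (ij if has_E else ej)
                tnew = rj + dt
                if not tstart < tnew < T:
                    return theta, x, 0.0, -np.inf
                tR[j] = tnew
        elif self.kind == "toggleE":
            if j == 0:
                return theta, x, 0.0, 0.0
            if not np.isfinite(ej):
                tnew = rng.uniform(0.0, T)
                tE[j] = tnew
                tI[j] = np.inf if has_E else tnew
                logq = np.log(T)
            else:
                removable = (not np.isfinite(ij)) if has_E else (not np.isfinite(rj))
                if not removable:
                    return theta, x, 0.0, 0.0
                tE[j] = tI[j] = tR[j] = np.inf
                logq = -np.log(T)
        elif self.kind == "toggleI":
            if j == 0 or not has_E:
                return theta, x, 0.0, 0.0
            if np.isfinite(ej) and not np.isfinite(ij):
                tI[j] = rng.uniform(ej, T)
                logq = np.log(T - ej)
            elif np.isfinite(ij) and not np.isfinite(rj):
                tI[j] = np.inf
                logq = -np.log(T - ej)
            else:
                return theta, x, 0.0, 0.0
        else:  # toggleR
            tstart = 0.0 if j == 0 else (tI[j] if has_E else tE[j])
            if np.isfinite(tstart) and not np.isfinite(rj):
                if tstart >= T:
                    return theta, x, 0.0, 0.0
                tR[j] = rng.uniform(tstart, T)
                logq = np.log(T - tstart)
            elif np.isfinite(rj):
                tR[j] = np.inf
                logq = -np.log(T - tstart)
            else:
                return theta, x, 0.0, 0.0
        # encode Hastings correction as backward - forward = logq
        return theta, xp, 0.0, logq


class _RateWalk:
    def __init__(self, index, scale):
        self.index, self.scale = index, scale

    def propose(self, theta, x, rng):
        theta = np.array(theta)
        v = theta[self.index]
        vp = v * np.exp(self.scale * rng.standard_normal())
        theta[self.index] = vp
        return theta, x, -np.log(vp), -np.log(v)


def epi_model_interface(
    model_type: str,
    panel: TestPanel,
    priors: dict | None = None,
    shift_scale: float | None = None,
) -> ModelInterface:
    """Pure-Python ModelInterface for data-augmentation inference.

    theta = (beta, nu, gamma) (absent rates carried but unused); x holds the
    per-individual event-time triples.  Latent kernels: per individual, a
    time-shift move and reversible add/remove toggles for its exposure, onset
    and recovery.  Intended for small populations; benchmark-scale runs go
    through the numba kernel (see :func:`epi_evidence`).
    """
    if model_type not in MODEL_TYPES:
        raise ValueError(f"unknown model type {model_type!r}")
    priors = {**EPI_PRIORS, **(priors or {})}
    p, T = panel.p, panel.T
    if np.any((panel.results != 0) & (panel.results != 1)):
        raise ValueError("panel results must be binary")
    has_E = "E" in model_type
    has_R = model_type.endswith("R")
    b_lo, b_hi = priors["beta"]
    n_lo, n_hi = priors["nu"]
    g_lo, g_hi = priors["gamma"]
    if shift_scale is None:
        shift_scale = 0.1 * T

    def _spec(theta) -> CompartmentalSpec:
        return CompartmentalSpec(
            model_type,
            beta=theta[0],
            nu=theta[1] if has_E else None,
            gamma=theta[2] if has_R else None,
            p=p,
            T=T,
        )

    def log_prior(theta):
        if not b_lo < theta[0] < b_hi:
            return -np.inf
        if has_E and not n_lo < theta[1] < n_hi:
            return -np.inf
        if has_R and not g_lo < theta[2] < g_hi:
            return -np.inf
        lp = -np.log(b_hi - b_lo)
        if has_E:
            lp -= np.log(n_hi - n_lo)
        if has_R:
            lp -= np.log(g_hi - g_lo)
        return lp

    def log_latent(x, theta):
        events = _triples_to_events(x.tE, x.tI, x.tR, p, T, has_E)
        try:
            return epi_log_latent(events, _spec(theta))
        except ValueError:
            return -np.inf

    def log_obs(theta, x):
        infected = (x.tE[:, None] <= panel.times[None, :]) & (
            panel.times[None, :] < x.tR[:, None]
        )
        pos = panel.results == 1
        counts = (
            int(np.sum(pos & infected)),
            int(np.sum(~pos & infected)),
            int(np.sum(~pos & ~infected)),
            int(np.sum(pos & ~infected)),
        )
        probs = (panel.Se, 1.0 - panel.Se, panel.Sp, 1.0 - panel.Sp)
        ll = 0.0
        for n, pr in zip(counts, probs):
            if n:
                if pr <= 0.0:
                    return -np.inf
                ll += n * np.log(pr)
        return ll

    def init_state(rng):
        theta = np.array(
            [
                rng.uniform(b_lo, b_hi),
                rng.uniform(n_lo, n_hi),
                rng.uniform(g_lo, g_hi),
            ]
        )
        tE = np.full(p, np.inf)
        tI = np.full(p, np.inf)
        tR = np.full(p, np.inf)
        tE[0] = tI[0] = 0.0
        return theta, _EpiLatentState(tE, tI, tR)

    param_kernels = [_RateWalk(0, 0.4)]
    if has_E:
        param_kernels.append(_RateWalk(1, 0.4))
    if has_R:
        param_kernels.append(_RateWalk(2, 0.4))
    latent_kernels = []
    for j in range(p):
        latent_kernels.append(_EpiMove(j, "shift", has_E, has_R, T, shift_scale))
        latent_kernels.append(_EpiMove(j, "toggleE", has_E, has_R, T, shift_scale))
        if has_E:
            latent_kernels.append(_EpiMove(j, "toggleI", has_E, has_R, T, shift_scale))
        if has_R:
            latent_kernels.append(_EpiMove(j, "toggleR", has_E, has_R, T, shift_scale))

    return ModelInterface(
        log_prior=log_prior,
        log_obs=log_obs,
        log_latent=log_latent,
        parameter_kernels=param_kernels,
        latent_kernels=latent_kernels,
        init_state=init_state,
        summarize=lambda theta, x: np.array(theta),
    )


# ---------------------------------------------------------------------------
# benchmark-scale evidence and DIC via the numba kernel
# ---------------------------------------------------------------------------


def epi_evidence(
    model_type: str,
    panel: TestPanel,
    K: int = 20,
    n_burnin: int = 2000,
    n_samples: int = 20000,
    swap_interval: int = 1,
    seed: int = 0,
    priors: dict | None = None,
    latent_reps: int = 1,
    ladder: TemperatureLadder | None = None,
) -> tuple[EvidenceEstimate, dict]:
    """Steppingstone evidence and DIC3-6 for one candidate epidemic model.

    Runs the tempered data-augmentation sampler and returns the evidence
    estimate together with a dict of DICResult objects (variants 3-6 computed
    from the posterior chain; the conditional plug-ins use the overall
    posterior-mean rates) and posterior-mean rates.
    """
    if model_type not in MODEL_TYPES:
        raise ValueError(f"unknown model type {model_type!r}")
    priors = {**EPI_PRIORS, **(priors or {})}
    has_E = "E" in model_type
    has_R = model_type.endswith("R")
    if ladder is None:
        ladder = make_ladder(K)
    log_obs, lat0, st0, rates0, rates_prior, _ = epi_ss_kernel(
        has_E,
        has_R,
        panel.p,
        float(panel.T),
        panel.times.astype(np.float64),
        np.ascontiguousarray(panel.results, dtype=np.int8),
        float(panel.Se),
        float(panel.Sp),
        ladder.phis,
        int(n_burnin),
        int(n_samples),
        int(swap_interval),
        int(seed) % 2**31,
        *map(float, priors["beta"]),
        *map(float, priors["nu"]),
        *map(float, priors["gamma"]),
        int(latent_reps),
    )
    trace = ChainTrace(phis=ladder.phis, log_obs=log_obs, log_latent=lat0)
    estimate = stepping_stone_log_evidence(trace, ladder)

    mean_rates = rates0.mean(axis=0)
    log_complete = log_obs[0] + lat0
    # P(y|theta,x) does not involve theta, so the DIC3 conditional plug-in
    # <log P(y|<theta>, x)>_x equals the posterior mean of log P(y|theta,x).
    plugin3 = float(np.mean(log_obs[0]))
    # DIC5 plug-in: re-evaluate log pi(x_i|<theta>) from stored statistics.
    bet, nu, gam = mean_rates
    lat_bar = st0[:, 0] * np.log(bet) + st0[:, 1] - bet * st0[:, 4]
    if has_E:
        lat_bar = lat_bar + st0[:, 2] * np.log(nu) - nu * st0[:, 5]
    if has_R:
        lat_bar = lat_bar + st0[:, 3] * np.log(gam) - gam * st0[:, 6]
    plugin5 = float(np.mean(log_obs[0] + lat_bar))
    dics = {
        "DIC3": dic_mod.dic3(log_obs[0], plugin3),
        "DIC4": dic_mod.dic4(log_obs[0]),
        "DIC5": dic_mod.dic5(log_complete, plugin5),
        "DIC6": dic_mod.dic6(log_complete),
    }
    extras = {
        "dic": dics,
        "posterior_mean_rates": {
            "beta": float(mean_rates[0]),
            "nu": float(mean_rates[1]) if has_E else None,
            "gamma": float(mean_rates[2]) if has_R else None,
        },
        "prior_chain_rates": rates_prior,
        "trace": trace,
    }
    return estimate, extras


def four_model_tournament(
    panels: dict[str, TestPanel],
    K: int = 20,
    n_burnin: int = 2000,
    n_samples: int = 20000,
    seed: int = 0,
    priors: dict | None = None,
    latent_reps: int = 1,
) -> pd.DataFrame:
    """Fit all four candidate models to each dataset; tabulate the measures.

    ``panels`` maps the generating model name to its simulated test panel.
    Returns a long-format table (true_model, candidate, measure_name, value,
    se) containing -2 log P_hat(y) under steppingstone sampling and DIC3-6;
    per row the candidate minimizing each measure identifies the selected
    model.
    """
    rows = []
    sub = 0
    for true_model, panel in panels.items():
        for cand in MODEL_TYPES:
            est, extras = epi_evidence(
                cand,
                panel,
                K=K,
                n_burnin=n_burnin,
                n_samples=n_samples,
                seed=seed + 7919 * sub,
                priors=priors,
                latent_reps=latent_reps,
            )
            sub += 1
            rows.append(
                {
                    "true_model": true_model,
                    "candidate": cand,
                    "measure_name": "minus2_log_evidence",
                    "value": est.minus_two_log_evidence,
                    "se": 2.0 * est.se,
                }
            )
            for name, res in extras["dic"].items():
                rows.append(
                    {
                        "true_model": true_model,
                        "candidate": cand,
                        "measure_name": name,
                        "value": res.value,
                        "se": np.nan,
                    }
                )
    return pd.DataFrame(rows)


def tournament_argmins(table: pd.DataFrame, measure: str = "minus2_log_evidence") -> dict[str, str]:
    """Per generating model, the candidate minimizing the given measure."""
    out = {}
    for true_model, grp in table[table.measure_name == measure].groupby("true_model"):
        out[true_model] = grp.loc[grp.value.idxmin(), "candidate"]
    return out
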