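"""Power-posterior MCMC with replica exchange and the steppingstone estimator.

K chains target the tempered densities P(y|theta,x)^phi_k pi(x|theta) pi(theta)
along a temperature ladder; adjacent chains periodically attempt state swaps to
improve mixing.  The steppingstone estimator turns the sampled log observed-data
likelihoods into an unbiased estimate of the model evidence P(y),

    P_hat(y) = prod_{k=2}^{K} (1/N) sum_i P(y|theta_i^k, x_i^k)^(phi_{k-1}-phi_k),

evaluated entirely in log space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .autocorr import integrated_autocorr
from .interface import ModelInterface, TemperedChainState
from .ladder import TemperatureLadder

__all__ = [
    "ChainTrace",
    "EvidenceEstimate",
    "tempered_log_accept",
    "swap_adjacent",
    "run_power_posteriors",
    "stepping_stone_log_evidence",
    "log_bayes_factor",
]

_MAX_INIT_RETRIES = 100


@dataclass
class ChainTrace:
    """Post-burn-in samples from a ladder of tempered chains.

    ``log_obs`` has shape (K, N): the log observed-data likelihood sampled on
    every chain, which is all the steppingstone estimator needs.  The posterior
    chain (k=1) optionally carries the log latent-process likelihood and model
    summaries for DIC computation.
    """

    phis: np.ndarray
    log_obs: np.ndarray
    log_latent: np.ndarray | None = None
    posterior_summaries: np.ndarray | None = None
    swap_attempts: np.ndarray | None = None
    swap_accepts: np.ndarray | None = None
    accept_rates: np.ndarray | None = None

    @property
    def K(self) -> int:
        return int(self.log_obs.shape[0])

    @property
    def N(self) -> int:
        return int(self.log_obs.shape[1])

    def to_csv(self, path: str | Path) -> None:
        K, N = self.log_obs.shape
        df = pd.DataFrame(
            {
                "chain_index": np.repeat(np.arange(1, K + 1), N),
                "phi": np.repeat(self.phis, N),
                "iteration": np.tile(np.arange(1, N + 1), K),
                "log_obs_likelihood": self.log_obs.ravel(),
            }
        )
        df.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ChainTrace":
        df = pd.read_csv(path)
        chains = np.sort(df["chain_index"].unique())
        phis = np.array(
            [df.loc[df.chain_index == c, "phi"].iloc[0] for c in chains]
        )
        log_obs = np.vstack(
            [
                df.loc[df.chain_index == c].sort_values("iteration")[
                    "log_obs_likelihood"
                ].to_numpy()
                for c in chains
            ]
        )
        return cls(phis=phis, log_obs=log_obs)


@dataclass(frozen=True)
class EvidenceEstimate:
    """Steppingstone estimate of the log model evidence with its MC error."""

    log_evidence: float
    se: float
    K: int
    N: int

    @property
    def minus_two_log_evidence(self) -> float:
        return -2.0 * self.log_evidence

    def to_dict(self) -> dict:
        return {
            "log_evidence": self.log_evidence,
            "minus_two_log_evidence": self.minus_two_log_evidence,
            "se": self.se,
            "K": self.K,
            "N": self.N,
        }


def tempered_log_accept(
    current: TemperedChainState,
    proposal: TemperedChainState,
    log_fwd: float = 0.0,
    log_bwd: float = 0.0,
) -> float:
    """Log MH acceptance probability for a tempered chain at inverse temperature phi.

    Only the observed-data likelihood is raised to the power phi; the latent
    process likelihood and the prior enter untempered, so the phi=0 chain
    ignores the data entirely.  Out-of-support proposals (non-finite log prior
    or latent density) return -inf rather than raising, which makes hard
    uniform-prior bounds act as ordinary rejections.
    """
    if not np.isfinite(proposal.log_prior) or not np.isfinite(proposal.log_latent):
        return -np.inf
    phi = current.phi
    lik_term = phi * (proposal.log_obs - current.log_obs) if phi != 0.0 else 0.0
    ratio = (
        lik_term
        + (proposal.log_latent + proposal.log_prior)
        - (current.log_latent + current.log_prior)
        + log_bwd
        - log_fwd
    )
    return min(0.0, ratio)


def swap_adjacent(
    state_k: TemperedChainState,
    state_k1: TemperedChainState,
    phi_k: float,
    phi_k1: float,
    rng: np.random.Generator,
) -> tuple[TemperedChainState, TemperedChainState, bool]:
    """Attempt a replica-exchange swap between adjacent chains k and k+1.

    The exchange is accepted with probability
    min{1, exp[(phi_k - phi_{k+1}) (logL_{k+1} - logL_k)]}, which preserves the
    product of the two tempered densities.  Returns the (possibly exchanged)
    states, with their phi fields updated to the owning chain.
    """
    log_alpha = (phi_k - phi_k1) * (state_k1.log_obs - state_k.log_obs)
    accepted = log_alpha >= 0.0 or rng.random() < np.exp(log_alpha)
    if accepted:
        state_k, state_k1 = state_k1, state_k
    state_k.phi = phi_k
    state_k1.phi = phi_k1
    return state_k, state_k1, accepted


def _mh_step(
    model: ModelInterface,
    state: TemperedChainState,
    kernel,
    rng: np.random.Generator,
) -> tuple[TemperedChainState, bool]:
    theta_p, x_p, log_fwd, log_bwd = kernel.propose(state.theta, state.x, rng)
    prop = TemperedChainState.evaluate(model, theta_p, x_p, state.phi)
    log_alpha = tempered_log_accept(state, prop, log_fwd, log_bwd)
    if log_alpha >= 0.0 or rng.random() < np.exp(log_alpha):
        return prop, True
    return state, False


def run_power_posteriors(
    model: ModelInterface,
    ladder: TemperatureLadder,
    n_burnin: int,
    n_samples: int,
    swap_interval: int = 1,
    seed: int | np.random.SeedSequence = 0,
    record_latent: bool = False,
    record_summaries: bool = False,
) -> ChainTrace:
    """Run K tempered chains serially with adjacent-chain swap sweeps.

    Every "update" applies each parameter kernel and each latent kernel once to
    each chain; every ``swap_interval`` updates a sweep of adjacent-pair swap
    attempts runs, alternating odd/even pairings between sweeps.  Chains use
    independent RNG streams spawned from ``seed``, so the run is reproducible
    and chain trajectories do not depend on K-ordering artifacts.
    """
    if n_burnin < 0 or n_samples < 1:
        raise ValueError("need n_burnin >= 0 and n_samples >= 1")
    phis = ladder.phis
    K = ladder.K
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = [np.random.Generator(np.random.PCG64(s)) for s in seq.spawn(K + 1)]
    swap_rng = streams[-1]

    kernels = model.kernels()
    states: list[TemperedChainState] = []
    for k in range(K):
        state = None
        for _ in range(_MAX_INIT_RETRIES):
            theta0, x0 = model.init_state(streams[k])
            cand = TemperedChainState.evaluate(model, theta0, x0, phis[k])
            if np.isfinite(cand.log_obs) and np.isfinite(cand.log_prior):
                state = cand
                break
        if state is None:
            raise RuntimeError(
                f"chain {k + 1}: could not initialize a state with finite "
                f"log observed-data likelihood after {_MAX_INIT_RETRIES} draws"
            )
        states.append(state)

    log_obs = np.empty((K, n_samples))
    log_latent = np.empty(n_samples) if record_latent else None
    summaries: list[np.ndarray] = []
    n_kernels = len(kernels)
    accepts = np.zeros((K, n_kernels), dtype=np.int64)
    swap_attempts = np.zeros(K - 1, dtype=np.int64)
    swap_accepts = np.zeros(K - 1, dtype=np.int64)

    total = n_burnin + n_samples
    parity = 0
    for it in range(total):
        for k in range(K):
            st = states[k]
            for j, kern in enumerate(kernels):
                st, ok = _mh_step(model, st, kern, streams[k])
                if ok:
                    accepts[k, j] += 1
            states[k] = st
        if swap_interval > 0 and (it + 1) % swap_interval == 0:
            for k in range(parity, K - 1, 2):
                swap_attempts[k] += 1
                states[k], states[k + 1], ok = swap_adjacent(
                    states[k], states[k + 1], phis[k], phis[k + 1], swap_rng
                )
                if ok:
                    swap_accepts[k] += 1
            parity = 1 - parity
        if it >= n_burnin:
            i = it - n_burnin
            for k in range(K):
                log_obs[k, i] = states[k].log_obs
            if record_latent:
                log_latent[i] = states[0].log_latent
            if record_summaries and model.summarize is not None:
                summaries.append(np.asarray(model.summarize(states[0].theta, states[0].x)))

    return ChainTrace(
        phis=phis.copy(),
        log_obs=log_obs,
        log_latent=log_latent,
        posterior_summaries=np.asarray(summaries) if summaries else None,
        swap_attempts=swap_attempts,
        swap_accepts=swap_accepts,
        accept_rates=accepts / total,
    )


def _ratio_log_mean_and_var(logw: np.ndarray) -> tuple[float, float]:
    """Log of the sample mean of exp(logw), and delta-method variance of that log.

    With relative weights w~ = exp(logw - log r), var(log r) is the iid
    variance of the mean of w~ inflated by the integrated autocorrelation
    length of the weight series, so MCMC correlation within a chain is
    accounted for.
    """
    n = logw.size
    log_r = float(logsumexp(logw) - np.log(n))
    rel = np.exp(logw - log_r) - 1.0
    v_iid = float(np.sum(rel**2)) / (n * max(n - 1, 1))
    tau = integrated_autocorr(rel) if n >= 4 else 1.0
    return log_r, v_iid * tau


def stepping_stone_log_evidence(
    trace: ChainTrace,
    ladder: TemperatureLadder | None = None,
) -> EvidenceEstimate:
    """Steppingstone estimate of log P(y) from a power-posterior trace.

    Each factor k in the product uses samples from chain k with importance
    exponent phi_{k-1} - phi_k, evaluated through log-sum-exp; raw likelihoods
    are never exponentiated.  The standard error combines per-ratio
    autocorrelation-corrected delta-method variances (the ratio terms use
    disjoint chains, so their log contributions add independently).
    """
    phis = ladder.phis if ladder is not None else trace.phis
    if trace.log_obs.shape[0] != phis.size:
        raise ValueError("trace and ladder disagree on the number of chains")
    K, N = trace.log_obs.shape
    log_ev = 0.0
    var = 0.0
    for k in range(1, K):
        logl = trace.log_obs[k]
        if not np.all(np.isfinite(logl)):
            raise ValueError(
                f"chain {k + 1} contains non-finite sampled log-likelihoods"
            )
        dphi = phis[k - 1] - phis[k]
        log_r, v = _ratio_log_mean_and_var(dphi * logl)
        log_ev += log_r
        var += v
    return EvidenceEstimate(log_evidence=log_ev, se=float(np.sqrt(var)), K=K, N=N)


def log_bayes_factor(e1: EvidenceEstimate, e2: EvidenceEstimate) -> float:
    """log B_{1,2} = log P(y|m1) - log P(y|m2) for estimates on the same data."""
    return e1.log_evidence - e2.log_evidence


def write_run_sidecar(
    path: str | Path,
    trace: ChainTrace,
    estimate: EvidenceEstimate | None,
    seed: int,
    extra: dict | None = None,
) -> None:
    """JSON sidecar with ladder, seed, acceptance/swap rates and the estimate."""
    payload = {
        "seed": seed,
        "ladder": [float(p) for p in trace.phis],
        "swap_rates": (
            (trace.swap_accepts / np.maximum(trace.swap_attempts, 1)).tolist()
            if trace.swap_accepts is not None
            else None
        ),
        "accept_rates": (
            trace.accept_rates.mean(axis=1).tolist()
            if trace.accept_rates is not None
            else None
        ),
        "evidence": estimate.to_dict() if estimate is not None else None,
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2))
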