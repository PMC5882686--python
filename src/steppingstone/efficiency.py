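"""Analytic predictions of the update count needed for a target accuracy.

For a target sampling standard deviation epsilon in the model-selection
measure (-2 log P(y) for steppingstone, the DIC value otherwise), the number
of MCMC updates U required is predicted from per-chain statistics:

    SS:   (4/eps^2) K sum_{k=2}^K n_k^cor sigma_k^2 (phi_{k-1} - phi_k)^2
    DIC1: 16 n_1^cor  sigma_1^2 / eps^2
    DIC2:  8 n_1'^cor sigma_1^4 / eps^2

where sigma_k is the standard deviation of the log observed-data likelihood
on chain k, n_k^cor its integrated autocorrelation length in updates, and
n'^cor the autocorrelation length of the squared-deviation series (the
variance estimator mixes on that series, not on the raw one).  For large K
the SS prediction is independent of K: doubling K halves each temperature
gap, and the two effects cancel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autocorr import integrated_autocorr
from .ladder import TemperatureLadder
from .tempering import ChainTrace

__all__ = ["ChainStats", "EfficiencyPrediction", "chain_stats", "predict_updates",
           "integrated_autocorr"]


@dataclass(frozen=True)
class ChainStats:
    sigma: float  # sd of log observed-data likelihood
    n_cor: float  # integrated autocorrelation length, in updates
    n_cor_alt: float  # same, for the squared-deviation series

    def to_dict(self) -> dict:
        return {"sigma": self.sigma, "n_cor": self.n_cor, "n_cor_alt": self.n_cor_alt}


@dataclass(frozen=True)
class EfficiencyPrediction:
    method: str
    U: float
    epsilon: float

    def to_dict(self) -> dict:
        return {"method": self.method, "U": self.U, "epsilon": self.epsilon}


def chain_stats(trace: ChainTrace | np.ndarray, k: int = 1) -> ChainStats:
    """Per-chain statistics feeding the update-count predictions.

    Parameters
    ----------
    trace : ChainTrace or 1-d array
        Sampled log observed-data likelihoods; for a ChainTrace, chain ``k``
        (1-based, 1 = posterior) is used.
    """
    series = trace.log_obs[k - 1] if isinstance(trace, ChainTrace) else np.asarray(trace)
    if series.size < 100:
        raise ValueError("need at least 100 samples for stable chain statistics")
    sigma = float(np.std(series, ddof=1))
    if sigma == 0.0:
        return ChainStats(sigma=0.0, n_cor=1.0, n_cor_alt=1.0)
    dev2 = (series - series.mean()) ** 2
    return ChainStats(
        sigma=sigma,
        n_cor=integrated_autocorr(series),
        n_cor_alt=integrated_autocorr(dev2),
    )


def predict_updates(
    stats: list[ChainStats] | ChainStats,
    ladder: TemperatureLadder | None,
    method: str,
    epsilon: float,
) -> EfficiencyPrediction:
    """Predicted number of updates U to reach sampling sd ``epsilon``.

    For SS, ``stats`` must list one ChainStats per chain of ``ladder``
    (chain 1 first); for DIC1/DIC2 only the posterior chain's statistics are
    used and ``ladder`` may be None.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    method = method.upper()
    if method == "SS":
        if ladder is None:
            raise ValueError("SS prediction needs the temperature ladder")
        if not isinstance(stats, (list, tuple)) or len(stats) != ladder.K:
            raise ValueError("SS prediction needs ChainStats for every chain")
        phis = ladder.phis
        acc = 0.0
        for k in range(1, ladder.K):
            s = stats[k]
            acc += s.n_cor * s.sigma**2 * (phis[k - 1] - phis[k]) ** 2
        U = 4.0 / epsilon**2 * ladder.K * acc
    else:
        s1 = stats[0] if isinstance(stats, (list, tuple)) else stats
        if method == "DIC1":
            U = 16.0 * s1.n_cor * s1.sigma**2 / epsilon**2
        elif method == "DIC2":
            U = 8.0 * s1.n_cor_alt * s1.sigma**4 / epsilon**2
        else:
            raise ValueError(f"unknown method {method!r}; expected SS, DIC1 or DIC2")
    return EfficiencyPrediction(method=method, U=float(U), epsilon=float(epsilon))
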