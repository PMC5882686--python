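"""Generic model interface consumed by the power-posterior sampler.

A model is specified through three log densities — a (proper) parameter prior
pi(theta), a latent process likelihood pi(x|theta) (identically zero for models
without latent variables), and an observed-data likelihood P(y|theta,x) — plus
Metropolis–Hastings proposal kernels for parameters and latent state, and an
initializer drawing (theta, x) from prior x latent process.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Callable, Protocol, Sequence

import numpy as np

__all__ = ["ProposalKernel", "ModelInterface", "TemperedChainState"]


class ProposalKernel(Protocol):
    """A reversible MH proposal on the joint state (theta, x).

    ``propose`` returns the proposed state together with the log forward and
    log backward proposal densities; for symmetric kernels both are zero.
    Swapping the roles of current and proposed state must swap the two
    reported densities.
    """

    def propose(
        self, theta: Any, x: Any, rng: np.random.Generator
    ) -> tuple[Any, Any, float, float]: ...


@dataclass
class ModelInterface:
    """Bundle of densities and kernels defining one candidate model."""

    log_prior: Callable[[Any], float]
    log_obs: Callable[[Any, Any], float]
    parameter_kernels: Sequence[ProposalKernel]
    init_state: Callable[[np.random.Generator], tuple[Any, Any]]
    log_latent: Callable[[Any, Any], float] = lambda x, theta: 0.0
    latent_kernels: Sequence[ProposalKernel] = ()
    #: optional summary extractor recorded on the posterior chain
    summarize: Callable[[Any, Any], np.ndarray] | None = None

    @property
    def has_latent(self) -> bool:
        return len(self.latent_kernels) > 0

    def kernels(self) -> list[ProposalKernel]:
        return list(self.parameter_kernels) + list(self.latent_kernels)


@dataclass
class TemperedChainState:
    """Current state of one tempered chain with cached log densities."""

    theta: Any
    x: Any
    log_obs: float
    log_latent: float
    log_prior: float
    phi: float

    @classmethod
    def evaluate(cls, model: ModelInterface, theta: Any, x: Any, phi: float) -> "TemperedChainState":
        lp = float(model.log_prior(theta))
        if np.isfinite(lp):
            ll = float(model.log_latent(x, theta))
            lo = float(model.log_obs(theta, x))
        else:  # out of support: caches are -inf, never used for accepted states
            ll = -np.inf
            lo = -np.inf
        return cls(theta=theta, x=x, log_obs=lo, log_latent=ll, log_prior=lp, phi=phi)

    @property
    def log_complete(self) -> float:
        """log P(y, x | theta) = log P(y|theta,x) + log pi(x|theta)."""
        return self.log_obs + self.log_latent
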