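"""Inverse-temperature ladders bridging posterior (phi=1) to prior (phi=0)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TemperatureLadder", "make_ladder"]


@dataclass(frozen=True)
class TemperatureLadder:
    """An ordered set of inverse temperatures phi_1 = 1 > phi_2 > ... > phi_K = 0.

    Chain k targets the power posterior P(y|theta,x)^phi_k pi(x|theta) pi(theta);
    the first chain is the posterior, the last samples parameters from the prior
    and latent variables from the latent process.
    """

    phis: np.ndarray = field()

    def __post_init__(self) -> None:
        phis = np.asarray(self.phis, dtype=float)
        object.__setattr__(self, "phis", phis)
        if phis.ndim != 1 or phis.size < 2:
            raise ValueError("a temperature ladder needs at least two chains")
        if phis[0] != 1.0 or phis[-1] != 0.0:
            raise ValueError("ladder endpoints must be exactly phi=1 and phi=0")
        if np.any(np.diff(phis) >= 0):
            raise ValueError("inverse temperatures must be strictly decreasing")

    @property
    def K(self) -> int:
        return int(self.phis.size)

    def __len__(self) -> int:
        return self.K

    def __iter__(self):
        return iter(self.phis)


def make_ladder(K: int, power: float = 5.0) -> TemperatureLadder:
    """Power-law ladder phi_k = ((K-k)/(K-1))**power for k = 1..K.

    The default fifth-power schedule concentrates chains at low inverse
    temperature, where the variance of the log observed-data likelihood is
    largest and adjacent-chain overlap is hardest to maintain.

    Parameters
    ----------
    K : int
        Number of chains (>= 2).
    power : float
        Exponent of the schedule; larger values push more chains toward the
        prior end.
    """
    if K < 2:
        raise ValueError(f"K must be >= 2, got {K}")
    k = np.arange(1, K + 1, dtype=float)
    phis = ((K - k) / (K - 1)) ** float(power)
    phis[0] = 1.0
    phis[-1] = 0.0
    return TemperatureLadder(phis)
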