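"""Linear-regression benchmark: simulator, likelihood, priors and MCMC interface.

The model is y_r = sum_j X_rj beta_j + eps_r with eps_r ~ N(0, eta^2).  The
benchmark design has an intercept column of ones followed by Bernoulli(1/2)
binary regressors; nested candidate models keep the first J_sel columns.
Priors: beta_j ~ U(-2, 2), eta^2 ~ U(0.1, 2) — proper, and diffuse relative
to the posterior at the benchmark sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .interface import ModelInterface

__all__ = [
    "RegressionData",
    "LM_PRIORS",
    "simulate_design",
    "simulate_lm",
    "lm_log_obs",
    "lm_model_interface",
    "default_lm_truth",
]

#: uniform prior bounds used throughout the regression benchmarks
LM_PRIORS = {"beta": (-2.0, 2.0), "eta2": (0.1, 2.0), "omega2": (0.1, 2.0)}


@dataclass
class RegressionData:
    """Response vector and design matrix (first column all ones)."""

    y: np.ndarray
    X: np.ndarray

    @property
    def R(self) -> int:
        return int(self.y.size)

    @property
    def Jprime(self) -> int:
        return int(self.X.shape[1])

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.X, columns=[f"x{j + 1}" for j in range(self.Jprime)])
        df.insert(0, "y", self.y)
        df.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "RegressionData":
        df = pd.read_csv(path)
        xcols = [c for c in df.columns if c.startswith("x")]
        return cls(y=df["y"].to_numpy(float), X=df[xcols].to_numpy(float))


def simulate_design(R: int, Jprime: int, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Design matrix: intercept column of ones, then iid Bernoulli(1/2) columns."""
    if R < 1 or Jprime < 1:
        raise ValueError("need R >= 1 and Jprime >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    X = np.empty((R, Jprime))
    X[:, 0] = 1.0
    if Jprime > 1:
        X[:, 1:] = rng.integers(0, 2, size=(R, Jprime - 1)).astype(float)
    return X


def default_lm_truth(Jprime: int = 10, n_active: int = 5, beta: float = 0.5) -> np.ndarray:
    """Benchmark truth: beta_j = 0.5 for the first five regressors, 0 after."""
    b = np.zeros(Jprime)
    b[:n_active] = beta
    return b


def simulate_lm(
    X: np.ndarray,
    beta_true: np.ndarray,
    eta2_true: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> RegressionData:
    """Draw y = X beta + eps with eps iid N(0, eta2_true)."""
    X = np.asarray(X, dtype=float)
    beta_true = np.asarray(beta_true, dtype=float)
    if X.shape[1] != beta_true.size:
        raise ValueError("design and coefficient dimensions disagree")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    eps = rng.normal(0.0, np.sqrt(eta2_true), size=X.shape[0]) if eta2_true > 0 else 0.0
    return RegressionData(y=X @ beta_true + eps, X=X)


def lm_log_obs(data: RegressionData, beta: np.ndarray, eta2: float) -> float:
    """Gaussian log likelihood of the responses given coefficients and eta^2."""
    if eta2 <= 0:
        raise ValueError("residual variance must be positive")
    beta = np.asarray(beta, dtype=float)
    resid = data.y - data.X[:, : beta.size] @ beta if beta.size else data.y
    R = data.R
    return float(-0.5 * R * np.log(2 * np.pi * eta2) - np.dot(resid, resid) / (2 * eta2))


class _BetaWalk:
    def __init__(self, index: int, scale: float):
        self.index, self.scale = index, scale

    def propose(self, theta, x, rng):
        theta = np.array(theta)
        theta[self.index] += self.scale * rng.standard_normal()
        return theta, x, 0.0, 0.0


class _LogVarianceWalk:
    """Multiplicative random walk on a positive parameter (last slot of theta).

    The proposal is v' = v exp(eps); its density in v-space carries a 1/v'
    Jacobian, so the reported forward/backward log densities differ by
    log(v'/v).
    """

    def __init__(self, index: int, scale: float):
        self.index, self.scale = index, scale

    def propose(self, theta, x, rng):
        theta = np.array(theta)
        v = theta[self.index]
        vp = v * np.exp(self.scale * rng.standard_normal())
        theta[self.index] = vp
        return theta, x, -np.log(vp), -np.log(v)


def lm_model_interface(
    data: RegressionData,
    J_sel: int | None = None,
    priors: dict | None = None,
    beta_scale: float = 0.3,
    eta2_scale: float = 0.3,
) -> ModelInterface:
    """Latent-free ModelInterface for a nested regression model.

    theta = (beta_1 .. beta_{J_sel}, eta2); single-site Gaussian random walks
    on the coefficients and a log-scale walk on eta2.  Proposals landing
    outside the uniform prior bounds are rejected through the -inf log prior.
    """
    priors = {**LM_PRIORS, **(priors or {})}
    J = data.Jprime if J_sel is None else int(J_sel)
    if not 0 <= J <= data.Jprime:
        raise ValueError("J_sel out of range")
    b_lo, b_hi = priors["beta"]
    e_lo, e_hi = priors["eta2"]
    Xs = data.X[:, :J]
    y = data.y
    R = data.R

    def log_prior(theta):
        beta, eta2 = theta[:J], theta[J]
        if np.any(beta < b_lo) or np.any(beta > b_hi) or not (e_lo < eta2 < e_hi):
            return -np.inf
        return -J * np.log(b_hi - b_lo) - np.log(e_hi - e_lo)

    def log_obs(theta, x):
        beta, eta2 = theta[:J], theta[J]
        resid = y - Xs @ beta if J else y
        return float(-0.5 * R * np.log(2 * np.pi * eta2) - resid @ resid / (2 * eta2))

    def init_state(rng):
        theta = np.empty(J + 1)
        theta[:J] = rng.uniform(b_lo, b_hi, size=J)
        theta[J] = rng.uniform(e_lo, e_hi)
        return theta, None

    kernels = [_BetaWalk(j, beta_scale) for j in range(J)]
    kernels.append(_LogVarianceWalk(J, eta2_scale))
    return ModelInterface(
        log_prior=log_prior,
        log_obs=log_obs,
        parameter_kernels=kernels,
        init_state=init_state,
        summarize=lambda theta, x: np.array(theta),
    )
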