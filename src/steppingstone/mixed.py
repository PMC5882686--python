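"""Pedigree mixed model ("animal model"): simulator, likelihoods, MCMC interface.

y_r = sum_j X_rj beta_j + u_r + eps_r, with one additive-genetic random effect
per individual, u ~ MVN(0, omega^2 A) for the pedigree relationship matrix A,
and environmental residuals eps ~ N(0, eta^2).  Heritability is
h^2 = omega^2 / (omega^2 + eta^2).  The random effects are the latent
variables x; the latent process likelihood is the MVN density of u.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .interface import ModelInterface
from .linear import LM_PRIORS, RegressionData, _BetaWalk, _LogVarianceWalk

__all__ = [
    "omega2_from_h2",
    "simulate_mixed",
    "mixed_log_obs",
    "mixed_log_latent",
    "mixed_model_interface",
]


def omega2_from_h2(h2: float, eta2: float) -> float:
    """Genetic variance implied by heritability h2 and environmental variance eta2."""
    if not 0.0 <= h2 < 1.0:
        raise ValueError("heritability must lie in [0, 1)")
    return h2 * eta2 / (1.0 - h2)


def simulate_mixed(
    A: np.ndarray,
    X: np.ndarray,
    beta_true: np.ndarray,
    eta2_true: float = 0.5,
    h2_true: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> tuple[RegressionData, np.ndarray]:
    """Simulate phenotypes with additive genetic effects u ~ MVN(0, omega^2 A)."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    A = np.asarray(A, dtype=float)
    R = A.shape[0]
    if X.shape[0] != R:
        raise ValueError("design matrix rows must match pedigree size")
    omega2 = omega2_from_h2(h2_true, eta2_true)
    try:
        L = np.linalg.cholesky(A)
    except np.linalg.LinAlgError as err:
        raise ValueError("relationship matrix must be positive definite") from err
    u = np.sqrt(omega2) * (L @ rng.standard_normal(R)) if omega2 > 0 else np.zeros(R)
    eps = rng.normal(0.0, np.sqrt(eta2_true), size=R)
    y = X @ np.asarray(beta_true, dtype=float) + u + eps
    return RegressionData(y=y, X=np.asarray(X, dtype=float)), u


def mixed_log_obs(data: RegressionData, beta: np.ndarray, eta2: float, u: np.ndarray) -> float:
    """Gaussian observed-data log likelihood given fixed effects and random effects."""
    if eta2 <= 0:
        raise ValueError("environmental variance must be positive")
    beta = np.asarray(beta, dtype=float)
    resid = data.y - (data.X[:, : beta.size] @ beta if beta.size else 0.0) - u
    R = data.R
    return float(-0.5 * R * np.log(2 * np.pi * eta2) - resid @ resid / (2 * eta2))


def mixed_log_latent(u: np.ndarray, omega2: float, A: np.ndarray) -> float:
    """MVN(0, omega^2 A) log density of the random effects, via Cholesky."""
    if omega2 <= 0:
        raise ValueError("genetic variance must be positive")
    R = u.size
    try:
        c = cho_factor(np.asarray(A, dtype=float), lower=True)
    except np.linalg.LinAlgError as err:
        raise ValueError("relationship matrix must be positive definite") from err
    logdetA = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
    quad = float(u @ cho_solve(c, u))
    return float(
        -0.5 * R * np.log(2 * np.pi) - 0.5 * R * np.log(omega2) - 0.5 * logdetA
        - quad / (2.0 * omega2)
    )


class _RandomEffectWalk:
    """Symmetric single-site walk on one random effect u_q."""

    def __init__(self, q: int, scale: float):
        self.q, self.scale = q, scale

    def propose(self, theta, x, rng):
        x = np.array(x)
        x[self.q] += self.scale * rng.standard_normal()
        return theta, x, 0.0, 0.0


class _RescaleU:
    """Joint multiplicative rescale u -> s u, s = exp(eps).

    Treated as a change of variables: the |ds u / du| = s^R Jacobian enters
    through the reported proposal densities.
    """

    def __init__(self, scale: float):
        self.scale = scale

    def propose(self, theta, x, rng):
        s = np.exp(self.scale * rng.standard_normal())
        xp = np.asarray(x) * s
        R = xp.size
        # log q ratio contributes +R log s; encode as backward - forward
        return theta, xp, -0.5 * R * np.log(s), 0.5 * R * np.log(s)


def mixed_model_interface(
    data: RegressionData,
    A: np.ndarray,
    J_sel: int | None = None,
    priors: dict | None = None,
    beta_scale: float = 0.3,
    var_scale: float = 0.3,
    u_scale: float = 0.4,
) -> ModelInterface:
    """ModelInterface for a nested mixed model with latent random effects.

    theta = (beta_1..beta_{J_sel}, eta2, omega2); x = u (length R).  Parameter
    kernels: single-site walks on beta, log-scale walks on both variances.
    Latent kernels: single-site walks on each u_q plus a joint rescale move.
    """
    priors = {**LM_PRIORS, **(priors or {})}
    J = data.Jprime if J_sel is None else int(J_sel)
    if not 0 <= J <= data.Jprime:
        raise ValueError("J_sel out of range")
    b_lo, b_hi = priors["beta"]
    e_lo, e_hi = priors["eta2"]
    w_lo, w_hi = priors["omega2"]
    A = np.asarray(A, dtype=float)
    R = data.R
    c = cho_factor(A, lower=True)
    logdetA = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
    Ainv = cho_solve(c, np.eye(R))
    cholA = np.linalg.cholesky(A)
    Xs = data.X[:, :J]
    y = data.y
    latent_const = -0.5 * R * np.log(2 * np.pi) - 0.5 * logdetA

    def log_prior(theta):
        beta, eta2, omega2 = theta[:J], theta[J], theta[J + 1]
        if (
            np.any(beta < b_lo)
            or np.any(beta > b_hi)
            or not (e_lo < eta2 < e_hi)
            or not (w_lo < omega2 < w_hi)
        ):
            return -np.inf
        return -J * np.log(b_hi - b_lo) - np.log(e_hi - e_lo) - np.log(w_hi - w_lo)

    def log_latent(x, theta):
        omega2 = theta[J + 1]
        if not w_lo < omega2 < w_hi:
            return -np.inf
        quad = float(x @ Ainv @ x)
        return latent_const - 0.5 * R * np.log(omega2) - quad / (2.0 * omega2)

    def log_obs(theta, x):
        beta, eta2 = theta[:J], theta[J]
        resid = y - (Xs @ beta if J else 0.0) - x
        return float(-0.5 * R * np.log(2 * np.pi * eta2) - resid @ resid / (2 * eta2))

    def init_state(rng):
        theta = np.empty(J + 2)
        theta[:J] = rng.uniform(b_lo, b_hi, size=J)
        theta[J] = rng.uniform(e_lo, e_hi)
        theta[J + 1] = rng.uniform(w_lo, w_hi)
        u = np.sqrt(theta[J + 1]) * (cholA @ rng.standard_normal(R))
        return theta, u

    param_kernels = [_BetaWalk(j, beta_scale) for j in range(J)]
    param_kernels += [_LogVarianceWalk(J, var_scale), _LogVarianceWalk(J + 1, var_scale)]
    latent_kernels = [_RandomEffectWalk(q, u_scale) for q in range(R)]
    latent_kernels.append(_RescaleU(0.1))

    def summarize(theta, x):
        eta2, omega2 = theta[J], theta[J + 1]
        return np.concatenate([theta, [omega2 / (omega2 + eta2)]])

    return ModelInterface(
        log_prior=log_prior,
        log_obs=log_obs,
        log_latent=log_latent,
        parameter_kernels=param_kernels,
        latent_kernels=latent_kernels,
        init_state=init_state,
        summarize=summarize,
    )
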