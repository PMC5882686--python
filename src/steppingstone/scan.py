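"""Nested-model comparison for the regression benchmarks.

Candidate models are indexed by J_sel: the model keeping regressors
1..J_sel (column 1 is the intercept).  For each candidate the steppingstone
evidence and the applicable DIC variants are computed from the same tempered
run: the full ladder feeds the evidence, its phi=1 chain feeds DIC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import dic as dic_mod
from ._kernels import lm_ss_kernel, mixed_ss_kernel
from .ladder import TemperatureLadder, make_ladder
from .linear import LM_PRIORS, RegressionData
from .tempering import ChainTrace, EvidenceEstimate, stepping_stone_log_evidence

__all__ = [
    "lm_evidence",
    "mixed_evidence",
    "fit_mixed_posterior",
    "MixedPosteriorFit",
    "nested_model_scan",
    "scan_argmin",
]


def _bounds(priors):
    priors = {**LM_PRIORS, **(priors or {})}
    return priors["beta"], priors["eta2"], priors["omega2"]


def lm_evidence(
    data: RegressionData,
    J_sel: int | None = None,
    K: int = 20,
    n_burnin: int = 2000,
    n_samples: int = 20000,
    swap_interval: int = 1,
    seed: int = 0,
    priors: dict | None = None,
    ladder: TemperatureLadder | None = None,
) -> tuple[EvidenceEstimate, dict]:
    """Steppingstone evidence plus DIC1/DIC2 for one nested regression model."""
    J = data.Jprime if J_sel is None else int(J_sel)
    if not 0 <= J <= data.Jprime:
        raise ValueError("J_sel out of range")
    (b_lo, b_hi), (e_lo, e_hi), _ = _bounds(priors)
    if ladder is None:
        ladder = make_ladder(K)
    X = np.ascontiguousarray(data.X[:, :J], dtype=np.float64)
    log_obs, beta_mean, eta2_mean, eta2_prior = lm_ss_kernel(
        data.y.astype(np.float64),
        X,
        ladder.phis,
        int(n_burnin),
        int(n_samples),
        int(swap_interval),
        int(seed) % 2**31,
        b_lo,
        b_hi,
        e_lo,
        e_hi,
    )
    trace = ChainTrace(phis=ladder.phis, log_obs=log_obs)
    estimate = stepping_stone_log_evidence(trace, ladder)
    resid = data.y - X @ beta_mean if J else data.y.copy()
    R = data.R
    plugin = float(
        -0.5 * R * np.log(2 * np.pi * eta2_mean) - resid @ resid / (2 * eta2_mean)
    )
    extras = {
        "dic": {
            "DIC1": dic_mod.dic1(log_obs[0], plugin),
            "DIC2": dic_mod.dic2(log_obs[0]),
        },
        "posterior_mean": {"beta": beta_mean, "eta2": float(eta2_mean)},
        "prior_chain_eta2": eta2_prior,
        "trace": trace,
    }
    return estimate, extras


def mixed_evidence(
    data: RegressionData,
    A: np.ndarray,
    J_sel: int | None = None,
    K: int = 20,
    n_burnin: int = 2000,
    n_samples: int = 20000,
    swap_interval: int = 1,
    seed: int = 0,
    priors: dict | None = None,
    ladder: TemperatureLadder | None = None,
) -> tuple[EvidenceEstimate, dict]:
    """Steppingstone evidence plus DIC3-6 for one nested mixed model.

    Conditional plug-ins for DIC3/DIC5 use the overall posterior-mean
    parameters; the stored per-sample residual statistics let the plug-in
    likelihoods be re-evaluated exactly without a second chain.
    """
    J = data.Jprime if J_sel is None else int(J_sel)
    if not 0 <= J <= data.Jprime:
        raise ValueError("J_sel out of range")
    (b_lo, b_hi), (e_lo, e_hi), (w_lo, w_hi) = _bounds(priors)
    if ladder is None:
        ladder = make_ladder(K)
    A = np.asarray(A, dtype=np.float64)
    R = data.R
    if A.shape != (R, R):
        raise ValueError("relationship matrix shape must match the data")
    sign, logdetA = np.linalg.slogdet(A)
    if sign <= 0:
        raise ValueError("relationship matrix must be positive definite")
    Ainv = np.linalg.inv(A)
    X = np.ascontiguousarray(data.X[:, :J], dtype=np.float64)
    (
        log_obs, lat0, h2_0, beta0, eta2_0, omega2_0, ssr0, q0, g0,
    ) = mixed_ss_kernel(
        data.y.astype(np.float64),
        X,
        Ainv,
        float(logdetA),
        ladder.phis,
        int(n_burnin),
        int(n_samples),
        int(swap_interval),
        int(seed) % 2**31,
        b_lo,
        b_hi,
        e_lo,
        e_hi,
        w_lo,
        w_hi,
    )
    trace = ChainTrace(phis=ladder.phis, log_obs=log_obs, log_latent=lat0)
    estimate = stepping_stone_log_evidence(trace, ladder)

    beta_bar = beta0.mean(axis=0)
    eta2_bar = float(eta2_0.mean())
    omega2_bar = float(omega2_0.mean())
    XtX = X.T @ X
    d = beta0 - beta_bar  # (N, J)
    ssr_bar = ssr0 + 2.0 * np.einsum("ij,ij->i", d, g0) + np.einsum(
        "ij,jk,ik->i", d, XtX, d
    ) if J else ssr0
    log_obs_bar = -0.5 * R * np.log(2 * np.pi * eta2_bar) - ssr_bar / (2 * eta2_bar)
    lat_bar = (
        -0.5 * R * np.log(2 * np.pi)
        - 0.5 * logdetA
        - 0.5 * R * np.log(omega2_bar)
        - q0 / (2 * omega2_bar)
    )
    log_complete = log_obs[0] + lat0
    dics = {
        "DIC3": dic_mod.dic3(log_obs[0], float(np.mean(log_obs_bar))),
        "DIC4": dic_mod.dic4(log_obs[0]),
        "DIC5": dic_mod.dic5(log_complete, float(np.mean(log_obs_bar + lat_bar))),
        "DIC6": dic_mod.dic6(log_complete),
    }
    extras = {
        "dic": dics,
        "posterior_mean": {
            "beta": beta_bar,
            "eta2": eta2_bar,
            "omega2": omega2_bar,
            "h2": float(h2_0.mean()),
        },
        "h2_trace": h2_0,
        "trace": trace,
    }
    return estimate, extras


@dataclass(frozen=True)
class MixedPosteriorFit:
    """Single posterior-chain summary for the mixed model."""

    h2_mean: float
    h2_sd: float
    beta_mean: np.ndarray
    eta2_mean: float
    omega2_mean: float
    n_samples: int


def fit_mixed_posterior(
    data: RegressionData,
    A: np.ndarray,
    J_sel: int | None = None,
    n_burnin: int = 2000,
    n_samples: int = 100000,
    seed: int = 0,
    priors: dict | None = None,
) -> MixedPosteriorFit:
    """Posterior-only MCMC (a single phi=1 chain) for parameter recovery."""
    (b_lo, b_hi), (e_lo, e_hi), (w_lo, w_hi) = _bounds(priors)
    J = data.Jprime if J_sel is None else int(J_sel)
    A = np.asarray(A, dtype=np.float64)
    sign, logdetA = np.linalg.slogdet(A)
    if sign <= 0:
        raise ValueError("relationship matrix must be positive definite")
    Ainv = np.linalg.inv(A)
    X = np.ascontiguousarray(data.X[:, :J], dtype=np.float64)
    (
        _, _, h2_0, beta0, eta2_0, omega2_0, _, _, _,
    ) = mixed_ss_kernel(
        data.y.astype(np.float64),
        X,
        Ainv,
        float(logdetA),
        np.array([1.0]),
        int(n_burnin),
        int(n_samples),
        0,
        int(seed) % 2**31,
        b_lo,
        b_hi,
        e_lo,
        e_hi,
        w_lo,
        w_hi,
    )
    return MixedPosteriorFit(
        h2_mean=float(h2_0.mean()),
        h2_sd=float(h2_0.std(ddof=1)),
        beta_mean=beta0.mean(axis=0),
        eta2_mean=float(eta2_0.mean()),
        omega2_mean=float(omega2_0.mean()),
        n_samples=int(n_samples),
    )


def nested_model_scan(
    data: RegressionData,
    model_family: str = "lm",
    jsels=None,
    A: np.ndarray | None = None,
    K: int = 20,
    n_burnin: int = 2000,
    n_samples: int = 20000,
    seed: int = 0,
    priors: dict | None = None,
) -> pd.DataFrame:
    """Evidence and DIC over the nested candidate ladder J_sel = 0..J'.

    Returns a long table (J_sel, measure_name, value, se); ``scan_argmin``
    reads off the selected model per measure, breaking ties toward the
    smaller (more parsimonious) J_sel.
    """
    if model_family not in ("lm", "mixed"):
        raise ValueError("model_family must be 'lm' or 'mixed'")
    if model_family == "mixed" and A is None:
        raise ValueError("the mixed family needs the relationship matrix A")
    if jsels is None:
        jsels = range(data.Jprime + 1)
    jsels = list(jsels)
    if not jsels:
        raise ValueError("empty J_sel range")
    ladder = make_ladder(K)
    rows = []
    for idx, J in enumerate(jsels):
        sub_seed = seed + 7919 * idx
        if model_family == "lm":
            est, extras = lm_evidence(
                data, J, K=K, n_burnin=n_burnin, n_samples=n_samples,
                seed=sub_seed, priors=priors, ladder=ladder,
            )
        else:
            est, extras = mixed_evidence(
                data, A, J, K=K, n_burnin=n_burnin, n_samples=n_samples,
                seed=sub_seed, priors=priors, ladder=ladder,
            )
        rows.append(
            {
                "J_sel": J,
                "measure_name": "minus2_log_evidence",
                "value": est.minus_two_log_evidence,
                "se": 2.0 * est.se,
            }
        )
        for name, res in extras["dic"].items():
            rows.append(
                {"J_sel": J, "measure_name": name, "value": res.value, "se": np.nan}
            )
    return pd.DataFrame(rows)


def scan_argmin(table: pd.DataFrame, measure: str = "minus2_log_evidence") -> int:
    """J_sel minimizing the measure; ties go to the smallest J_sel."""
    sub = table[table.measure_name == measure].sort_values("J_sel")
    if sub.empty:
        raise ValueError(f"measure {measure!r} not present in the table")
    return int(sub.loc[sub.value.idxmin(), "J_sel"])
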