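"""AIC and the six deviance-information-criterion variants.

For models without latent variables two DIC definitions are in circulation:
one with a plug-in penalty (DIC1) and one with a variance penalty (DIC2),
both computed from the posterior samples of the log observed-data likelihood.
With latent variables x the observed-data likelihood P(y|theta,x) (DIC3/DIC4)
or the complete likelihood P(y,x|theta) = P(y|theta,x) pi(x|theta)
(DIC5/DIC6) can be used, again with either penalty style.

Every result satisfies ``value = mean_deviance + p_eff`` with
``mean_deviance = -2 <logL>``.  For the plug-in variants
``p_eff = 2 (logL_plugin - <logL>)``; relative to the plug-in deviance
``-2 logL_plugin`` the penalty is twice that, which is the quantity that
converges to 2 p_m in the flat-prior limit.  The variance-penalty variants
have ``p_eff = 2 var[logL] >= 0``; the plug-in penalties may be negative for
poor plug-ins and are reported as computed, never clamped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "PosteriorSample",
    "DICResult",
    "aic",
    "dic1",
    "dic2",
    "dic3",
    "dic4",
    "dic5",
    "dic6",
    "dic_from_arrays",
]


@dataclass(frozen=True)
class PosteriorSample:
    """One posterior draw: parameters plus cached log likelihoods.

    ``log_complete - log_obs`` equals the log latent-process density at the
    stored latent state (zero when the model has none).
    """

    theta: np.ndarray | None
    log_obs: float
    log_complete: float | None = None
    x_id: object = None


@dataclass(frozen=True)
class DICResult:
    variant: str
    value: float
    mean_deviance: float
    p_eff: float
    n_samples: int

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "value": self.value,
            "mean_deviance": self.mean_deviance,
            "p_eff": self.p_eff,
            "n_samples": self.n_samples,
        }


def aic(log_obs_max: float, p_m: int) -> float:
    """Akaike information criterion -2 log P(y|theta_max) + 2 p_m."""
    if p_m < 0:
        raise ValueError("p_m must be nonnegative")
    return -2.0 * log_obs_max + 2.0 * p_m


def _as_logl(samples: Sequence[PosteriorSample] | np.ndarray, attr: str) -> np.ndarray:
    if isinstance(samples, np.ndarray):
        arr = np.asarray(samples, dtype=float)
    else:
        if len(samples) and isinstance(samples[0], PosteriorSample):
            arr = np.array([getattr(s, attr) for s in samples], dtype=float)
        else:
            arr = np.asarray(samples, dtype=float)
    if arr.size == 0:
        raise ValueError("empty posterior sample")
    if np.any(np.isnan(arr)):
        raise ValueError(f"posterior sample contains missing {attr} values")
    return arr


def _plugin_variant(logl: np.ndarray, plugin: float, variant: str) -> DICResult:
    mean = float(np.mean(logl))
    mean_dev = -2.0 * mean
    value = mean_dev + 2.0 * (plugin - mean)
    return DICResult(variant, value, mean_dev, value - mean_dev, logl.size)


def _variance_variant(logl: np.ndarray, variant: str) -> DICResult:
    if logl.size < 2:
        raise ValueError(f"{variant} needs at least two samples")
    mean_dev = -2.0 * float(np.mean(logl))
    p_eff = 2.0 * float(np.var(logl, ddof=1))
    return DICResult(variant, mean_dev + p_eff, mean_dev, p_eff, logl.size)


def dic1(samples, plugin_log_obs: float) -> DICResult:
    """DIC1 = -2<log P(y|theta)> + 2(log P(y|<theta>) - <log P(y|theta)>).

    ``plugin_log_obs`` is the observed-data log likelihood at the posterior
    mean parameters, supplied by the caller since it costs one extra
    likelihood evaluation.
    """
    return _plugin_variant(_as_logl(samples, "log_obs"), plugin_log_obs, "DIC1")


def dic2(samples) -> DICResult:
    """DIC2 = -2<log P(y|theta)> + 2 var[log P(y|theta)] (unbiased variance)."""
    return _variance_variant(_as_logl(samples, "log_obs"), "DIC2")


def dic3(samples, plugin_log_obs_conditional: float) -> DICResult:
    """Plug-in DIC on the observed-data likelihood averaged over latent states.

    The plug-in term approximates <log P(y|<theta>_{theta|x}, x)>_x; by default
    callers approximate the conditional posterior mean with the overall
    posterior mean <theta>, averaging the resulting log likelihood over the
    sampled latent states.
    """
    return _plugin_variant(
        _as_logl(samples, "log_obs"), plugin_log_obs_conditional, "DIC3"
    )


def dic4(samples) -> DICResult:
    """Variance-penalty DIC on log P(y|theta,x) over the full (theta, x) posterior."""
    return _variance_variant(_as_logl(samples, "log_obs"), "DIC4")


def dic5(samples, plugin_log_complete_conditional: float) -> DICResult:
    """Plug-in DIC on the complete likelihood P(y,x|theta)."""
    return _plugin_variant(
        _as_logl(samples, "log_complete"), plugin_log_complete_conditional, "DIC5"
    )


def dic6(samples) -> DICResult:
    """Variance-penalty DIC on the complete likelihood P(y,x|theta)."""
    return _variance_variant(_as_logl(samples, "log_complete"), "DIC6")


def dic_from_arrays(
    log_obs: np.ndarray,
    log_complete: np.ndarray | None = None,
    plugin_log_obs: float | None = None,
    plugin_log_complete: float | None = None,
) -> dict[str, DICResult]:
    """Convenience: all applicable variants from raw posterior-chain arrays.

    Latent-free chains (``log_complete`` None or equal to ``log_obs``) yield
    DIC1/DIC2; latent models yield DIC3..DIC6.  Plug-in variants are emitted
    only when the corresponding plug-in value is supplied.
    """
    out: dict[str, DICResult] = {}
    latent = log_complete is not None and not np.array_equal(log_obs, log_complete)
    if not latent:
        if plugin_log_obs is not None:
            out["DIC1"] = dic1(log_obs, plugin_log_obs)
        out["DIC2"] = dic2(log_obs)
    else:
        if plugin_log_obs is not None:
            out["DIC3"] = dic3(log_obs, plugin_log_obs)
        out["DIC4"] = dic4(log_obs)
        if plugin_log_complete is not None:
            out["DIC5"] = dic5(log_complete, plugin_log_complete)
        out["DIC6"] = dic6(log_complete)
    return out
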