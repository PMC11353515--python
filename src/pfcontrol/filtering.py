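"""Adaptive particle filter: ESS-triggered multinomial resampling and SIR steps.

The filter approximates p(x_t | y_{1:t}) by N weighted particles.  Before
each prediction it checks the effective sample size (ESS) of the previous
weights; when ESS <= alpha*N it redraws ancestors by multinomial resampling
(predecessor weights then count as uniform), otherwise ancestors are the
identity and predecessor weights carry through.  The proposal equals the
system model, so the incremental weight is the observation likelihood alone;
weights are combined in log space with a max-shift before normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ssm import (
    DegenerateWeightsError,
    InvalidParameterError,
    ParticleEnsemble,
    StateSpaceModel,
)

__all__ = [
    "PFConfig",
    "effective_sample_size",
    "multinomial_resample",
    "init_particles",
    "pf_step",
    "filtering_mean",
    "normalize_log_weights",
]


@dataclass(frozen=True)
class PFConfig:
    """Particle count N and resampling-threshold rate alpha in [0, 1]."""

    n: int = 1000
    alpha: float = 0.8

    def __post_init__(self) -> None:
        if self.n < 1:
            raise InvalidParameterError("particle count N must be >= 1")
        if not 0.0 <= self.alpha <= 1.0:
            raise InvalidParameterError("alpha must lie in [0, 1]")


def effective_sample_size(weights: np.ndarray) -> float:
    """ESS = 1 / sum_i w_i^2 of a normalized weight vector; in [1, N]."""
    w = np.asarray(weights, dtype=float)
    s = float(np.sum(w * w))
    if s == 0.0:
        raise DegenerateWeightsError("all weights are zero")
    return 1.0 / s


def multinomial_resample(weights: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw N ancestor indices i.i.d. from the categorical given by ``weights``."""
    w = np.asarray(weights, dtype=float)
    if abs(w.sum() - 1.0) > 1e-9:
        raise InvalidParameterError("weights must be normalized for resampling")
    n = w.size
    # inverse-CDF sampling; equivalent to n categorical draws
    cdf = np.cumsum(w)
    cdf[-1] = 1.0
    return np.searchsorted(cdf, rng.random(n), side="left").astype(np.intp)


def normalize_log_weights(logw: np.ndarray, t: int | str = "?") -> np.ndarray:
    """Max-shifted exponentiation and normalization of log-weights.

    Raises
    ------
    DegenerateWeightsError
        If every log-weight is -inf or NaN (total likelihood underflow),
        naming the time index ``t``.
    """
    logw = np.asarray(logw, dtype=float)
    m = np.max(logw, initial=-np.inf, where=np.isfinite(logw))
    if not np.isfinite(m):
        raise DegenerateWeightsError(f"all particle weights underflowed at t={t}")
    w = np.exp(np.where(np.isfinite(logw), logw - m, -np.inf))
    total = w.sum()
    if total == 0.0 or not np.isfinite(total):
        raise DegenerateWeightsError(f"all particle weights underflowed at t={t}")
    return w / total


def init_particles(
    model: StateSpaceModel, cfg: PFConfig, rng: np.random.Generator
) -> ParticleEnsemble:
    """Ensemble at t=0: N draws from p0(x), uniform weights, identity indices."""
    x0 = model.initial_sample(cfg.n, rng)
    ident = np.arange(cfg.n, dtype=np.intp)
    return ParticleEnsemble(
        t=0,
        x=x0,
        w=np.full(cfg.n, 1.0 / cfg.n),
        ancestors=ident.copy(),
        enoch=ident.copy(),
        resampled=False,
    )


def pf_step(
    prev: ParticleEnsemble,
    y_t: np.ndarray,
    u_prev: np.ndarray | float,
    model: StateSpaceModel,
    theta: np.ndarray,
    cfg: PFConfig,
    rng: np.random.Generator,
) -> ParticleEnsemble:
    """One resample/predict/weight cycle of the adaptive particle filter.

    The resampling decision uses the weights at t-1: when their ESS is at
    most alpha*N, ancestors are multinomial draws and predecessor weights are
    treated as uniform; otherwise ancestors are the identity and predecessor
    weights carry through.  Particles are then propagated through the system
    model conditioned on ``u_prev`` and reweighted by the observation
    likelihood of ``y_t``.
    """
    n = cfg.n
    if prev.n != n:
        raise InvalidParameterError("ensemble size does not match PFConfig.n")
    resample = effective_sample_size(prev.w) <= cfg.alpha * n
    if resample:
        ancestors = multinomial_resample(prev.w, rng)
        log_w_pred = np.zeros(n)  # uniform predecessor weights, constant dropped
    else:
        ancestors = np.arange(n, dtype=np.intp)
        with np.errstate(divide="ignore"):
            log_w_pred = np.log(prev.w)

    u_anc = u_prev if np.isscalar(u_prev) else np.asarray(u_prev)[ancestors]
    x_new = model.transition_sample(prev.x[ancestors], u_anc, theta, rng)
    log_lik = model.observation_logpdf(y_t, x_new, theta)
    w_new = normalize_log_weights(log_w_pred + log_lik, t=prev.t + 1)

    return ParticleEnsemble(
        t=prev.t + 1,
        x=x_new,
        w=w_new,
        ancestors=ancestors,
        enoch=prev.enoch[ancestors],
        resampled=resample,
    )


def filtering_mean(ens: ParticleEnsemble) -> np.ndarray:
    """Weighted-mean point estimate sum_i w^(i) x^(i) of the latent state."""
    return ens.w @ ens.x
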