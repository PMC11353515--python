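"""AdaSmooth-based online EM: kappa recursion, Enoch-index diversity, backward
ancestor sampling, and the online M-step.

Online EM replaces the batch E-step with a stochastic-approximation update of
a per-particle statistic kappa_t^(i), shaped like the model's additive
sufficient-statistic increment s~.  With decay rate gamma_t (default 1/t),

    kappa_t^(i) = (1 - gamma_t) kappa_{t-1}^(A_t(i))
                  + gamma_t s~_t(x_{t-1}^(A_t(i)), x_t^(i)).

Propagating kappa along the filter genealogy alone degenerates as lineages
coalesce, so the recursion is stabilized adaptively: each particle's Enoch
index tracks its lineage back to the last backward-sampling event, and when
the number of unique Enoch indices falls to beta*N or below, one backward
ancestor B_t^(i) per particle is drawn from the smoothing kernel

    B_t^(i) ~ Categorical( w_{t-1}^(l) p(x_t^(i) | x_{t-1}^(l)) )

and the kappa update becomes the half/half blend of the ancestor-path and
backward-path updates.  The smoothed statistic sum_i w_t^(i) kappa_t^(i)
feeds the model's M-step map Lambda to produce theta-hat_t.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .filtering import multinomial_resample, normalize_log_weights
from .ssm import (
    DegenerateWeightsError,
    InvalidParameterError,
    ParticleEnsemble,
    SingularStatisticsError,
    StateSpaceModel,
    SuffStats,
)

__all__ = [
    "decay_rate",
    "make_decay_schedule",
    "update_enoch",
    "ancestor_diversity",
    "backward_ancestor_sample",
    "backward_ancestor_sample_all",
    "SmoothingState",
    "update_kappa",
    "smoothed_statistic",
    "em_update",
    "OnlineEM",
]

logger = logging.getLogger(__name__)


def decay_rate(t: int, exponent: float = 1.0) -> float:
    """Stochastic-approximation decay gamma_t = t^(-exponent), default 1/t.

    Exponents in (0.5, 1] satisfy the Robbins–Monro conditions
    (sum gamma_t diverges, sum gamma_t^2 converges; for exponent 1 the square
    sum is pi^2/6).
    """
    if t < 1:
        raise InvalidParameterError(f"decay rate defined for t >= 1, got {t}")
    if not 0.5 < exponent <= 1.0:
        raise InvalidParameterError("decay exponent must lie in (0.5, 1]")
    return float(t) ** (-exponent)


def make_decay_schedule(exponent: float = 1.0) -> Callable[[int], float]:
    """Return the map t -> t^(-exponent) as a callable schedule."""
    decay_rate(1, exponent)  # validate exponent eagerly
    return lambda t: decay_rate(t, exponent)


def update_enoch(
    prev_enoch: np.ndarray, ancestors: np.ndarray, just_backward_sampled: bool
) -> np.ndarray:
    """Enoch-index update: identity right after backward sampling, ancestor
    composition E_t^(i) = E_{t-1}^(A_t(i)) otherwise."""
    prev_enoch = np.asarray(prev_enoch, dtype=np.intp)
    ancestors = np.asarray(ancestors, dtype=np.intp)
    n = prev_enoch.size
    for name, idx in (("prev_enoch", prev_enoch), ("ancestors", ancestors)):
        if idx.min(initial=0) < 0 or idx.max(initial=0) >= n:
            raise InvalidParameterError(f"{name} indices must lie in 0..N-1")
    if just_backward_sampled:
        return np.arange(n, dtype=np.intp)
    return prev_enoch[ancestors]


def ancestor_diversity(enoch: np.ndarray) -> int:
    """Number of unique Enoch indices N^anc, in [1, N]."""
    return int(np.unique(np.asarray(enoch)).size)


def _backward_log_kernel(
    prev: ParticleEnsemble,
    x_t: np.ndarray,
    u_prev: np.ndarray | float,
    model: StateSpaceModel,
    theta: np.ndarray,
) -> np.ndarray:
    """Log of the un-normalized backward kernel for each previous particle."""
    with np.errstate(divide="ignore"):
        logw = np.log(prev.w)
    return logw + model.transition_logpdf(prev.x, x_t[None, :], u_prev, theta)


def backward_ancestor_sample(
    prev: ParticleEnsemble,
    x_t_i: np.ndarray,
    u_prev: np.ndarray | float,
    model: StateSpaceModel,
    theta: np.ndarray,
    rng: np.random.Generator,
    max_trials: int | None = None,
) -> int:
    """Draw one backward ancestor index for a single current-time particle.

    Target law: Categorical with un-normalized probabilities
    w_{t-1}^(l) p(x_t | x_{t-1}^(l), u_prev; theta).  Implemented by
    rejection sampling — propose l ~ M(w_{t-1}), accept with probability
    p / p_max — capped at ceil(sqrt(N)) trials, then an exact categorical
    draw over all N terms as fallback.
    """
    x_t_i = np.asarray(x_t_i, dtype=float).reshape(-1)
    n = prev.n
    cap = max_trials if max_trials is not None else max(1, math.ceil(math.sqrt(n)))
    log_pmax = model.transition_logpdf_max(u_prev, theta)
    cdf = np.cumsum(prev.w)
    cdf[-1] = 1.0
    for _ in range(cap):
        l = int(np.searchsorted(cdf, rng.random(), side="left"))
        logp = float(
            model.transition_logpdf(prev.x[l][None, :], x_t_i[None, :], u_prev, theta)[0]
        )
        if math.log(rng.random() + 1e-300) < logp - log_pmax:
            return l
    # exact fallback over all N terms
    logk = _backward_log_kernel(prev, x_t_i, u_prev, model, theta)
    try:
        probs = normalize_log_weights(logk, t=prev.t)
    except DegenerateWeightsError as exc:
        raise DegenerateWeightsError(
            f"backward kernel degenerate at t={prev.t + 1}"
        ) from exc
    cdf = np.cumsum(probs)
    cdf[-1] = 1.0
    return int(np.searchsorted(cdf, rng.random(), side="left"))


def backward_ancestor_sample_all(
    prev: ParticleEnsemble,
    curr: ParticleEnsemble,
    u_prev: np.ndarray | float,
    model: StateSpaceModel,
    theta: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized backward ancestor draw, one index per current particle.

    Runs up to ceil(sqrt(N)) synchronized rejection rounds for all particles
    at once, then resolves the still-unaccepted ones with exact categorical
    draws (one N-term kernel evaluation per leftover particle, batched).
    """
    n = prev.n
    if not np.isscalar(u_prev):
        u_prev = np.asarray(u_prev, dtype=float)
    log_pmax = model.transition_logpdf_max(u_prev, theta)
    cap = max(1, math.ceil(math.sqrt(n)))
    cdf = np.cumsum(prev.w)
    cdf[-1] = 1.0

    out = np.full(n, -1, dtype=np.intp)
    pending = np.arange(n, dtype=np.intp)
    for _ in range(cap):
        if pending.size == 0:
            break
        props = np.searchsorted(cdf, rng.random(pending.size), side="left").astype(np.intp)
        logp = model.transition_logpdf(prev.x[props], curr.x[pending], u_prev, theta)
        accept = np.log(rng.random(pending.size) + 1e-300) < logp - log_pmax
        out[pending[accept]] = props[accept]
        pending = pending[~accept]

    if pending.size:
        with np.errstate(divide="ignore"):
            logw_prev = np.log(prev.w)
        # (n_pending, N) kernel matrix; memory-bounded by chunking
        chunk = max(1, int(2_000_000 // max(n, 1)))
        for s in range(0, pending.size, chunk):
            idx = pending[s : s + chunk]
            logk = logw_prev[None, :] + model.transition_logpdf(
                prev.x[None, :, :], curr.x[idx][:, None, :], u_prev, theta
            )
            m = logk.max(axis=1, keepdims=True)
            if not np.all(np.isfinite(m)):
                raise DegenerateWeightsError(
                    f"backward kernel degenerate at t={curr.t}"
                )
            p = np.exp(logk - m)
            p /= p.sum(axis=1, keepdims=True)
            c = np.cumsum(p, axis=1)
            c[:, -1] = 1.0
            u = rng.random((idx.size, 1))
            out[idx] = (c < u).sum(axis=1).astype(np.intp)
    return out


# ---------------------------------------------------------------------------
# Smoothing state and the kappa recursion
# ---------------------------------------------------------------------------

@dataclass
class SmoothingState:
    """Per-particle kappa statistics and the AdaSmooth bookkeeping.

    ``kappa_A``/``kappa_b`` have shapes (N, k, k) and (N, k) matching the
    model's sufficient-statistic increment; ``enoch`` holds the lineage
    indices; ``t0`` the time of the last backward-sampling event (0 before
    any); ``beta`` the diversity-threshold rate; ``gamma`` the decay
    schedule; ``burn_in`` the number of steps during which theta-hat stays
    frozen while kappa accumulates.
    """

    kappa_A: np.ndarray
    kappa_b: np.ndarray
    enoch: np.ndarray
    t0: int = 0
    beta: float = 0.7
    gamma: Callable[[int], float] = field(default_factory=make_decay_schedule)
    burn_in: int = 0
    last_backward: bool = False

    @classmethod
    def initial(
        cls,
        n: int,
        k: int,
        beta: float = 0.7,
        gamma: Callable[[int], float] | None = None,
        burn_in: int = 0,
    ) -> "SmoothingState":
        if not 0.0 <= beta <= 1.0:
            raise InvalidParameterError("beta must lie in [0, 1]")
        return cls(
            kappa_A=np.zeros((n, k, k)),
            kappa_b=np.zeros((n, k)),
            enoch=np.arange(n, dtype=np.intp),
            t0=0,
            beta=beta,
            gamma=gamma or make_decay_schedule(),
            burn_in=burn_in,
        )


def update_kappa(
    smooth: SmoothingState,
    prev: ParticleEnsemble,
    curr: ParticleEnsemble,
    u_prev: np.ndarray | float,
    model: StateSpaceModel,
    theta: np.ndarray,
    rng: np.random.Generator,
) -> SmoothingState:
    """One AdaSmooth update of the per-particle statistics at time t = curr.t.

    Evaluates the ancestor diversity on the Enoch indices composed through
    A_t (reset to the identity when t = t0 + 1); above the beta*N threshold
    it applies the plain genealogy update, otherwise it draws one backward
    ancestor per particle and applies the half/half blend, advancing t0.
    """
    t = curr.t
    gam = smooth.gamma(t)
    A = curr.ancestors
    enoch = update_enoch(smooth.enoch, A, just_backward_sampled=(t == smooth.t0 + 1))
    diversity = ancestor_diversity(enoch)

    sA_A, sA_b = model.suffstat_increment(prev.x[A], curr.x, u_prev)
    kA_A = (1.0 - gam) * smooth.kappa_A[A] + gam * sA_A
    kA_b = (1.0 - gam) * smooth.kappa_b[A] + gam * sA_b

    if diversity > smooth.beta * curr.n:
        new_A, new_b = kA_A, kA_b
        t0, backward = smooth.t0, False
    else:
        B = backward_ancestor_sample_all(prev, curr, u_prev, model, theta, rng)
        sB_A, sB_b = model.suffstat_increment(prev.x[B], curr.x, u_prev)
        kB_A = (1.0 - gam) * smooth.kappa_A[B] + gam * sB_A
        kB_b = (1.0 - gam) * smooth.kappa_b[B] + gam * sB_b
        new_A = 0.5 * (kA_A + kB_A)
        new_b = 0.5 * (kA_b + kB_b)
        t0, backward = t, True

    return SmoothingState(
        kappa_A=new_A,
        kappa_b=new_b,
        enoch=enoch,
        t0=t0,
        beta=smooth.beta,
        gamma=smooth.gamma,
        burn_in=smooth.burn_in,
        last_backward=backward,
    )


def smoothed_statistic(curr: ParticleEnsemble, smooth: SmoothingState) -> SuffStats:
    """Weighted average sum_i w_t^(i) kappa_t^(i), component-wise."""
    w = curr.w
    return SuffStats(
        A=np.einsum("i,ijk->jk", w, smooth.kappa_A),
        b=np.einsum("i,ij->j", w, smooth.kappa_b),
    )


def em_update(
    stat: SuffStats,
    t: int,
    model: StateSpaceModel,
    smooth: SmoothingState,
    theta_prev: np.ndarray,
) -> np.ndarray:
    """Online M-step: theta-hat_t = Lambda(stat / t) after burn-in.

    During burn-in (t <= burn_in) the previous estimate is returned while
    kappa keeps accumulating.  A singular A-part keeps the previous estimate
    and logs a warning rather than aborting the closed loop.  Both shipped
    Lambda maps are scale-invariant, so the 1/t factor has no effect on them.
    """
    if t < 1:
        raise InvalidParameterError("em_update defined for t >= 1")
    if t <= smooth.burn_in:
        return theta_prev
    try:
        theta = model.lambda_map((1.0 / t) * stat)
    except (SingularStatisticsError, np.linalg.LinAlgError):
        logger.warning("singular sufficient statistics at t=%d; keeping theta", t)
        return theta_prev
    if not np.all(np.isfinite(theta)):
        logger.warning("non-finite M-step output at t=%d; keeping theta", t)
        return theta_prev
    theta, projected = model.project_params(theta)
    if projected:
        logger.info("positivity projection active at t=%d", t)
    return theta


class OnlineEM:
    """Stateful convenience wrapper driving the AdaSmooth online EM recursion.

    Call :meth:`step` once per filter step with the consecutive ensembles;
    it updates kappa/Enoch bookkeeping, performs the M-step, and returns the
    current parameter estimate.
    """

    def __init__(
        self,
        model: StateSpaceModel,
        n: int,
        theta0: np.ndarray,
        beta: float = 0.7,
        gamma: Callable[[int], float] | None = None,
        burn_in: int = 0,
    ) -> None:
        self.model = model
        self.theta = np.asarray(theta0, dtype=float).copy()
        self.state = SmoothingState.initial(
            n, model.suffstat_dim, beta=beta, gamma=gamma, burn_in=burn_in
        )

    @property
    def diversity(self) -> int:
        return ancestor_diversity(self.state.enoch)

    @property
    def backward_sampled(self) -> bool:
        return self.state.last_backward

    def step(
        self,
        prev: ParticleEnsemble,
        curr: ParticleEnsemble,
        u_prev: np.ndarray | float,
        rng: np.random.Generator,
    ) -> np.ndarray:
        self.state = update_kappa(
            self.state, prev, curr, u_prev, self.model, self.theta, rng
        )
        stat = smoothed_statistic(curr, self.state)
        self.theta = em_update(stat, curr.t, self.model, self.state, self.theta)
        return self.theta
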