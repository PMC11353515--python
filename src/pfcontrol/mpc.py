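"""Particle-filter model predictive control (PF-MPC).

The control problem over a receding horizon of T_H steps is recast as a
filtering problem on an augmented state zeta = (x-bar, u-bar, u-tilde): the
predictive state, the predictive input (a clamped random walk), and a frozen
copy of the initial input carried along each lineage.  The reference
trajectory plays the role of observations through a Gaussian likelihood
N(r_tau | selector(x-bar), sigma_r^2).  Running the same adaptive-resampling
particle-filter machinery over the horizon and taking the weighted mean of
the preserved initial inputs at the final horizon time yields the applied
control — by construction a convex combination of proposals that satisfy the
input constraint.
"""

from __future__ import annotations

import abc
import math
from dataclasses import dataclass

import numpy as np

from .filtering import PFConfig, effective_sample_size, multinomial_resample, normalize_log_weights
from .ssm import InvalidParameterError, ParticleEnsemble, StateSpaceModel

__all__ = [
    "AugmentedEnsemble",
    "ReferenceModel",
    "ControlTransitionModel",
    "init_augmented",
    "horizon_step",
    "extract_control",
    "mpc_control",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass
class AugmentedEnsemble:
    """Horizon particles (x-bar, u-bar, u-tilde) with weights at horizon time tau."""

    tau: int
    x: np.ndarray  # (N, state_dim) predictive states
    u: np.ndarray  # (N,) predictive inputs
    u_init: np.ndarray  # (N,) preserved initial inputs
    w: np.ndarray  # (N,) normalized weights

    def __post_init__(self) -> None:
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        self.u = np.asarray(self.u, dtype=float).reshape(-1)
        self.u_init = np.asarray(self.u_init, dtype=float).reshape(-1)
        self.w = np.asarray(self.w, dtype=float).reshape(-1)
        n = self.x.shape[0]
        if not (self.u.size == self.u_init.size == self.w.size == n):
            raise InvalidParameterError("augmented ensemble arrays disagree in length")

    @property
    def n(self) -> int:
        return self.x.shape[0]


@dataclass(frozen=True)
class ReferenceModel:
    """Gaussian reference likelihood over a selected state coordinate.

    ``selector`` is the index of the state coordinate compared against the
    reference (the y-coordinate for Lorenz, the membrane potential for
    Morris–Lecar); ``sigma_r2`` the acceptable-error variance; ``horizon``
    the number of horizon steps T_H.
    """

    selector: int
    sigma_r2: float
    horizon: int

    def __post_init__(self) -> None:
        if self.sigma_r2 <= 0:
            raise InvalidParameterError("sigma_r2 must be positive")
        if self.horizon < 1:
            raise InvalidParameterError("horizon T_H must be >= 1")

    def log_likelihood(self, r: float, x: np.ndarray) -> np.ndarray:
        z = np.asarray(x, dtype=float)[..., self.selector] - r
        return -0.5 * (_LOG_2PI + math.log(self.sigma_r2) + z * z / self.sigma_r2)


class ControlTransitionModel(abc.ABC):
    """Proposal dynamics of the control input within and into the horizon.

    Implementations must guarantee the input constraint by construction
    (clamping built into both methods).
    """

    @abc.abstractmethod
    def initialize(self, u_prev: float, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw N initial input particles around the previously applied input."""

    @abc.abstractmethod
    def propagate(self, u: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Advance input particles one horizon step (clamped random walk)."""

    def net_input(self, u: np.ndarray) -> np.ndarray:
        """Effective input fed to the system dynamics (adds injected current
        for the neuron model; identity by default)."""
        return u


def init_augmented(
    state_ens: ParticleEnsemble,
    u_prev: float,
    ctm: ControlTransitionModel,
    rng: np.random.Generator,
) -> AugmentedEnsemble:
    """Initial augmented ensemble: states and weights copied from the state
    PF, inputs drawn from the initial proposal, u-tilde = u-bar."""
    u0 = ctm.initialize(u_prev, state_ens.n, rng)
    return AugmentedEnsemble(
        tau=state_ens.t,
        x=state_ens.x.copy(),
        u=u0,
        u_init=u0.copy(),
        w=state_ens.w.copy(),
    )


def reweight_reference(aug: AugmentedEnsemble, r: float, ref: ReferenceModel) -> AugmentedEnsemble:
    """Multiply the augmented weights by the reference likelihood of ``r``."""
    with np.errstate(divide="ignore"):
        logw = np.log(aug.w)
    w = normalize_log_weights(logw + ref.log_likelihood(r, aug.x), t=f"horizon {aug.tau}")
    return AugmentedEnsemble(tau=aug.tau, x=aug.x, u=aug.u, u_init=aug.u_init, w=w)


def horizon_step(
    aug: AugmentedEnsemble,
    r_tau: float,
    model: StateSpaceModel,
    ctm: ControlTransitionModel,
    ref: ReferenceModel,
    theta: np.ndarray,
    cfg: PFConfig,
    rng: np.random.Generator,
) -> AugmentedEnsemble:
    """One adaptive PF step on the augmented ensemble against reference r_tau.

    Resample-if-needed with the same alpha as the state PF, propagate x-bar
    through the system model under the per-particle inputs, advance u-bar
    through the control transition, carry u-tilde through the ancestors, and
    reweight with the Gaussian reference likelihood.
    """
    n = aug.n
    resample = effective_sample_size(aug.w) <= cfg.alpha * n
    if resample:
        anc = multinomial_resample(aug.w, rng)
        log_w_pred = np.zeros(n)
    else:
        anc = np.arange(n, dtype=np.intp)
        with np.errstate(divide="ignore"):
            log_w_pred = np.log(aug.w)

    x_new = model.transition_sample(aug.x[anc], ctm.net_input(aug.u[anc]), theta, rng)
    u_new = ctm.propagate(aug.u[anc], rng)
    u_init = aug.u_init[anc]
    logw = log_w_pred + ref.log_likelihood(r_tau, x_new)
    w = normalize_log_weights(logw, t=f"horizon {aug.tau + 1}")
    return AugmentedEnsemble(tau=aug.tau + 1, x=x_new, u=u_new, u_init=u_init, w=w)


def extract_control(aug: AugmentedEnsemble) -> float:
    """Applied input: weighted mean of the preserved initial inputs,
    sum_i w-bar^(i) u-tilde^(i) — a convex combination, hence inside the
    constraint set.  The dot product is pinned to the convex hull of the
    u-tilde values, which floating-point summation can otherwise overshoot
    by a few ulps."""
    val = float(aug.w @ aug.u_init)
    return float(np.clip(val, aug.u_init.min(), aug.u_init.max()))


def mpc_control(
    state_ens: ParticleEnsemble,
    u_prev: float,
    reference_segment: np.ndarray,
    model: StateSpaceModel,
    ctm: ControlTransitionModel,
    ref: ReferenceModel,
    theta: np.ndarray,
    cfg: PFConfig,
    rng: np.random.Generator,
) -> float:
    """Solve one control-filtering problem and return the applied input.

    ``reference_segment`` holds the T_H + 1 reference values r_t .. r_{t+T_H}
    (pad by repeating the last value when a stored reference trajectory
    ends).  The first value reweights the initial augmented ensemble; each of
    the T_H horizon steps then consumes one subsequent value.
    """
    r = np.asarray(reference_segment, dtype=float).reshape(-1)
    if r.size != ref.horizon + 1:
        raise InvalidParameterError(
            f"reference segment must have T_H+1={ref.horizon + 1} values, got {r.size}"
        )
    aug = init_augmented(state_ens, u_prev, ctm, rng)
    aug = reweight_reference(aug, r[0], ref)
    for k in range(1, ref.horizon + 1):
        aug = horizon_step(aug, r[k], model, ctm, ref, theta, cfg, rng)
    return extract_control(aug)
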