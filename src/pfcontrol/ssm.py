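"""State-space model contract, particle ensembles, and a linear-Gaussian reference model.

A state-space model (SSM) couples a Markov system model
``x_t ~ p(x_t | x_{t-1}, u_{t-1}; theta)`` with an observation model
``y_t ~ p(y_t | x_t; theta)``.  Every concrete model in this package
(:class:`LinearGaussianModel`, the Lorenz plug-in, the Morris–Lecar plug-in)
implements the :class:`StateSpaceModel` contract: vectorized transition
sampling and density evaluation, observation log-likelihoods, an initial
distribution, and — for online EM — an additive sufficient-statistic
increment ``s~(x_{t-1}, x_t)`` together with the M-step maximizer map
``Lambda`` that turns averaged statistics into a parameter estimate.

All stochastic operations receive an explicit :class:`numpy.random.Generator`;
there is no hidden global RNG state.
"""

from __future__ import annotations

import abc
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PFControlError",
    "InvalidParameterError",
    "DegenerateWeightsError",
    "SingularStatisticsError",
    "StateSpaceModel",
    "ParticleEnsemble",
    "SuffStats",
    "LinearGaussianModel",
    "lg_transition_density",
    "kalman_filter",
    "rts_smoother",
]

_LOG_2PI = math.log(2.0 * math.pi)


class PFControlError(Exception):
    """Base class for errors raised by this package."""


class InvalidParameterError(PFControlError, ValueError):
    """A model or algorithm parameter violates its domain constraint."""


class DegenerateWeightsError(PFControlError, FloatingPointError):
    """All particle weights underflowed to zero (filter collapse)."""


class SingularStatisticsError(PFControlError, np.linalg.LinAlgError):
    """The quadratic part of the sufficient statistics is singular."""


@dataclass
class SuffStats:
    """Additive sufficient-statistic pair (A, b) feeding the M-step map.

    ``A`` is a square matrix (diagonal for the Lorenz model, a Gram matrix for
    Morris–Lecar) and ``b`` a vector of matching dimension.  The M-step
    maximizer is ``Lambda(A, b) = A^{-1} b`` (Lorenz) or ``-A^{-1} b``
    (Morris–Lecar); both are invariant under joint rescaling of (A, b).
    """

    A: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        k = self.b.shape[-1]
        if self.A.shape[-2:] != (k, k):
            raise InvalidParameterError(
                f"A-part shape {self.A.shape} does not match b-part shape {self.b.shape}"
            )

    def __mul__(self, c: float) -> "SuffStats":
        return SuffStats(self.A * c, self.b * c)

    __rmul__ = __mul__

    def __add__(self, other: "SuffStats") -> "SuffStats":
        return SuffStats(self.A + other.A, self.b + other.b)


@dataclass
class ParticleEnsemble:
    """Weighted particle approximation of a filtering distribution at one time.

    Attributes
    ----------
    t : int
        Discrete time index of the ensemble.
    x : (N, state_dim) ndarray
        Particle states.
    w : (N,) ndarray
        Normalized importance weights.
    ancestors : (N,) int ndarray
        Index of the time-(t-1) particle each particle descends from
        (0-based internally; serialized 1-based).
    enoch : (N,) int ndarray
        Lineage index back to the last backward-sampling event; the number of
        unique values measures ancestor diversity.
    resampled : bool
        Whether probabilistic resampling occurred when forming this ensemble.
    """

    t: int
    x: np.ndarray
    w: np.ndarray
    ancestors: np.ndarray
    enoch: np.ndarray
    resampled: bool = False

    def __post_init__(self) -> None:
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        self.w = np.asarray(self.w, dtype=float)
        self.ancestors = np.asarray(self.ancestors, dtype=np.intp)
        self.enoch = np.asarray(self.enoch, dtype=np.intp)
        self.validate()

    @property
    def n(self) -> int:
        return self.x.shape[0]

    def validate(self) -> None:
        n = self.n
        if self.w.shape != (n,):
            raise InvalidParameterError("weights shape does not match particle count")
        if np.any(self.w < 0):
            raise InvalidParameterError("weights must be nonnegative")
        if abs(self.w.sum() - 1.0) > 1e-12:
            raise InvalidParameterError("weights must sum to 1 within 1e-12")
        for name, idx in (("ancestors", self.ancestors), ("enoch", self.enoch)):
            if idx.shape != (n,) or idx.min(initial=0) < 0 or idx.max(initial=0) >= n:
                raise InvalidParameterError(f"{name} indices must lie in 0..N-1")


class StateSpaceModel(abc.ABC):
    """Abstract contract for a controlled state-space model.

    The ``u`` argument of the transition methods is the *effective input to
    the dynamics* — the control input itself for the Lorenz system, the net
    current (control + injected) for the Morris–Lecar neuron.  It may be a
    scalar (shared input) or an (N,) array (per-particle inputs inside an
    MPC horizon).
    """

    state_dim: int
    param_dim: int
    obs_dim: int

    @abc.abstractmethod
    def transition_sample(
        self, x_prev: np.ndarray, u: np.ndarray | float, theta: np.ndarray, rng: np.random.Generator
    ) -> np.ndarray:
        """Draw x_t for each row of ``x_prev`` from p(x_t | x_{t-1}, u; theta)."""

    @abc.abstractmethod
    def transition_logpdf(
        self, x_prev: np.ndarray, x: np.ndarray, u: np.ndarray | float, theta: np.ndarray
    ) -> np.ndarray:
        """Evaluate log p(x | x_prev, u; theta), broadcasting over leading axes."""

    @abc.abstractmethod
    def transition_logpdf_max(self, u: np.ndarray | float, theta: np.ndarray) -> float:
        """Upper bound of the transition log-density over x_prev for fixed x.

        For the Gaussian transitions shipped here this is the log of the
        normalizing constant (the density value at the mode), which is what
        the rejection-sampling backward kernel needs.
        """

    @abc.abstractmethod
    def observation_logpdf(self, y: np.ndarray, x: np.ndarray, theta: np.ndarray) -> np.ndarray:
        """Evaluate log p(y | x; theta) for each row of ``x``."""

    @abc.abstractmethod
    def initial_sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n particles from the initial distribution p0(x)."""

    @abc.abstractmethod
    def suffstat_increment(
        self, x_prev: np.ndarray, x_curr: np.ndarray, u_prev: np.ndarray | float
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per-transition statistic s~(x_{t-1}, x_t) given the applied input.

        Returns per-particle arrays ``(A, b)`` of shapes (N, k, k) and (N, k).
        """

    @abc.abstractmethod
    def lambda_map(self, stats: SuffStats) -> np.ndarray:
        """M-step maximizer Lambda(.) mapping averaged statistics to theta-hat."""

    def project_params(self, theta: np.ndarray) -> tuple[np.ndarray, bool]:
        """Project a parameter vector back into the physical domain.

        Returns the (possibly adjusted) vector and a flag saying whether the
        projection was active.  Default: identity.
        """
        return theta, False

    @property
    def suffstat_dim(self) -> int:
        """Dimension k of the (A, b) statistic pair."""
        return self.param_dim


# ---------------------------------------------------------------------------
# Linear-Gaussian reference model
# ---------------------------------------------------------------------------

def _gauss_logpdf(x: np.ndarray, mean: np.ndarray, var: float) -> np.ndarray:
    return -0.5 * (_LOG_2PI + math.log(var) + (x - mean) ** 2 / var)


def lg_transition_density(x_prev: float, x: float, a: float, b: float) -> float:
    """Gaussian transition density N(x | a*x_prev, b^2) of the scalar model.

    Raises
    ------
    InvalidParameterError
        If the noise scale ``b`` is not strictly positive.
    """
    if b <= 0:
        raise InvalidParameterError(f"state noise scale b must be positive, got {b}")
    return float(np.exp(_gauss_logpdf(np.asarray(x, dtype=float), a * x_prev, b * b)))


class LinearGaussianModel(StateSpaceModel):
    """Scalar linear-Gaussian SSM: x_t = a x_{t-1} + b z_t, y_t = c x_t + d eta_t.

    The unknown parameter exposed to the online EM machinery is the transition
    coefficient ``a`` (theta = [a]); the noise scales and observation gain are
    treated as known.  The additive statistic is
    s~ = (x_{t-1}^2, x_{t-1} x_t), whose ratio is the complete-data MLE of a.
    The control input is ignored (the model is autonomous); it exists so that
    the model can stand in for any :class:`StateSpaceModel` in tests.
    """

    state_dim = 1
    param_dim = 1
    obs_dim = 1

    def __init__(
        self,
        a: float = 0.9,
        b: float = 0.5,
        c: float = 1.0,
        d: float = 0.3,
        prior_mean: float = 0.0,
        prior_var: float = 1.0,
    ) -> None:
        if b <= 0 or d <= 0:
            raise InvalidParameterError("noise scales b and d must be positive")
        self.a, self.b, self.c, self.d = float(a), float(b), float(c), float(d)
        self.prior_mean, self.prior_var = float(prior_mean), float(prior_var)

    # -- transition -----------------------------------------------------
    def _a(self, theta: np.ndarray | None) -> float:
        return self.a if theta is None else float(np.asarray(theta).reshape(-1)[0])

    def transition_sample(self, x_prev, u, theta, rng):
        x_prev = np.atleast_2d(np.asarray(x_prev, dtype=float))
        mean = self._a(theta) * x_prev
        return mean + self.b * rng.standard_normal(x_prev.shape)

    def transition_logpdf(self, x_prev, x, u, theta):
        x_prev = np.asarray(x_prev, dtype=float)
        x = np.asarray(x, dtype=float)
        d2 = np.sum((x - self._a(theta) * x_prev) ** 2, axis=-1)
        return -0.5 * (_LOG_2PI + 2.0 * math.log(self.b) + d2 / self.b**2)

    def transition_logpdf_max(self, u, theta):
        return -0.5 * (_LOG_2PI + 2.0 * math.log(self.b))

    def observation_logpdf(self, y, x, theta):
        x = np.asarray(x, dtype=float)
        y = float(np.asarray(y).reshape(-1)[0])
        return _gauss_logpdf(self.c * x[..., 0], y, self.d**2)

    def initial_sample(self, n, rng):
        return (self.prior_mean + math.sqrt(self.prior_var) * rng.standard_normal((n, 1)))

    # -- online EM ------------------------------------------------------
    def suffstat_increment(self, x_prev, x_curr, u_prev):
        x_prev = np.atleast_2d(np.asarray(x_prev, dtype=float))
        x_curr = np.atleast_2d(np.asarray(x_curr, dtype=float))
        A = (x_prev[:, 0] ** 2).reshape(-1, 1, 1)
        b = (x_prev[:, 0] * x_curr[:, 0]).reshape(-1, 1)
        return A, b

    def lambda_map(self, stats: SuffStats) -> np.ndarray:
        A = float(stats.A.reshape(()))
        if A == 0.0 or not np.isfinite(A):
            raise SingularStatisticsError("A-part of the statistics is singular")
        return np.array([float(stats.b.reshape(())) / A])


# ---------------------------------------------------------------------------
# Exact-filter oracles for the linear-Gaussian model (test support)
# ---------------------------------------------------------------------------

def kalman_filter(
    observations: np.ndarray,
    model: LinearGaussianModel,
    prior_mean: float | None = None,
    prior_var: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact filtering means/variances for the scalar linear-Gaussian model.

    Follows the conjugate predict/update recursion; used as an independent
    oracle against the particle filter.  Returns empty arrays for an empty
    observation series.
    """
    a, b, c, d = model.a, model.b, model.c, model.d
    m = model.prior_mean if prior_mean is None else prior_mean
    v = model.prior_var if prior_var is None else prior_var
    obs = np.asarray(observations, dtype=float).reshape(-1)
    means = np.empty(obs.size)
    variances = np.empty(obs.size)
    for t, y in enumerate(obs):
        # predict
        m_pred = a * m
        v_pred = a * a * v + b * b
        # update
        s = c * c * v_pred + d * d
        k = v_pred * c / s
        m = m_pred + k * (y - c * m_pred)
        v = v_pred - k * c * v_pred
        means[t] = m
        variances[t] = v
    return means, variances


def rts_smoother(
    observations: np.ndarray, model: LinearGaussianModel
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rauch–Tung–Striebel smoother with lag-one smoothed covariances.

    Returns (smoothed means, smoothed variances, lag-one covariances) where
    ``lag_one[t] = Cov(x_t, x_{t-1} | y_{1:T})`` for t >= 1 (entry 0 unused,
    set to NaN).  Used by the exact smoothed-sufficient-statistic oracle.
    """
    a, b = model.a, model.b
    obs = np.asarray(observations, dtype=float).reshape(-1)
    T = obs.size
    mf, vf = kalman_filter(obs, model)
    # predicted variances v_{t|t-1}, with the prior at t=0
    m_prev = np.concatenate(([model.prior_mean], mf[:-1]))
    v_prev = np.concatenate(([model.prior_var], vf[:-1]))
    v_pred = a * a * v_prev + b * b

    ms = np.empty(T)
    vs = np.empty(T)
    ms[-1], vs[-1] = mf[-1], vf[-1]
    J = np.empty(T)  # J[t] = v_{t|t} a / v_{t+1|t}, gain from t+1 back to t
    for t in range(T - 2, -1, -1):
        J[t] = vf[t] * a / v_pred[t + 1]
        ms[t] = mf[t] + J[t] * (ms[t + 1] - a * mf[t])
        vs[t] = vf[t] + J[t] ** 2 * (vs[t + 1] - v_pred[t + 1])
    lag_one = np.full(T, np.nan)
    for t in range(1, T):
        Jm1 = vf[t - 1] * a / v_pred[t]
        lag_one[t] = Jm1 * vs[t]
    return ms, vs, lag_one
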