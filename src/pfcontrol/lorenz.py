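"""Lorenz-system plug-in: SSM, EM sufficient statistics, constrained control
transition, reference model, and the RK4 truth simulator.

The continuous-time Lorenz system

    dx/dt' = sigma (y - x)
    dy/dt' = r x - y - x z + u
    dz/dt' = x y - b z

is Euler-discretized with step dt into a Gaussian state-space model
x_{t+1} ~ N(x_t + f(x_t, u_t) dt, Sigma_x dt); observations are the full
state plus Gaussian noise.  The unknown parameter is theta = (sigma, r, b).
The control input acts only on the y-equation and is used to stabilize the
chaotic attractor onto the unstable fixed point
(sqrt(b(r-1)), sqrt(b(r-1)), r-1), which exists for r > 1 and is unstable
for r above the subcritical Hopf point r_H = sigma(sigma+b+3)/(sigma-b-1)
(~24.7368 for sigma=10, b=8/3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .mpc import ControlTransitionModel
from .ssm import InvalidParameterError, StateSpaceModel, SuffStats

__all__ = [
    "LorenzNoiseConfig",
    "LorenzControlConfig",
    "LorenzModel",
    "LorenzControlTransition",
    "lorenz_drift",
    "clamp",
    "fixed_point",
    "hopf_threshold",
    "hopf_threshold_numeric",
    "truth_step_rk4",
]

_LOG_2PI = math.log(2.0 * math.pi)
PARAM_FLOOR = 1e-6


def lorenz_drift(x: np.ndarray, u: np.ndarray | float, theta: np.ndarray) -> np.ndarray:
    """Drift f(x, u; theta) of the Lorenz system; broadcasts over particles.

    ``x`` has shape (..., 3); ``u`` is a scalar or an array broadcastable to
    the leading shape; returns an array shaped like ``x``.
    """
    x = np.asarray(x, dtype=float)
    sigma, r, b = np.asarray(theta, dtype=float)
    x1, x2, x3 = x[..., 0], x[..., 1], x[..., 2]
    return np.stack(
        [sigma * (x2 - x1), r * x1 - x2 - x1 * x3 + u, x1 * x2 - b * x3],
        axis=-1,
    )


def clamp(u: np.ndarray | float, u_lim: float) -> np.ndarray | float:
    """Saturation to [-u_lim, u_lim].

    Algebraically (|u + u_lim| - |u - u_lim|) / 2; computed as
    min(max(u, -u_lim), u_lim), which is the same function but keeps the
    bound exact in floating point (the absolute-value form can overshoot the
    limit by a few ulps through catastrophic cancellation).
    """
    if u_lim <= 0:
        raise InvalidParameterError("u_lim must be positive")
    return np.clip(u, -u_lim, u_lim)


def fixed_point(theta: np.ndarray) -> np.ndarray:
    """Nontrivial fixed point (+sqrt(b(r-1)), +sqrt(b(r-1)), r-1); needs r > 1."""
    sigma, r, b = np.asarray(theta, dtype=float)
    if r <= 1:
        raise InvalidParameterError("nontrivial fixed points require r > 1")
    s = math.sqrt(b * (r - 1.0))
    return np.array([s, s, r - 1.0])


def _jacobian_at_fixed_point(r: float, sigma: float, b: float) -> np.ndarray:
    xf, yf, zf = fixed_point(np.array([sigma, r, b]))
    return np.array(
        [
            [-sigma, sigma, 0.0],
            [r - zf, -1.0, -xf],
            [yf, xf, -b],
        ]
    )


def hopf_threshold(sigma: float, b: float) -> float:
    """Critical r of the subcritical Hopf bifurcation of the nontrivial fixed points.

    Closed form sigma (sigma + b + 3) / (sigma - b - 1), from the
    Routh–Hurwitz crossing condition of the Jacobian's characteristic
    polynomial; defined only when sigma - b - 1 > 0.
    """
    if sigma - b - 1.0 <= 0.0:
        raise InvalidParameterError("no Hopf bifurcation: need sigma - b - 1 > 0")
    return sigma * (sigma + b + 3.0) / (sigma - b - 1.0)


def hopf_threshold_numeric(sigma: float, b: float) -> float:
    """Hopf point located by root-finding on the Routh–Hurwitz condition.

    For the characteristic polynomial s^3 + a2 s^2 + a1 s + a0 of the
    Jacobian at the nontrivial fixed point, a purely imaginary eigenvalue
    pair crosses where h(r) = a2*a1 - a0 = 0; h is evaluated from the
    numerically computed polynomial coefficients and bracketed by brentq.
    Cross-checks the closed form independently of it.
    """
    if sigma - b - 1.0 <= 0.0:
        raise InvalidParameterError("no Hopf bifurcation: need sigma - b - 1 > 0")

    def hurwitz(r: float) -> float:
        J = _jacobian_at_fixed_point(r, sigma, b)
        c = np.poly(J)  # [1, a2, a1, a0]
        return c[1] * c[2] - c[3]

    lo, hi = 1.0 + 1e-9, 2.0
    while hurwitz(hi) > 0:
        hi *= 2.0
        if hi > 1e8:
            raise InvalidParameterError("failed to bracket the Hopf point")
    return float(brentq(hurwitz, lo, hi, xtol=1e-12, rtol=1e-14))


@dataclass
class LorenzNoiseConfig:
    """Discretization step and noise levels of the Lorenz SSM.

    ``sx`` are the system-noise variances (the transition covariance is
    diag(sx)*dt); ``sy`` the observation-noise variances; ``x0``/``sx0`` the
    initial-distribution mean and variances.
    """

    dt: float = 0.01
    sx: np.ndarray = field(default_factory=lambda: np.ones(3))
    sy: np.ndarray = field(default_factory=lambda: np.ones(3))
    x0: np.ndarray = field(default_factory=lambda: np.ones(3))
    sx0: np.ndarray = field(default_factory=lambda: np.full(3, 100.0))

    def __post_init__(self) -> None:
        self.sx = np.asarray(self.sx, dtype=float).reshape(3)
        self.sy = np.asarray(self.sy, dtype=float).reshape(3)
        self.x0 = np.asarray(self.x0, dtype=float).reshape(3)
        self.sx0 = np.asarray(self.sx0, dtype=float).reshape(3)
        if self.dt <= 0 or np.any(self.sx <= 0) or np.any(self.sy <= 0) or np.any(self.sx0 <= 0):
            raise InvalidParameterError("dt and all variances must be positive")


@dataclass
class LorenzControlConfig:
    """Input bound and proposal/reference variances of the Lorenz controller."""

    u_lim: float = 10.0
    sigma_u2: float = 1.0
    sigma_u0_2: float = 100.0
    sigma_r2: float = 1.0

    def __post_init__(self) -> None:
        if self.u_lim <= 0 or min(self.sigma_u2, self.sigma_u0_2, self.sigma_r2) <= 0:
            raise InvalidParameterError("u_lim and variances must be positive")


class LorenzModel(StateSpaceModel):
    """Gaussian SSM for the Lorenz system with theta = (sigma, r, b)."""

    state_dim = 3
    param_dim = 3
    obs_dim = 3

    def __init__(self, noise: LorenzNoiseConfig | None = None) -> None:
        self.noise = noise or LorenzNoiseConfig()
        n = self.noise
        self._trans_var = n.sx * n.dt
        self._log_norm_trans = -0.5 * (3 * _LOG_2PI + np.log(self._trans_var).sum())
        self._log_norm_obs = -0.5 * (3 * _LOG_2PI + np.log(n.sy).sum())

    def transition_mean(self, x_prev, u, theta):
        return np.asarray(x_prev, dtype=float) + lorenz_drift(x_prev, u, theta) * self.noise.dt

    def transition_sample(self, x_prev, u, theta, rng):
        mean = self.transition_mean(np.atleast_2d(x_prev), u, theta)
        return mean + np.sqrt(self._trans_var) * rng.standard_normal(mean.shape)

    def transition_logpdf(self, x_prev, x, u, theta):
        mean = self.transition_mean(x_prev, u, theta)
        d2 = np.sum((np.asarray(x, dtype=float) - mean) ** 2 / self._trans_var, axis=-1)
        return self._log_norm_trans - 0.5 * d2

    def transition_logpdf_max(self, u, theta):
        return float(self._log_norm_trans)

    def observation_logpdf(self, y, x, theta):
        y = np.asarray(y, dtype=float).reshape(3)
        d2 = np.sum((np.asarray(x, dtype=float) - y) ** 2 / self.noise.sy, axis=-1)
        return self._log_norm_obs - 0.5 * d2

    def initial_sample(self, n, rng):
        return self.noise.x0 + np.sqrt(self.noise.sx0) * rng.standard_normal((n, 3))

    def suffstat_increment(self, x_prev, x_curr, u_prev):
        """Per-transition (A~, b~) whose ratio is the complete-data MLE of theta.

        A~ = diag((y-x)^2/sx1, x^2/sx2, z^2/sx3) * dt and b~ couples each
        parameter's regressor with the corresponding state increment.
        """
        xp = np.atleast_2d(np.asarray(x_prev, dtype=float))
        xc = np.atleast_2d(np.asarray(x_curr, dtype=float))
        dt = self.noise.dt
        s1, s2, s3 = self.noise.sx
        x1, y1, z1 = xp[:, 0], xp[:, 1], xp[:, 2]
        n = xp.shape[0]
        u = np.broadcast_to(np.asarray(u_prev, dtype=float), (n,))

        diag = np.stack(
            [(y1 - x1) ** 2 / s1, x1**2 / s2, z1**2 / s3], axis=-1
        ) * dt
        A = np.zeros((n, 3, 3))
        idx = np.arange(3)
        A[:, idx, idx] = diag

        b = np.stack(
            [
                (y1 - x1) / s1 * (xc[:, 0] - x1),
                x1 / s2 * (xc[:, 1] - y1 + (y1 + x1 * z1 - u) * dt),
                -z1 / s3 * (xc[:, 2] - z1 - x1 * y1 * dt),
            ],
            axis=-1,
        )
        return A, b

    def lambda_map(self, stats: SuffStats) -> np.ndarray:
        """M-step maximizer Lambda(A, b) = A^{-1} b -> (sigma, r, b)."""
        return np.linalg.solve(stats.A, stats.b)

    def project_params(self, theta):
        theta = np.asarray(theta, dtype=float).copy()
        projected = bool(theta[0] < PARAM_FLOOR or theta[2] < PARAM_FLOOR)
        theta[0] = max(theta[0], PARAM_FLOOR)  # sigma > 0
        theta[2] = max(theta[2], PARAM_FLOOR)  # b > 0; r unconstrained
        return theta, projected


class LorenzControlTransition(ControlTransitionModel):
    """Clamped-random-walk proposal for the scalar Lorenz input."""

    def __init__(self, cfg: LorenzControlConfig) -> None:
        self.cfg = cfg

    def initialize(self, u_prev, n, rng):
        z = math.sqrt(self.cfg.sigma_u0_2) * rng.standard_normal(n)
        return clamp(u_prev + z, self.cfg.u_lim)

    def propagate(self, u, rng):
        z = math.sqrt(self.cfg.sigma_u2) * rng.standard_normal(u.shape)
        return clamp(u + z, self.cfg.u_lim)


def truth_step_rk4(
    x: np.ndarray,
    u: float,
    theta: np.ndarray,
    noise: LorenzNoiseConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Classical RK4 step of the deterministic drift (u held constant over
    the step) plus additive Gaussian noise with covariance Sigma_x * dt.

    Pass ``rng=None`` for the deterministic plant.
    """
    x = np.asarray(x, dtype=float)
    dt = noise.dt
    k1 = lorenz_drift(x, u, theta)
    k2 = lorenz_drift(x + 0.5 * dt * k1, u, theta)
    k3 = lorenz_drift(x + 0.5 * dt * k2, u, theta)
    k4 = lorenz_drift(x + dt * k3, u, theta)
    x_new = x + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    if rng is not None:
        x_new = x_new + np.sqrt(noise.sx * dt) * rng.standard_normal(3)
    return x_new
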