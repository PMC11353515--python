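"""Morris–Lecar neuron plug-in: SSM, EM sufficient statistics, net-current-
constrained control transition, and the Euler truth/reference simulator.

The two-variable conductance-based neuron model

    Cm dv/dt' = -gL (v - EL) - gCa m_inf(v) (v - ECa) - gK n (v - EK) + I
       dn/dt' = -phi cosh((v - V3)/(2 V4)) (n - n_inf(v))

couples the membrane potential v [mV] with the potassium gating variable n.
m_inf and n_inf are the tanh-sigmoid steady-state activations of the calcium
and potassium channels.  The net input current I = u + I_inj splits into the
controllable current u and the known injected current from other neurons.
The unknown parameter is theta = (gL, gCa, gK), the maximal conductances.

The shipped constants profile is the canonical "Homoclinic" set (Cm=20,
EL=-60, ECa=120, EK=-84, V1=-1.2, V2=18, V3=12, V4=17.4, phi=0.23; truth
conductances gL=2, gCa=4, gK=8), a regime in which periodic spiking and the
resting state are bistable so a controller can switch between them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .lorenz import clamp
from .mpc import ControlTransitionModel
from .ssm import InvalidParameterError, StateSpaceModel, SuffStats

__all__ = [
    "MLConstants",
    "HOMOCLINIC",
    "HOMOCLINIC_THETA",
    "MLNoiseConfig",
    "MLControlConfig",
    "MorrisLecarModel",
    "MLControlTransition",
    "ml_drift",
    "truth_step_euler",
    "generate_reference",
]

_LOG_2PI = math.log(2.0 * math.pi)
PARAM_FLOOR = 1e-6


@dataclass(frozen=True)
class MLConstants:
    """Fixed (non-estimated) constants of the Morris–Lecar model."""

    cm: float = 20.0
    e_l: float = -60.0
    e_ca: float = 120.0
    e_k: float = -84.0
    v1: float = -1.2
    v2: float = 18.0
    v3: float = 12.0
    v4: float = 17.4
    phi: float = 0.23

    def __post_init__(self) -> None:
        if self.cm <= 0 or self.v2 <= 0 or self.v4 <= 0:
            raise InvalidParameterError("Cm, V2 and V4 must be positive")

    def m_inf(self, v: np.ndarray) -> np.ndarray:
        return 0.5 * (1.0 + np.tanh((v - self.v1) / self.v2))

    def n_inf(self, v: np.ndarray) -> np.ndarray:
        return 0.5 * (1.0 + np.tanh((v - self.v3) / self.v4))

    def rate(self, v: np.ndarray) -> np.ndarray:
        """Relaxation rate 1/tau(v) = phi cosh((v - V3)/(2 V4)) of the gate."""
        return self.phi * np.cosh((v - self.v3) / (2.0 * self.v4))

    def v_ion(self, x: np.ndarray) -> np.ndarray:
        """Driving potentials (v-EL, m_inf(v)(v-ECa), n(v-EK)); shape (..., 3)."""
        x = np.asarray(x, dtype=float)
        v, n = x[..., 0], x[..., 1]
        return np.stack(
            [v - self.e_l, self.m_inf(v) * (v - self.e_ca), n * (v - self.e_k)],
            axis=-1,
        )


HOMOCLINIC = MLConstants()
HOMOCLINIC_THETA = np.array([2.0, 4.0, 8.0])  # (gL, gCa, gK)


def ml_drift(
    x: np.ndarray,
    i_net: np.ndarray | float,
    theta: np.ndarray,
    consts: MLConstants = HOMOCLINIC,
) -> np.ndarray:
    """Drift (dv, dn) of the Morris–Lecar model; broadcasts over particles."""
    x = np.asarray(x, dtype=float)
    g = np.asarray(theta, dtype=float)
    v, n = x[..., 0], x[..., 1]
    vion = consts.v_ion(x)
    dv = (-(vion @ g) + i_net) / consts.cm
    dn = -consts.rate(v) * (n - consts.n_inf(v))
    return np.stack([dv, dn], axis=-1)


@dataclass
class MLNoiseConfig:
    """Step size, noise variances and initial distribution of the neuron SSM.

    p0 = N(v | (2/3) EL, 10^2) x Uniform(n | 0, 1).
    """

    dt: float = 0.1
    sv2: float = 0.01  # 0.1^2
    sn2: float = 1e-6  # 0.001^2
    sy2: float = 0.01
    v0_mean: float = -40.0
    v0_var: float = 100.0

    def __post_init__(self) -> None:
        if self.dt <= 0 or min(self.sv2, self.sn2, self.sy2, self.v0_var) <= 0:
            raise InvalidParameterError("dt and variances must be positive")


@dataclass
class MLControlConfig:
    """Net-current bound and proposal/reference variances of the controller."""

    i_lim: float = 150.0
    sigma_i2: float = 1.0
    sigma_i0_2: float = 100.0
    sigma_r2: float = 0.01

    def __post_init__(self) -> None:
        if self.i_lim <= 0 or min(self.sigma_i2, self.sigma_i0_2, self.sigma_r2) <= 0:
            raise InvalidParameterError("i_lim and variances must be positive")


class MorrisLecarModel(StateSpaceModel):
    """Gaussian SSM for the Morris–Lecar neuron with theta = (gL, gCa, gK).

    The ``u`` argument of the transition methods is the *net* current
    I = u + I_inj; the closed loop and the MPC horizon add the injected
    current before calling in.
    """

    state_dim = 2
    param_dim = 3
    obs_dim = 1

    def __init__(
        self, consts: MLConstants = HOMOCLINIC, noise: MLNoiseConfig | None = None
    ) -> None:
        self.consts = consts
        self.noise = noise or MLNoiseConfig()
        nz = self.noise
        self._trans_var = np.array([nz.sv2 * nz.dt, nz.sn2 * nz.dt])
        self._log_norm_trans = -0.5 * (2 * _LOG_2PI + np.log(self._trans_var).sum())
        self._log_norm_obs = -0.5 * (_LOG_2PI + math.log(nz.sy2))

    def transition_mean(self, x_prev, i_net, theta):
        x_prev = np.asarray(x_prev, dtype=float)
        return x_prev + ml_drift(x_prev, i_net, theta, self.consts) * self.noise.dt

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
        y = float(np.asarray(y).reshape(-1)[0])
        d = np.asarray(x, dtype=float)[..., 0] - y
        return self._log_norm_obs - 0.5 * d * d / self.noise.sy2

    def initial_sample(self, n, rng):
        v = self.noise.v0_mean + math.sqrt(self.noise.v0_var) * rng.standard_normal(n)
        gate = rng.random(n)
        return np.stack([v, gate], axis=-1)

    def suffstat_increment(self, x_prev, x_curr, u_prev):
        """Per-transition (A~, b~): A~ = (dt/Cm)^2 V_ion V_ion^T (rank-1 PSD)
        and b~ = (dt/Cm)(v_t - v_{t-1} - (dt/Cm) I_{t-1}) V_ion, where
        ``u_prev`` is the net current applied over the transition."""
        xp = np.atleast_2d(np.asarray(x_prev, dtype=float))
        xc = np.atleast_2d(np.asarray(x_curr, dtype=float))
        n = xp.shape[0]
        i_net = np.broadcast_to(np.asarray(u_prev, dtype=float), (n,))
        ratio = self.noise.dt / self.consts.cm
        vion = self.consts.v_ion(xp)  # (n, 3)
        A = ratio**2 * np.einsum("ij,ik->ijk", vion, vion)
        dv = xc[:, 0] - xp[:, 0] - ratio * i_net
        b = ratio * dv[:, None] * vion
        return A, b

    def lambda_map(self, stats: SuffStats) -> np.ndarray:
        """M-step maximizer Lambda(A, b) = -A^{-1} b -> (gL, gCa, gK)."""
        return -np.linalg.solve(stats.A, stats.b)

    def project_params(self, theta):
        theta = np.asarray(theta, dtype=float).copy()
        projected = bool(np.any(theta < PARAM_FLOOR))
        np.maximum(theta, PARAM_FLOOR, out=theta)
        return theta, projected


class MLControlTransition(ControlTransitionModel):
    """Clamped-random-walk proposal on the *net* current, shifted back to u.

    The constraint |u + I_inj| <= I_lim is enforced by clamping the net
    current; the injected-current prediction is frozen at the value observed
    at the decision time t for the whole horizon.
    """

    def __init__(self, cfg: MLControlConfig, i_inj: float = 0.0) -> None:
        self.cfg = cfg
        self.i_inj = float(i_inj)

    def initialize(self, u_prev, n, rng):
        z = math.sqrt(self.cfg.sigma_i0_2) * rng.standard_normal(n)
        return clamp(u_prev + self.i_inj + z, self.cfg.i_lim) - self.i_inj

    def propagate(self, u, rng):
        z = math.sqrt(self.cfg.sigma_i2) * rng.standard_normal(u.shape)
        return clamp(u + self.i_inj + z, self.cfg.i_lim) - self.i_inj

    def net_input(self, u):
        return u + self.i_inj


def truth_step_euler(
    x: np.ndarray,
    i_net: float,
    theta: np.ndarray,
    consts: MLConstants,
    noise: MLNoiseConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Euler step of the true neuron dynamics plus Gaussian system noise.

    The gate n is not clipped; the relaxation toward n_inf in (0, 1) keeps it
    near the unit interval on its own.  Pass ``rng=None`` for the
    deterministic plant.
    """
    x = np.asarray(x, dtype=float)
    x_new = x + ml_drift(x, i_net, theta, consts) * noise.dt
    if rng is not None:
        std = np.sqrt(np.array([noise.sv2, noise.sn2]) * noise.dt)
        x_new = x_new + std * rng.standard_normal(2)
    return x_new


def generate_reference(
    consts: MLConstants,
    theta_true: np.ndarray,
    schedule: list[tuple[float, float]],
    noise: MLNoiseConfig | None = None,
    x0: np.ndarray | None = None,
) -> np.ndarray:
    """Reference v-trace from the deterministic true model under a drive plan.

    ``schedule`` is a list of (duration in continuous time, drive current)
    segments; segments must cover the full run.  Returns the membrane
    potential at steps t = 1 .. T where T = total duration / dt.

    The default drive pair used by the shipped experiment (spiking ~45,
    rest ~5) sits inside the bistable range of the Homoclinic profile, so
    the trace alternates between periodic firing and rest.
    """
    noise = noise or MLNoiseConfig()
    dt = noise.dt
    if not schedule:
        raise InvalidParameterError("reference schedule is empty")
    if x0 is None:
        v0 = consts.e_l
        x = np.array([v0, float(consts.n_inf(np.asarray(v0)))])
    else:
        x = np.asarray(x0, dtype=float).copy()
    steps_per_seg = [int(round(dur / dt)) for dur, _ in schedule]
    total = sum(steps_per_seg)
    ref = np.empty(total)
    t = 0
    for (dur, drive), m in zip(schedule, steps_per_seg):
        for _ in range(m):
            x = truth_step_euler(x, drive, theta_true, consts, noise, rng=None)
            ref[t] = x[0]
            t += 1
    return ref
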