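"""Closed-loop orchestration: truth plant -> particle filter -> online EM ->
PF-MPC, with configuration, seeding, trace collection and CSV/JSON output.

Per step t: (1) the truth plant advances under the previously applied input
and emits a noisy observation; (2) the state PF assimilates it using
theta-hat_{t-1}; (3) the AdaSmooth online EM updates kappa/Enoch bookkeeping
and produces theta-hat_t; (4) if control is enabled, PF-MPC solves the
control-filtering problem over the horizon with theta-hat_t frozen and
returns the applied input.  Four independent child RNG streams (truth, state
PF, EM backward sampling, control PF) are spawned from the root seed, so
disabling one module never perturbs the draws of another.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd
import yaml

from . import lorenz as lz
from . import morris_lecar as ml
from .filtering import PFConfig, effective_sample_size, filtering_mean, init_particles, pf_step
from .mpc import ReferenceModel, mpc_control
from .smoothing import OnlineEM, make_decay_schedule
from .ssm import InvalidParameterError

__all__ = [
    "ExperimentConfig",
    "RunResult",
    "lorenz_config",
    "morris_lecar_config",
    "run_closed_loop",
    "load_config",
    "save_config",
    "write_traces",
]


@dataclass
class ExperimentConfig:
    """Full closed-loop experiment specification.

    ``control_on`` is the first discrete step at which the controller output
    is applied (steps before it use u = 0); ``steps`` maps to continuous
    time t' = steps * dt.  ``noise``/``control``/``reference`` hold the
    model-specific keyword blocks documented in :mod:`pfcontrol.lorenz` and
    :mod:`pfcontrol.morris_lecar`.
    """

    model: str
    theta_true: list[float]
    theta0: list[float]
    n: int = 1000
    alpha: float = 0.8
    beta: float = 0.7
    gamma_exponent: float = 1.0
    burn_in: int = 100
    horizon: int = 10
    steps: int = 3000
    control_on: int = 1
    control_enabled: bool = True
    deterministic_plant: bool = False
    seed: int = 0
    noise: dict[str, Any] = field(default_factory=dict)
    control: dict[str, Any] = field(default_factory=dict)
    reference: dict[str, Any] = field(default_factory=dict)
    x0_true: list[float] | None = None
    i_inj: list[float] | None = None

    def __post_init__(self) -> None:
        if self.model not in ("lorenz", "morris_lecar"):
            raise InvalidParameterError(f"unknown model '{self.model}'")
        if self.steps <= self.burn_in:
            raise InvalidParameterError("run length must exceed the EM burn-in")


def lorenz_config(**overrides: Any) -> ExperimentConfig:
    """Default chaotic-stabilization experiment: truth (10, 28, 8/3), dt=0.01,
    N=1000, alpha=0.8, beta=0.7, gamma_t=1/t, burn-in 100, horizon 10,
    u_lim=10, control enabled from t'=5, run until t'=30."""
    base = dict(
        model="lorenz",
        theta_true=[10.0, 28.0, 8.0 / 3.0],
        theta0=[5.0, 20.0, 1.5],
        burn_in=100,
        steps=3000,
        control_on=500,
    )
    base.update(overrides)
    return ExperimentConfig(**base)


def morris_lecar_config(**overrides: Any) -> ExperimentConfig:
    """Default neuron trajectory-control experiment: Homoclinic truth
    (2, 4, 8), dt=0.1, N=1000, burn-in 1000, horizon 10, I_lim=150, reference
    alternating spiking (drive 45) and rest (drive 5) every t'=250, run until
    t'=1000."""
    base = dict(
        model="morris_lecar",
        theta_true=[2.0, 4.0, 8.0],
        theta0=[1.0, 2.0, 4.0],
        burn_in=1000,
        steps=10000,
        control_on=1,
        reference={"schedule": [[250.0, 45.0], [250.0, 5.0], [250.0, 45.0], [250.0, 5.0]]},
    )
    base.update(overrides)
    return ExperimentConfig(**base)


@dataclass
class RunResult:
    """Closed-loop traces, all sharing the discrete time axis t = 1..steps."""

    states: pd.DataFrame
    params: pd.DataFrame
    control: pd.DataFrame
    final_theta: np.ndarray
    summary: dict[str, Any]


class _Problem:
    """Model-specific closed-loop plumbing resolved from an ExperimentConfig."""

    def __init__(self, cfg: ExperimentConfig):
        self.cfg = cfg
        theta_true = np.asarray(cfg.theta_true, dtype=float)
        if cfg.model == "lorenz":
            self.noise = lz.LorenzNoiseConfig(**cfg.noise)
            self.model = lz.LorenzModel(self.noise)
            self.ctrl = lz.LorenzControlConfig(**cfg.control)
            y_f = cfg.reference.get("y_f")
            if y_f is None:
                y_f = float(lz.fixed_point(theta_true)[1])
            self.ref_values = np.full(cfg.steps + cfg.horizon + 2, y_f)
            self.ref_model = ReferenceModel(selector=1, sigma_r2=self.ctrl.sigma_r2,
                                            horizon=cfg.horizon)
            self.x0_true = (np.asarray(cfg.x0_true, dtype=float)
                            if cfg.x0_true is not None else self.noise.x0.copy())
            self.i_inj = np.zeros(cfg.steps + 1)
            self.limit = self.ctrl.u_lim
            self.state_cols = ["x", "y", "z"]
            self.obs_cols = ["y_obs_x", "y_obs_y", "y_obs_z"]
        else:
            consts_kwargs = cfg.reference.get("constants", {})
            self.consts = ml.MLConstants(**consts_kwargs) if consts_kwargs else ml.HOMOCLINIC
            self.noise = ml.MLNoiseConfig(**cfg.noise)
            self.model = ml.MorrisLecarModel(self.consts, self.noise)
            self.ctrl = ml.MLControlConfig(**cfg.control)
            schedule = [tuple(seg) for seg in cfg.reference.get(
                "schedule", [[250.0, 45.0], [250.0, 5.0], [250.0, 45.0], [250.0, 5.0]])]
            ref = ml.generate_reference(self.consts, theta_true, schedule, self.noise)
            need = cfg.steps + cfg.horizon + 2
            if ref.size < need:  # hold the last value when the stored reference ends
                ref = np.concatenate([ref, np.full(need - ref.size, ref[-1])])
            # ref[k] is r at discrete time k+1; prepend placeholder for t=0
            self.ref_values = np.concatenate([[ref[0]], ref])[:need]
            self.ref_model = ReferenceModel(selector=0, sigma_r2=self.ctrl.sigma_r2,
                                            horizon=cfg.horizon)
            if cfg.x0_true is not None:
                self.x0_true = np.asarray(cfg.x0_true, dtype=float)
            else:
                v0 = self.noise.v0_mean
                self.x0_true = np.array([v0, float(self.consts.n_inf(np.asarray(v0)))])
            if cfg.i_inj is not None:
                inj = np.asarray(cfg.i_inj, dtype=float).reshape(-1)
                if inj.size < cfg.steps + 1:
                    raise InvalidParameterError("i_inj series shorter than the run")
                self.i_inj = inj
            else:
                self.i_inj = np.zeros(cfg.steps + 1)
            self.limit = self.ctrl.i_lim
            self.state_cols = ["v", "n"]
            self.obs_cols = ["y_obs"]
        self.theta_true = theta_true

    @property
    def dt(self) -> float:
        return self.noise.dt

    def truth_step(self, x, u_applied, t, rng):
        if self.cfg.model == "lorenz":
            return lz.truth_step_rk4(x, u_applied, self.theta_true, self.noise, rng)
        i_net = u_applied + self.i_inj[t - 1]
        return ml.truth_step_euler(x, i_net, self.theta_true, self.consts, self.noise, rng)

    def observe(self, x_true, rng):
        if self.cfg.model == "lorenz":
            return x_true + np.sqrt(self.noise.sy) * rng.standard_normal(3)
        return np.array([x_true[0] + np.sqrt(self.noise.sy2) * rng.standard_normal()])

    def effective_input(self, u_applied: float, t: int) -> float:
        """Input fed to the SSM transition over step t-1 -> t (net current
        for the neuron model, the control input itself for Lorenz)."""
        if self.cfg.model == "lorenz":
            return u_applied
        return u_applied + self.i_inj[t - 1]

    def make_ctm(self, t: int):
        if self.cfg.model == "lorenz":
            return lz.LorenzControlTransition(self.ctrl)
        return ml.MLControlTransition(self.ctrl, i_inj=self.i_inj[t])


def run_closed_loop(cfg: ExperimentConfig) -> RunResult:
    """Run the full estimation-and-control loop and collect traces."""
    prob = _Problem(cfg)
    ss = np.random.SeedSequence(cfg.seed)
    rng_truth, rng_pf, rng_em, rng_ctrl = (np.random.default_rng(s) for s in ss.spawn(4))
    truth_rng = None if cfg.deterministic_plant else rng_truth

    pf_cfg = PFConfig(n=cfg.n, alpha=cfg.alpha)
    ens = init_particles(prob.model, pf_cfg, rng_pf)
    em = OnlineEM(
        prob.model,
        cfg.n,
        np.asarray(cfg.theta0, dtype=float),
        beta=cfg.beta,
        gamma=make_decay_schedule(cfg.gamma_exponent),
        burn_in=cfg.burn_in,
    )

    x_true = prob.x0_true.copy()
    u_applied = 0.0
    rows_s, rows_p, rows_c = [], [], []
    violations = 0

    for t in range(1, cfg.steps + 1):
        x_true = prob.truth_step(x_true, u_applied, t, truth_rng)
        y_t = prob.observe(x_true, rng_truth)
        eff_prev = prob.effective_input(u_applied, t)
        prev = ens
        ens = pf_step(prev, y_t, eff_prev, prob.model, em.theta, pf_cfg, rng_pf)
        theta = em.step(prev, ens, eff_prev, rng_em)

        if cfg.control_enabled and t >= cfg.control_on:
            seg = prob.ref_values[t : t + cfg.horizon + 1]
            u_applied = mpc_control(
                ens, u_applied, seg, prob.model, prob.make_ctm(t), prob.ref_model,
                theta, pf_cfg, rng_ctrl,
            )
        else:
            u_applied = 0.0

        est = filtering_mean(ens)
        net = prob.effective_input(u_applied, t + 1)
        if abs(net) > prob.limit + 1e-9:
            violations += 1

        row = {"t": t, "t_prime": t * prob.dt}
        row.update({f"{c}_true": x_true[k] for k, c in enumerate(prob.state_cols)})
        row.update({f"{c}_est": est[k] for k, c in enumerate(prob.state_cols)})
        row.update({c: y_t[k] for k, c in enumerate(prob.obs_cols)})
        if cfg.model == "morris_lecar":
            row["r"] = prob.ref_values[t]
        rows_s.append(row)

        prow = {"t": t, "t_prime": t * prob.dt}
        names = ("sigma", "r", "b") if cfg.model == "lorenz" else ("gL", "gCa", "gK")
        prow.update({nm: theta[k] for k, nm in enumerate(names)})
        prow.update(
            ess=effective_sample_size(ens.w),
            diversity=em.diversity,
            resampled=ens.resampled,
            backward=em.backward_sampled,
        )
        rows_p.append(prow)

        crow = {"t": t, "t_prime": t * prob.dt, "u": u_applied, "limit": prob.limit}
        if cfg.model == "morris_lecar":
            crow["i_inj"] = prob.i_inj[t]
            crow["net"] = u_applied + prob.i_inj[t]
        rows_c.append(crow)

    states = pd.DataFrame(rows_s)
    params = pd.DataFrame(rows_p)
    control = pd.DataFrame(rows_c)
    summary = {
        "model": cfg.model,
        "steps": cfg.steps,
        "final_theta": [float(v) for v in em.theta],
        "theta_true": [float(v) for v in prob.theta_true],
        "constraint_violations": violations,
        "seed": cfg.seed,
    }
    return RunResult(states, params, control, em.theta.copy(), summary)


def run_estimation(cfg: ExperimentConfig, observations: np.ndarray) -> pd.DataFrame:
    """PF + online EM on a supplied observation series with no control.

    ``observations`` has one row per step (obs_dim columns).  Returns the
    parameter trace with filter diagnostics.
    """
    prob = _Problem(cfg)
    ss = np.random.SeedSequence(cfg.seed)
    _, rng_pf, rng_em, _ = (np.random.default_rng(s) for s in ss.spawn(4))
    pf_cfg = PFConfig(n=cfg.n, alpha=cfg.alpha)
    ens = init_particles(prob.model, pf_cfg, rng_pf)
    em = OnlineEM(
        prob.model, cfg.n, np.asarray(cfg.theta0, dtype=float),
        beta=cfg.beta, gamma=make_decay_schedule(cfg.gamma_exponent), burn_in=cfg.burn_in,
    )
    obs = np.atleast_2d(np.asarray(observations, dtype=float))
    names = ("sigma", "r", "b") if cfg.model == "lorenz" else ("gL", "gCa", "gK")
    rows = []
    for t in range(1, obs.shape[0] + 1):
        prev = ens
        ens = pf_step(prev, obs[t - 1], prob.effective_input(0.0, t), prob.model,
                      em.theta, pf_cfg, rng_pf)
        theta = em.step(prev, ens, prob.effective_input(0.0, t), rng_em)
        est = filtering_mean(ens)
        row = {"t": t, "t_prime": t * prob.dt}
        row.update({nm: theta[k] for k, nm in enumerate(names)})
        row.update({f"{c}_est": est[k] for k, c in enumerate(prob.state_cols)})
        row.update(ess=effective_sample_size(ens.w), diversity=em.diversity,
                   backward=em.backward_sampled)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Config and trace I/O
# ---------------------------------------------------------------------------

def save_config(cfg: ExperimentConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=False))


def load_config(path: str | Path) -> ExperimentConfig:
    """Load a YAML experiment config; unknown or missing keys raise errors
    naming the offending key."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise InvalidParameterError(f"config file {path} does not hold a mapping")
    known = {f.name for f in dataclasses.fields(ExperimentConfig)}
    unknown = set(raw) - known
    if unknown:
        raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
    required = {"model", "theta_true", "theta0"}
    missing = required - set(raw)
    if missing:
        raise InvalidParameterError(f"missing required config keys: {sorted(missing)}")
    return ExperimentConfig(**raw)


def write_traces(result: RunResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.states.to_csv(out / "states.csv", index=False)
    result.params.to_csv(out / "params.csv", index=False)
    result.control.to_csv(out / "control.csv", index=False)
    (out / "summary.json").write_text(json.dumps(result.summary, indent=2))
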