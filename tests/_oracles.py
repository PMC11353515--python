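"""Independent oracles used by the test suite.

These deliberately avoid the package's own smoothing/filtering code paths:
brute-force quadrature for exact filtering, an O(N^2) forward-filtering
backward-smoothing pass for smoothed additive functionals, and closed-form
smoothed sufficient statistics from the RTS recursion.
"""

import numpy as np


def grid_filter_lg(observations, model, grid=None):
    """Exact filtering of the scalar LG model by numerical integration on a grid."""
    if grid is None:
        grid = np.linspace(-15, 15, 4001)
    dx = grid[1] - grid[0]
    a, b, c, d = model.a, model.b, model.c, model.d
    prior = np.exp(-0.5 * (grid - model.prior_mean) ** 2 / model.prior_var)
    prior /= prior.sum() * dx
    trans = np.exp(-0.5 * (grid[:, None] - a * grid[None, :]) ** 2 / b**2)  # [x_t, x_{t-1}]
    trans /= trans.sum(axis=0, keepdims=True) * dx
    means, variances = [], []
    p = prior
    for y in np.asarray(observations, dtype=float).reshape(-1):
        pred = trans @ p * dx
        lik = np.exp(-0.5 * (y - c * grid) ** 2 / d**2)
        post = pred * lik
        post /= post.sum() * dx
        m = np.sum(grid * post) * dx
        v = np.sum((grid - m) ** 2 * post) * dx
        means.append(m)
        variances.append(v)
        p = post
    return np.array(means), np.array(variances)


def ffbsm_additive(ensembles, model, theta, suffstat, u=0.0):
    """Exact O(N^2) particle smoother for an additive functional.

    ``ensembles`` is the list of particle ensembles produced by the forward
    filter (index 0 at t=0).  ``suffstat(x_prev, x_curr)`` maps (N, d) pairs
    to per-pair statistic vectors.  Implements the backward-statistic
    recursion T_t^(i) = sum_l beta_t(i,l) [T_{t-1}^(l) + s(x_{t-1}^(l),
    x_t^(i))] with beta the normalized backward kernel, and returns
    sum_i w_T^(i) T_T^(i).
    """
    prev = ensembles[0]
    n = prev.n
    probe = suffstat(prev.x[:1], prev.x[:1])
    stat_dim = probe.shape[-1]
    T = np.zeros((n, stat_dim))
    for k in range(1, len(ensembles)):
        curr = ensembles[k]
        with np.errstate(divide="ignore"):
            logw = np.log(prev.w)
        logk = logw[None, :] + model.transition_logpdf(
            prev.x[None, :, :], curr.x[:, None, :], u, theta
        )
        m = logk.max(axis=1, keepdims=True)
        beta = np.exp(logk - m)
        beta /= beta.sum(axis=1, keepdims=True)
        # s[i, l, :] = s(x_{t-1}^(l), x_t^(i))
        s = np.stack(
            [suffstat(prev.x, np.repeat(curr.x[i : i + 1], n, axis=0)) for i in range(n)]
        )
        T = np.einsum("il,ilk->ik", beta, T[None, :, :] + s)
        prev = curr
    return ensembles[-1].w @ T


def lg_pair_suffstat(x_prev, x_curr):
    """(x_{t-1}^2, x_{t-1} x_t) for the scalar LG model, shape (N, 2)."""
    return np.stack([x_prev[:, 0] ** 2, x_prev[:, 0] * x_curr[:, 0]], axis=-1)


def rts_smoothed_suffstats(observations, model):
    """Closed-form smoothed (sum E[x_{t-1}^2], sum E[x_{t-1} x_t]) over
    tau = 1..T including the (x_0, x_1) pair with x_0 from the prior."""
    from pfcontrol.ssm import rts_smoother

    ms, vs, lag1 = rts_smoother(observations, model)
    a, b = model.a, model.b
    v_pred1 = a * a * model.prior_var + b * b
    J0 = model.prior_var * a / v_pred1
    m0 = model.prior_mean + J0 * (ms[0] - a * model.prior_mean)
    v0 = model.prior_var + J0**2 * (vs[0] - v_pred1)
    m_full = np.concatenate([[m0], ms])
    v_full = np.concatenate([[v0], vs])
    lag_full = np.concatenate([[J0 * vs[0]], lag1[1:]])
    S_A = float(np.sum(v_full[:-1] + m_full[:-1] ** 2))
    S_b = float(np.sum(lag_full + m_full[:-1] * m_full[1:]))
    return S_A, S_b
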