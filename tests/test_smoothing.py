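"""AdaSmooth online EM: decay schedule, Enoch bookkeeping, backward ancestor
sampling, the kappa recursion, and M-step behavior."""

import numpy as np
import pytest
from scipy import stats

from pfcontrol.filtering import PFConfig, init_particles, pf_step
from pfcontrol.smoothing import (
    OnlineEM,
    SmoothingState,
    ancestor_diversity,
    backward_ancestor_sample,
    backward_ancestor_sample_all,
    decay_rate,
    em_update,
    smoothed_statistic,
    update_enoch,
    update_kappa,
)
from pfcontrol.ssm import (
    InvalidParameterError,
    LinearGaussianModel,
    ParticleEnsemble,
    SuffStats,
)

from conftest import make_lg_observations


def ensemble(x, w=None, ancestors=None, t=1, resampled=False):
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == 1 and x.shape[1] > 1:
        x = x.T
    n = x.shape[0]
    w = np.full(n, 1 / n) if w is None else np.asarray(w, dtype=float)
    anc = np.arange(n) if ancestors is None else np.asarray(ancestors)
    return ParticleEnsemble(t=t, x=x, w=w, ancestors=anc, enoch=np.arange(n), resampled=resampled)


class TestDecayRate:
    @pytest.mark.parametrize("t, expected", [(1, 1.0), (2, 0.5), (100, 0.01)])
    def test_default_schedule(self, t, expected):
        assert decay_rate(t) == pytest.approx(expected)

    def test_alternative_exponent(self):
        assert decay_rate(16, exponent=0.75) == pytest.approx(16 ** -0.75)

    def test_domain_errors(self):
        with pytest.raises(InvalidParameterError):
            decay_rate(0)
        with pytest.raises(InvalidParameterError):
            decay_rate(5, exponent=0.4)  # sum of squares would diverge


class TestEnoch:
    def test_reset_after_backward_sampling(self):
        out = update_enoch(np.array([4, 4, 4, 4, 4]), np.zeros(5, int), True)
        np.testing.assert_array_equal(out, np.arange(5))

    def test_hand_composition(self):
        out = update_enoch(np.array([0, 0, 2]), np.array([2, 2, 2]), False)
        np.testing.assert_array_equal(out, [2, 2, 2])

    def test_identity_ancestors_leave_unchanged(self):
        prev = np.array([3, 1, 1, 0])
        out = update_enoch(prev, np.arange(4), False)
        np.testing.assert_array_equal(out, prev)

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidParameterError):
            update_enoch(np.array([0, 5]), np.arange(2), False)

    @pytest.mark.parametrize(
        "enoch, expected", [([0, 1, 2, 3], 4), ([6, 6, 6, 6], 1), ([0, 0, 1, 4], 3)]
    )
    def test_diversity_counts(self, enoch, expected):
        assert ancestor_diversity(np.array(enoch)) == expected

    def test_diversity_non_increasing_between_backward_events(self, rng):
        # Enoch composition can only merge lineages.
        n = 64
        enoch = np.arange(n)
        last = n
        for _ in range(30):
            anc = rng.integers(0, n, size=n)
            enoch = update_enoch(enoch, anc, False)
            d = ancestor_diversity(enoch)
            assert d <= last
            last = d


class TestBackwardSampling:
    def test_single_particle(self, rng):
        model = LinearGaussianModel()
        prev = ensemble([[0.0]])
        b = backward_ancestor_sample(prev, np.array([0.1]), 0.0, model, None, rng)
        assert b == 0

    def test_flat_kernel_reduces_to_filter_weights(self, rng):
        # With a transition density that is constant in x_{t-1} (huge noise
        # scale), the backward law collapses to the filter weights.
        model = LinearGaussianModel(a=0.0, b=1e6)
        n = 5
        w = np.array([0.4, 0.3, 0.15, 0.1, 0.05])
        prev = ensemble(np.zeros((n, 1)), w=w)
        counts = np.zeros(n)
        draws = 10_000
        for _ in range(draws):
            counts[backward_ancestor_sample(prev, np.array([0.0]), 0.0, model, None, rng)] += 1
        chi2 = np.sum((counts - draws * w) ** 2 / (draws * w))
        assert stats.chi2.sf(chi2, df=n - 1) > 0.01

    def test_rejection_and_exact_paths_agree(self, rng):
        # Two-sample chi-square between the rejection sampler and the exact
        # categorical fallback on a small LG case.
        model = LinearGaussianModel(a=0.9, b=0.5)
        n = 10
        x_prev = np.linspace(-1, 1, n).reshape(-1, 1)
        w = rng.random(n)
        w /= w.sum()
        prev = ensemble(x_prev, w=w)
        x_t = np.array([0.3])
        draws = 10_000
        rej = np.zeros(n)
        exact = np.zeros(n)
        for _ in range(draws):
            rej[backward_ancestor_sample(prev, x_t, 0.0, model, None, rng)] += 1
            exact[backward_ancestor_sample(prev, x_t, 0.0, model, None, rng, max_trials=0)] += 1
        tot = rej + exact
        keep = tot > 5
        chi2 = np.sum((rej[keep] - exact[keep]) ** 2 / (rej[keep] + exact[keep]))
        assert stats.chi2.sf(chi2, df=keep.sum() - 1) > 0.01

    def test_vectorized_matches_target_law(self):
        rng = np.random.default_rng(2024)
        model = LinearGaussianModel(a=0.9, b=0.5)
        n = 8
        x_prev = np.linspace(-1, 1, n).reshape(-1, 1)
        w = np.full(n, 1 / n)
        prev = ensemble(x_prev, w=w)
        x_t = np.full((n, 1), 0.25)
        curr = ensemble(x_t, t=2)
        logk = model.transition_logpdf(prev.x, x_t[:1], 0.0, None) + np.log(w)
        target = np.exp(logk - logk.max())
        target /= target.sum()
        counts = np.zeros(n)
        for _ in range(5000):
            b = backward_ancestor_sample_all(prev, curr, 0.0, model, None, rng)
            counts += np.bincount(b, minlength=n)
        tot = counts.sum()
        chi2 = np.sum((counts - tot * target) ** 2 / (tot * target))
        assert stats.chi2.sf(chi2, df=n - 1) > 0.001


class TestKappaRecursion:
    def setup_method(self):
        self.model = LinearGaussianModel()
        self.n = 6

    def make_state(self, gamma_value, beta=0.0, rng=None):
        r = rng or np.random.default_rng(0)
        st = SmoothingState.initial(self.n, 1, beta=beta, gamma=lambda t: gamma_value)
        st.kappa_A = r.standard_normal((self.n, 1, 1))
        st.kappa_b = r.standard_normal((self.n, 1))
        return st

    def test_gamma_one_forgets_past(self, rng):
        st = self.make_state(1.0)
        prev = ensemble(rng.standard_normal((self.n, 1)), t=1)
        anc = rng.integers(0, self.n, self.n)
        curr = ensemble(rng.standard_normal((self.n, 1)), ancestors=anc, t=2)
        out = update_kappa(st, prev, curr, 0.0, self.model, None, rng)
        sA, sb = self.model.suffstat_increment(prev.x[anc], curr.x, 0.0)
        np.testing.assert_allclose(out.kappa_A, sA)
        np.testing.assert_allclose(out.kappa_b, sb)

    def test_gamma_zero_permutes_ancestors(self, rng):
        st = self.make_state(0.0)
        prev = ensemble(rng.standard_normal((self.n, 1)), t=1)
        anc = rng.integers(0, self.n, self.n)
        curr = ensemble(rng.standard_normal((self.n, 1)), ancestors=anc, t=2)
        out = update_kappa(st, prev, curr, 0.0, self.model, None, rng)
        np.testing.assert_allclose(out.kappa_A, st.kappa_A[anc])
        np.testing.assert_allclose(out.kappa_b, st.kappa_b[anc])

    def test_blend_equals_plain_update_when_backward_equals_ancestor(self, rng):
        # Forcing B = A makes the half/half blend algebraically identical to
        # the plain genealogy update; realized here with a point-mass
        # previous ensemble so every index draws the same ancestor.
        n = self.n
        st = self.make_state(0.3, beta=1.0)  # always trigger backward branch
        st.kappa_A = np.repeat(st.kappa_A[:1], n, axis=0)
        st.kappa_b = np.repeat(st.kappa_b[:1], n, axis=0)
        prev = ensemble(np.zeros((n, 1)), w=np.r_[1.0, np.zeros(n - 1)], t=1)
        anc = np.zeros(n, dtype=int)
        curr = ensemble(rng.standard_normal((n, 1)), ancestors=anc, t=2, resampled=True)
        out = update_kappa(st, prev, curr, 0.0, self.model, None, rng)
        st2 = self.make_state(0.3, beta=0.0)
        st2.kappa_A = st.kappa_A.copy()
        st2.kappa_b = st.kappa_b.copy()
        plain = update_kappa(st2, prev, curr, 0.0, self.model, None, rng)
        np.testing.assert_allclose(out.kappa_A, plain.kappa_A)
        np.testing.assert_allclose(out.kappa_b, plain.kappa_b)
        assert out.last_backward and not plain.last_backward

    def test_running_average_on_degenerate_filter(self):
        # One particle, gamma_t = 1/t: kappa reproduces the running average
        # of the increments along the single surviving path.
        model = LinearGaussianModel()
        st = SmoothingState.initial(1, 1)
        rng = np.random.default_rng(3)
        xs = rng.standard_normal(6).reshape(-1, 1)
        incr = []
        for t in range(1, 6):
            prev = ensemble(xs[t - 1 : t], t=t - 1)
            curr = ensemble(xs[t : t + 1], t=t)
            st = update_kappa(st, prev, curr, 0.0, model, None, rng)
            incr.append(xs[t - 1, 0] * xs[t, 0])
            assert st.kappa_b[0, 0] == pytest.approx(np.mean(incr))


class TestSmoothedStatisticAndMStep:
    def test_point_mass_returns_its_kappa(self):
        st = SmoothingState.initial(3, 1)
        st.kappa_b = np.array([[1.0], [2.0], [3.0]])
        curr = ensemble(np.zeros((3, 1)), w=np.array([0.0, 1.0, 0.0]))
        assert smoothed_statistic(curr, st).b[0] == pytest.approx(2.0)

    def test_uniform_weights_plain_average(self, rng):
        st = SmoothingState.initial(4, 1)
        st.kappa_A = rng.standard_normal((4, 1, 1))
        st.kappa_b = rng.standard_normal((4, 1))
        curr = ensemble(np.zeros((4, 1)))
        out = smoothed_statistic(curr, st)
        np.testing.assert_allclose(out.A, st.kappa_A.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(out.b, st.kappa_b.mean(axis=0), atol=1e-12)

    def test_matches_brute_force_loop(self, rng):
        n = 20
        st = SmoothingState.initial(n, 2)
        st.kappa_A = rng.standard_normal((n, 2, 2))
        st.kappa_b = rng.standard_normal((n, 2))
        w = rng.random(n)
        w /= w.sum()
        curr = ensemble(np.zeros((n, 1)), w=w)
        out = smoothed_statistic(curr, st)
        brute_A = sum(w[i] * st.kappa_A[i] for i in range(n))
        brute_b = sum(w[i] * st.kappa_b[i] for i in range(n))
        np.testing.assert_allclose(out.A, brute_A, atol=1e-12)
        np.testing.assert_allclose(out.b, brute_b, atol=1e-12)

    def test_burn_in_freezes_theta(self):
        model = LinearGaussianModel()
        st = SmoothingState.initial(4, 1, burn_in=50)
        theta_prev = np.array([0.42])
        stat = SuffStats(A=np.array([[2.0]]), b=np.array([1.0]))
        out = em_update(stat, 10, model, st, theta_prev)
        np.testing.assert_array_equal(out, theta_prev)

    def test_lorenz_lambda_scale_invariant_through_em_update(self):
        from pfcontrol.lorenz import LorenzModel

        model = LorenzModel()
        st = SmoothingState.initial(4, 3, burn_in=0)
        stat = SuffStats(A=np.eye(3), b=np.array([10.0, 28.0, 8 / 3]))
        for t in (1, 7, 1000):
            out = em_update(stat, t, model, st, np.zeros(3))
            np.testing.assert_allclose(out, [10.0, 28.0, 8 / 3], rtol=1e-12)

    def test_singular_statistics_keeps_theta(self):
        model = LinearGaussianModel()
        st = SmoothingState.initial(4, 1, burn_in=0)
        stat = SuffStats(A=np.array([[0.0]]), b=np.array([1.0]))
        out = em_update(stat, 5, model, st, np.array([0.7]))
        np.testing.assert_array_equal(out, [0.7])


class TestOnlineEMRecovery:
    def test_lg_transition_coefficient_vs_complete_data_mle(self):
        # Online EM on PF output converges to within 0.1 of the closed-form
        # complete-data MLE sum x_{t-1} x_t / sum x_{t-1}^2 on the true path.
        model = LinearGaussianModel(a=0.9, b=0.5, c=1.0, d=0.3)
        T, N = 500, 500
        xs, ys = make_lg_observations(model, T, seed=7)
        mle = np.sum(xs[:-1] * xs[1:]) / np.sum(xs[:-1] ** 2)
        cfg = PFConfig(n=N, alpha=0.8)
        rng = np.random.default_rng(1)
        ens = init_particles(model, cfg, rng)
        em = OnlineEM(model, N, np.array([0.5]), beta=0.7, burn_in=20)
        for y in ys:
            prev = ens
            ens = pf_step(prev, np.array([y]), 0.0, model, em.theta, cfg, rng)
            theta = em.step(prev, ens, 0.0, rng)
        assert abs(theta[0] - mle) < 0.1
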