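# Methods

`pfcontrol` couples three sequential-Monte-Carlo components into one closed
loop over a controlled state-space model (SSM)

    x_t ~ p(x_t | x_{t-1}, u_{t-1}; θ),     y_t ~ p(y_t | x_t; θ):

1. an **adaptive particle filter** for the latent state,
2. an **online EM algorithm with adaptive backward sampling** for the
   parameters θ, and
3. a **particle-filter formulation of model predictive control** (PF-MPC)
   for the input u_t.

All three run on weighted particle ensembles and require only that the
model can be simulated forward and its transition density evaluated — no
derivatives, no linearization.

## Adaptive particle filter

The filter keeps N weighted particles. Before each prediction it computes
the effective sample size ESS = 1/Σ w² of the previous weights; when
ESS ≤ αN it redraws ancestors by multinomial resampling and treats the
predecessor weights as uniform, otherwise ancestors are the identity and
weights carry through. Particles are propagated through the system model
(the proposal equals the transition, so no proposal correction appears) and
reweighted by the observation likelihood. Likelihoods are combined in log
space with a max-shift before exponentiation, so long runs with N = 1000
particles do not underflow; if every log-weight is −∞ the filter raises a
degenerate-weights error naming the time index rather than silently
renormalizing garbage.

Defaults: N = 1000, α = 0.8. α = 0 disables resampling entirely; α = 1
resamples whenever weights are non-uniform.

## Online EM with adaptive backward sampling

For exponential-family SSMs the M-step is a closed-form map Λ applied to
smoothed additive sufficient statistics S_t = Σ_τ s̃(x_{τ−1}, x_τ). Online
EM replaces the batch E-step with a per-particle statistic κ_t^(i) updated
by stochastic approximation at decay rate γ_t:

    κ_t^(i) = (1 − γ_t) κ_{t−1}^(A_t(i)) + γ_t s̃(x_{t−1}^(A_t(i)), x_t^(i)).

γ_t = t^(−1) by default; any exponent in (0.5, 1] satisfies the
Robbins–Monro conditions and is configurable. With γ_t = 1/t, κ is exactly
the running average of increments along each surviving lineage, so the
weighted average Σ w_t κ_t estimates the *time-averaged* smoothed
statistic; because both shipped Λ maps are ratios (A⁻¹b and −A⁻¹b,
invariant under joint rescaling of A and b), the distinction between the
averaged and summed statistic never affects the estimate.

Propagating κ along the filter genealogy alone degenerates as lineages
coalesce. Each particle therefore carries an **Enoch index** — the index of
its ancestor at the last backward-sampling event — and when the number of
unique Enoch indices falls to βN or below (β = 0.7 default), one backward
ancestor per particle is drawn from the smoothing kernel
Categorical(w_{t−1}^(l) p(x_t^(i)|x_{t−1}^(l))) and the update becomes the
half/half blend of the ancestor-path and backward-path terms. Conditional
on the current particle, the genealogical ancestor is itself marginally a
draw from this kernel, so the blend is a proper two-sample smoothing
update. Backward draws use rejection sampling (propose from the filter
weights, accept with density/bound; the bound is the Gaussian transition's
normalizing constant), capped at ⌈√N⌉ synchronized rounds, after which the
remaining indices are resolved by exact categorical draws over all N terms
— bounding worst-case cost at O(N) per particle while keeping the sampler
exact.

Ordering per step: Enoch indices are composed through the new ancestors
(reset to identity on the step following a backward event), diversity is
evaluated, then κ is updated on whichever branch applies; the M-step
θ̂_t = Λ(Σ w κ / t) runs after a burn-in (θ̂ frozen at θ̂₀ while κ
accumulates; the γ schedule is indexed by absolute t with no restart).
Estimates are floored at 10⁻⁶ for parameters with a positivity constraint
(Lorenz σ, b; all conductances), and a singular A-part keeps the previous
estimate with a logged warning instead of aborting a closed loop mid-run.

## PF-MPC

The control problem over a horizon of T_H steps is solved as a filtering
problem on the augmented state ζ = (x̄, ū, ũ): the predictive state, the
predictive input, and a frozen copy of the initial input. The reference
trajectory acts as an observation through N(r_τ | selector(x̄), σ_r²). The
augmented ensemble is initialized from the state PF (states and weights
copied; inputs drawn from a clamped Gaussian around the previously applied
input, ũ = ū), reweighted once with the current reference value, then
advanced T_H times with the same adaptive-resampling machinery as the state
filter: propagate x̄ under each particle's ū with θ̂_t frozen, advance ū
as a clamped random walk, carry ũ through the ancestors, reweight with the
next reference value. The applied input is the weighted mean of the ũ
values at the end of the horizon — a convex combination of proposals that
individually satisfy the input constraint, so the constraint holds by
construction (the dot product is additionally pinned to the convex hull to
rule out few-ulp floating-point overshoot).

The horizon never feeds back into the state filter or the EM statistics.
Because the initial proposal is centered on the previously applied input,
the controller acts incrementally: per-decision corrections are modest, and
regulation emerges over successive steps.

## Lorenz application

Plant: dx/dt′ = σ(y−x), dy/dt′ = rx − y − xz + u, dz/dt′ = xy − bz, with
truth (σ, r, b) = (10, 28, 8/3), integrated by classical RK4 at Δt = 0.01
with additive process noise Σx·Δt (Σx = I; a deterministic-plant switch
exists). All three coordinates are observed with noise Σy = I. The SSM is
the Euler discretization with Gaussian noise Σx·Δt. The sufficient
statistics are diagonal quadratic forms whose ratio A⁻¹b is the
complete-data MLE of (σ, r, b) (verified in tests to <1 % on a long
simulated path).

The control target is the unstable fixed point; its y-value is
√(b(r−1)) ≈ 8.485 for the truth (the point at which the drift actually
vanishes — asserted by a property test over random parameters). For σ = 10,
b = 8/3 the fixed points lose stability at the subcritical Hopf point
r_H = σ(σ+b+3)/(σ−b−1) = 470/19 ≈ 24.7368, provided σ − b − 1 > 0; the
package also locates r_H numerically by root-finding on the Routh–Hurwitz
condition as an independent cross-check. Since r = 28 > r_H, the
uncontrolled attractor is chaotic and the reference r_t ≡ y_f with
|u| ≤ 10 stabilizes it.

Defaults not printed in the source experiments and chosen here once:
initial truth state x₀ = (1, 1, 1) (the initial particle distribution
N(x₀, 10²I) is wide enough to make the exact choice immaterial), initial
parameter guess θ̂₀ = (5, 20, 1.5), run length t′ ∈ [0, 30] with control
enabled at t′ = 5.

## Morris–Lecar application

Plant: the two-variable conductance-based neuron (membrane potential v,
potassium gate n) with tanh-sigmoid steady-state activations, Euler
integration at Δt = 0.1, process noise diag(0.1², 0.001²)·Δt, and only v
observed (noise 0.1²). The constants profile is the canonical
"Homoclinic" set (Cm = 20, EL = −60, ECa = 120, EK = −84, V1 = −1.2,
V2 = 18, V3 = 12, V4 = 17.4, φ = 0.23; truth conductances gL = 2, gCa = 4,
gK = 8), exposed as an overridable dataclass. In this regime rest and
periodic spiking are bistable, so a bounded-current controller can switch
the neuron between them. τ(v) is the reciprocal 1/(φ·cosh((v−V3)/(2V4))).

The sufficient statistics are built from the per-channel driving potentials
V_ion = (v−EL, m∞(v)(v−ECa), n(v−EK)): A accumulates rank-one Gram matrices
(Δt/Cm)² V_ion V_ionᵀ and Λ = −A⁻¹b is the complete-data MLE of the
conductances (verified to <5 % on a 20 000-step simulated path).

The net current I = u + I_inj splits into the controllable current and a
known injected series (zero by default; any series can be supplied). The
constraint |u + I_inj| ≤ 150 is enforced by clamping the *net* current in
the control proposal, with the injected-current prediction frozen at its
decision-time value across the horizon. The reference v-trace is generated
in advance by the deterministic true model under a drive schedule —
spiking drive 45 on t′ ∈ [0, 250] ∪ [500, 750], resting drive 5 elsewhere,
both verified to sit inside the profile's bistable range — over
t′ ∈ [0, 1000] (10 000 steps), with burn-in 1000 and θ̂₀ = (1, 2, 4).

## Numerical choices

- All weight arithmetic in log space with max-shift; total underflow raises
  a named error rather than producing NaNs.
- clamp(u, L) is computed as min(max(u, −L), L), algebraically identical to
  (|u+L| − |u−L|)/2 but exact in floating point.
- Λ solves the 3×3 system with `numpy.linalg.solve`; singular statistics
  are caught, logged, and skipped.
- Multinomial draws use inverse-CDF lookups on the cumulative weights with
  the final entry pinned to 1.
- Four independent RNG streams (truth plant, state filter, EM backward
  sampling, control filter) are spawned from the root seed via
  `numpy.random.SeedSequence`, so disabling one module never perturbs
  another's draws and whole runs are bitwise reproducible.

## What the synthetic experiments do and do not show

Both case studies are simulation studies: the "data" come from the same
model family the filter assumes (plus the RK4-vs-Euler discretization gap
in the Lorenz truth plant). Passing tests therefore demonstrate internal
consistency — exact statistics, unbiased smoothing, constraint satisfaction,
regulation — not robustness to model misspecification, non-Gaussian noise,
or unmodeled dynamics, all of which real laboratory data would add.

A practical property of the estimator worth knowing: with γ_t = 1/t and an
observation channel much noisier than the per-step transition noise (the
Lorenz setting: observation std 1 vs transition std 0.1), the one-step
proposal is nearly self-confirming and convergence of θ̂ from a distant
initial guess is slow — the estimate moves steadily but can remain tens of
percent from the truth after 3000 steps, even though the recursion's fixed
point is at the MLE (verified by starting at the truth, which stays within
a few percent). The Morris–Lecar setting, whose observations are precise
relative to the membrane dynamics, converges much faster. Run length,
initial guess, and noise levels therefore matter more than N for parameter
accuracy.

## Problem sizes used by the shipped experiments

Lorenz: N = 1000 particles, 3000 steps, three seeds (median reported).
Morris–Lecar: N = 1000, 10 000 steps. The oracle-equivalence checks use
N = 2000 × 100 replicates (filter vs Kalman) and N = 50, T = 20 × 200
replicates (AdaSmooth vs exact O(N²) smoother and RTS closed form).

## Known limitations

- Only multinomial resampling is implemented (the interface permits other
  schemes); no auxiliary/guided filters.
- Offline (batch) EM, fixed-lag smoothers, and gradient-based online ML are
  out of scope; the exact O(N²) smoother exists only as a test oracle.
- The Gaussian reference likelihood is the only augmented observation model;
  no input-rate penalties or economic MPC costs.
- Estimation of non-conductance neuron constants (Cm, φ, reversal
  potentials) is not supported.
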