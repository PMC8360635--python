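# Methods

## Model

Every circuit is a set of coupled bursty birth–death processes on
non-negative integer counts `(x, y, z)`.  Bursts of species `S` arrive as
a Poisson process; each burst adds an i.i.d. burst size `B_S` supported on
{1, 2, ...}; molecules decay one at a time.  Two burst laws are
implemented: deterministic (integer `b`, second moment `b²`) and shifted
geometric (`P(B=j) = (1−p)^{j−1}p`, `p = 1/⟨B⟩`, second moment
`2⟨B⟩²−⟨B⟩`), the law under which the intrinsic noise reduces to
`CV²_int = ⟨B_y⟩/ȳ = γ_y/k_y`.  The shifted-geometric parameterization on
{1, 2, ...} was chosen (over the {0, 1, ...} variant) because it
reproduces that moment identity exactly and every burst produces at least
one molecule.

The disturbance `X` multiplies the target's burst frequency by `x/x̄`,
with `x̄ = k_x⟨B_x⟩/γ_x` always the analytic stationary mean, never a
simulation estimate, so the average burst frequency stays `k_y` by
construction.  Regulation multiplies the frequency by `g(z) =
1/(1+(z/z_c)^h)` (proportional and integral topologies) or by `(z/y)^h`
(derivative topology).  The integral controller's `Z` is born in bursts
at rate `k_z·y/⟨B_z⟩` (mean influx `k_z·y`) and degraded at the constant
zero-order rate `k_z·y_set`, so `d⟨z⟩/dt = k_z(⟨y⟩−y_set)` is a
stochastic integrator of the set-point error.

## Deterministic layer

Stationary means solve the flux-balance fixed point per topology.  The
proportional mean equation `k_y·g(k_z⟨B_z⟩ȳ/γ_z)·⟨B_y⟩ = γ_y·ȳ` is solved
by Brent's method on the bracket `[0, k_y⟨B_y⟩/γ_y]` — valid because
`g ≤ 1` bounds the closed-loop mean by the open-loop mean — at relative
tolerance ~1e−15; uniqueness follows from monotonicity of `g` and is
cross-checked in the tests by a damped fixed-point iteration from a
different start.  The integral mean inverts the Hill function in closed
form and requires `y_set` strictly below the open-loop mean (repression
can only lower the mean); the boundary cases raise typed errors rather
than returning degenerate circuits.

Feedback gains are the log-sensitivities of the regulation at the
operating point: `f_p = f_i = h(1−g(z̄))`, strictly below `h`, and
`f_d = h·γ_y/γ_z`.  The static input–output sensitivity
`S = (k_y/ȳ)·dȳ/dk_y` is computed by centered finite difference over two
steady-state solves with default relative step 1e−4: the step is small
enough that the O(δ²) truncation error sits below 1e−6 relative even for
the curved proportional response, and large enough that the ~1e−15 solver
noise does not amplify (differencing noise ≈ 1e−15/2e−4 ≈ 5e−12).  For
the open, integral and derivative topologies the response is exactly
proportional/flat, so any sane step returns 1/0/1 to machine precision.

## Moment layer (LNA)

The only nonlinearity is the target's burst frequency; it is expanded to
first order in the normalized deviations `(s/s̄ − 1)` around the
deterministic means.  All propensities are then affine, so the first and
second uncentered moments close exactly.  The system `μ̇ = â + Aμ` is
assembled mechanically from the infinitesimal generator: for each moment
monomial and each reaction channel, (affine rate) × (expected change of
the monomial under the jump), with burst moments `(⟨B⟩, ⟨B²⟩)` entering
the second-order terms.  Moment ordering is fixed (means, then second
moments lexicographic) for reproducible matrix layouts.

Stationarity requires `A` Hurwitz; eigenvalue real parts must lie below
−1e−9 or a `StabilityError` names the offending eigenvalue — borderline
systems are rejected rather than solved.  The integral topology is
singular at `f_i = 0` (pure integrator, zero eigenvalue), so the moment
solver requires `f_i > 0`; the closed-form layer handles the limit, which
analytically recovers the open-loop noise split.  The stationary solve is
preconditioned by the diagonal similarity `D = diag(∏ s̄^m)` so the scaled
unknowns are O(1) (raw moments span ~12 orders of magnitude for
high-copy circuits), followed by one step of iterative refinement; this
keeps the residual at machine level, which matters because noise
components are recovered by differencing nearby solves.

Noise decomposition uses source silencing.  The stationary covariance of
a linear system is additive in the shot-noise contributions of its
independent event sources while the drift matrix is shared, so three
solves — (i) full, (ii) disturbance frozen at `x̄`, (iii) additionally all
controller shot terms (burst second moments *and* the ±1 death shot
terms) replaced by their drift-only Liouville parts — yield external =
(i)−(ii), controller = (ii)−(iii), intrinsic = (iii), with the total
exactly equal to the full solve.  Death shot terms must be silenced along
with burst variance because the controller's stationary noise
`CV²_Z = (⟨B_z⟩+⟨B_z²⟩)/(2⟨B_z⟩z̄)` receives its `⟨B_z⟩` part from death
events; silencing births alone would leave a spurious residue in the
controller component.  The decomposition agrees with the printed
three-component closed forms to better than 1e−8 relative (in practice
~1e−13) on hundreds of random circuits per topology — this
cross-validation is the package's central correctness argument, and the
generator-derived solver is the designated authority should a
transcription of a closed form ever disagree.

## Closed-form layer

All printed noise expressions are implemented as pure total functions of
a `NoiseInputs` record.  The optimal-gain and extremum identities are
re-derived by elementary calculus from their parent expressions (the
source renders their radicals ambiguously) and pinned by numeric
argmin/argmax oracles:

- integral band-pass peak `γ_x* = √(k_z f_i ȳ γ_y/z̄)` and the
  slow-disturbance optimum `f_i* = (CV_X/CV_Z)·√(z̄γ_x/(ȳk_z))` are exact
  stationary points (tested to 1e−6 against the oracles);
- the proportional optima `f_p* = (2CV²_Xγ_z/(CV²_Zγ_y))^{1/3}` (external
  noise only) and `f_p* = (CV_int/CV_Z)√(γ_z/γ_y)` (intrinsic only) are
  strong-feedback asymptotics: they approximate the true argmin with
  relative error of order `1/f_p*`, so tests evaluate them in their
  stated regime (small sensor noise, `f_p* ≈ 10²`, agreement ~1%, checked
  at 2%) and additionally assert convergence toward the asymptote.  At
  order-one gains the asymptotic formula is *not* close to the argmin —
  a property of the approximation, not a defect.

## Simulation layer

The SSA is the direct method (single exponential clock, event chosen
proportionally to propensities, all propensities recomputed after every
event) on the nonlinear circuits, compiled with numba.  Exactness rather
than speed-per-event is the design goal — the simulator is the
independent check on the linearized analysis, so no tau-leaping or hybrid
approximations are used.  Conventions at the boundaries of the state
space: the derivative ratio propensity evaluates `(z/max(y,1))^h` (the
ratio is undefined at `y = 0`; the unit floor keeps propensities finite
and is invisible in the small-noise regime where the closed forms hold),
and the integral controller's constant degradation channel is suppressed
at `z = 0` to keep counts non-negative.

Stationary estimates are time-weighted averages over post-burn-in
segments.  Default burn-in is `10/min(first-order decay rates)` — the
slowest relaxation clock sets the mixing time — and replicates start
deterministically at the rounded steady means to shorten transients
(configurable to zeros).  Standard errors come from a replicate-level
jackknife of the pooled estimator, since time-correlated samples
invalidate i.i.d. formulas.  A population cap (default 10⁶ per species)
converts runaway parameterizations into a typed error.  Replicate seeds
are spawned from a single user seed; identical (circuit, horizon, seed)
reruns are bit-identical.

Problem sizes for the bundled validation experiment (derivative circuit
at `k_y=2, γ_y=0.2, ⟨B_y⟩=20, ⟨B_z⟩=1, k_z=γ_z, h=1`, no disturbance)
are 12–16 replicates of ~2000 time units over a six-point `γ_z` grid,
which resolves the stationary CV² ≈ 0.08–0.1 to roughly 1–3% per point.
At that precision the simulated noise sits within 3 SE of the closed form
at every grid point.  At much higher precision a systematic ≈1%
linearization bias becomes resolvable at the strongest gain
(`f_d = 0.5`) — expected, since the closed forms are exact only in the
small-noise limit; the moment and formula layers carry no sampling error,
so their mutual agreement is tested at 1e−8 instead.

## What the experiments cover, and limits

The sweep runner reproduces the figure-level experiments as tables: gain
sweeps of the component decompositions (proportional, integral,
derivative), the disturbance-time-scale band-pass of the integral
controller, and the SSA-vs-analytics overlay.  Gain is swept either
abstractly (directly in the closed forms) or physically via the Hill
coefficient with means re-solved per point; normalization to the
zero-gain/open-loop total is applied last.  One fixture stores a
disturbance time-scale whose printed source is ambiguous
(`γ_x = γ_y/5` adopted, the alternative kept alongside); both readings
leave the qualitative gain-sweep structure unchanged.

Not covered, by design: combined PI/PID topologies, Ornstein–Uhlenbeck
disturbance models, parametric `g(y,z)` families beyond the matched-Hill
ratio limit, higher-order moment closures, and transient (non-stationary)
noise trajectories — the ODE right-hand side is exposed, but only
stationary moments are analyzed.  The simulator emulates phenomenological
bursty expression, not mechanistic promoter switching; agreement of the
three engines therefore validates the mathematics of this model class,
not the biological fidelity of any particular parameter set.
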