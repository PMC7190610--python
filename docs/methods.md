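# Methods

## Model

State `(x, y)`: producer and grazer carbon densities (mg C/l). Parameters
(units: rates /day, densities mg C/l, quotas mg P/mg C): producer growth
`b`, carrying capacity `K`, grazer conversion efficiency `e < 1`, grazer
loss `d`, producer minimal P:C quota `q`, grazer fixed P:C quota `θ`,
maximal ingestion `c`, half-saturation `a`, phosphorus pool `P_total`
(equivalently `p = P_total/θ`). Standing assumptions enforced by
`validate_params`: positivity, `c e > d`, `e < 1`, `q < θ`, `x* < p`, and
`K ≤ min{P_total/q, (θ/q) x*}` with `x* = a d/(c e − d)`. The invariant
set is the open trapezoid `Ω = {0 < x < K, 0 < y < p, qx + θy < P_total}`.

The drift is continuous but only piecewise `C¹`: the Liebig term
`min{x, p − y}` switches branches on the line `x + y = p`. States exactly
on the line are labelled quantity-limited (`x_limited`) by convention —
the drift agrees from both sides there, so only labels and Jacobians need
the rule; requesting a Jacobian on the line without an explicit branch is
an error rather than a silent choice.

## Deterministic structure

Interior equilibria are intersections of the producer nullcline parabola
`y = (b/c)(1 − x/K)(a + x)` with the two grazer-nullcline segments: `l1`
(`x = x*`) and `l2` (`d x + c e y = c e p − a d`). The `l2` intersections
are solved as an explicit quadratic in `u = a + x` (deterministic, no
initial guess); candidates are accepted strictly inside `Ω` with a
`1e−12` margin. The tangency threshold `K4` comes from the
zero-discriminant condition of that quadratic, a second quadratic in `K`;
the admissible root is the one exceeding `K1` whose tangency point lies in
`Ω`. Stability is read from the eigenvalues of the branch-correct
Jacobian, with a `1e−8` margin on real parts below which the label is
`marginal` rather than a hard call.

A subtlety worth recording: in the cycle/equilibrium regime
(`K ∈ (K2, K3)`) the three interior equilibria are the `l1` state — an
*unstable focus*, destabilised at `K2` where the parabola's peak crosses
`l1` — plus an `l2` saddle and an `l2` stable node. The limit cycle
surrounds the unstable focus; it cannot surround the saddle (index
theory). Published accounts sometimes attach the focus's role to the
saddle's coordinates; the package reports each point with its computed
eigenvalues so the roles are unambiguous.

### Integration and geometry

Deterministic flows use `scipy`'s DOP853 at `rtol = atol = 1e−10`. No
event-splitting is done at the branch line: the field is `C⁰` there and
the adaptive step control absorbs the kink; the invariants that would
expose a failure (finite-difference Jacobian agreement `<1e−5`, cycle
closure `<1e−6`, separatrix invariance `<1e−4` over 10 time units) all
hold at tolerance, so the extra machinery was judged unwarranted.

The separatrix is grown in reversed time from `saddle ± 1e−7 v_s` (unit
stable eigenvector), stopping at the box `[0, 1.5K] × [0, p]`, and stored
as an ordered polyline through the saddle. Basin membership is a
signed-side test against the nearest polyline segment; points within
`1e−9` are `on_separatrix`; the basin containing the smaller-`x` attractor
is `basin_A`.

The limit cycle is found by forward integration from a `1e−3` offset off
the unstable focus, collecting crossings of the section
`{x = x_focus, dx/dt > 0}`. The transient is considered over when
successive returns differ by `<1e−8`; the period is the mean of the last
few return intervals (the latest returns are the most converged; this
makes the period section-independent to `<1e−6`). Returns converging onto
the focus itself (spiral-in, amplitude `<1e−4`) are reported as "no
cycle". The default search horizon is `t = 8000` because the Floquet
contraction near the Hopf point is slow (multiplier ≈ `e^{−2}` per
17.4-day period; reaching the `1e−8` return tolerance takes ≈ 5500–6000
time units for the reference cycle). Whether the orbit crosses the branch
line is measured and stored, never assumed (the reference cycle does, by
a hair: max `x + y` ≈ 0.61747 vs `p = 0.617`).

## Stochastic simulation

Euler–Maruyama on the original variables, default `h = 1e−3` day:
`x ← x + F₁h + ε x √h ξ₁`, `y ← y + F₂h + ε y √h ξ₂`, independent standard
normals, intensity chosen by the regime (`x + y ≤ p` → `ε₁`, else `ε₂`) of
the pre-step state. The kernel is numba-compiled and bit-reproducible for
fixed `(seed, h)`; ensemble replicates derive per-replicate seeds from a
fixed affine map of the base seed. The exact solution is strictly
positive, so a step driving a component nonpositive is retried on halved
substeps (fresh increments, up to 20 halvings) and finally clamped at
`1e−12` with an audit flag; weak-noise studies never trigger the clamp.

This simulator **is** the synthetic-data generator of the analysis: its
ensembles emulate stationary fluctuation clouds around attractors and
basin-hopping paths. It does not emulate anything the model itself lacks —
demographic stochasticity, measurement error, parameter drift,
seasonality — so a green Monte-Carlo test establishes consistency between
the simulated model and the SSF theory, not fidelity to any field data.

Basin-hopping statistics label every 10th state by its separatrix side
(polyline decimated to ≤1200 vertices, KD-tree nearest segment) and count
label changes that persist at least the debounce time (default 5 days);
shorter excursions are absorbed as chatter. Extinction is operationalised
as both components simultaneously `< 1e−3` (no threshold is inherited
from the source material); the critical extinction intensity is only ever
reported as a bisection bracket over Monte-Carlo extinction frequency with
its binomial standard error, never as a sharp number.

## Stochastic sensitivity

At a stable hyperbolic equilibrium, `W` solves `F W + W Fᵀ + S = 0` with
`S = diag(x̄², ȳ²)`, written as the explicit 3-unknown linear system in
`(w₁₁, w₁₂, w₂₂)`; an independent route through `scipy`'s generic Lyapunov
solver agrees to `1e−12` and the residual is checked below `1e−10`. The
branch-correct Jacobian is used — for equilibria in the quality-limited
region the `x_limited` entries would not be stationary-correct.

Along the cycle, `μ(t)` solves `μ̇ = a μ + b` with
`a = 2f₁₁p₁² + 2(f₁₂+f₂₁)p₁p₂ + 2f₂₂p₂²`, `b = g₁₁²p₁² + g₂₂²p₂²`
(`p(t)` the unit normal, `g = (x, y)` on the orbit). `b` uses *squared*
diffusion entries, as `S = G Gᵀ` dictates; printed accounts that drop the
squares are dimensionally inconsistent with their own `S`. The periodic
solution is built from per-segment exponential step maps
(`μ ← e^{a·dt} μ + b (e^{a·dt} − 1)/a`, endpoint-averaged coefficients),
which is exact for constant coefficients and second-order otherwise;
segments straddling the branch line — where `a(t)` jumps — are split at
the interpolated crossing. This yields periodicity residual at machine
level and `<1e−4` relative change under 2× resampling. `∫a dt ≥ 0`
(orbitally unstable cycle) is rejected.

Confidence domains: ellipse level `2ε² ln 1/(1−P)` with boundary sampled
from the Cholesky factor of `W`; band half-width `ε k √(2μ(t))`,
`k = erf⁻¹(P)` (`k = 1.385904` at `P = 0.95`; `√2·k` is the Gaussian
97.5 % quantile). The tangency threshold `ε*` minimises the Mahalanobis
distance from the ellipse centre to the separatrix (vertex scan plus
golden-section refinement on the adjacent segments) and divides by
`√(2 ln 1/(1−P))`.

## Numerical and design choices

- Tie-break on `x + y = p`: `x_limited`; drift continuous there.
- Config accepts exactly one of `P_total` or `p` (`P_total = p·θ`); all
  quantities carried in the source units, no conversions.
- `Ω`-membership margin `1e−12`; classification margin `1e−8`.
- Monte-Carlo checks against `W` use thinned stationary sampling (400
  replicates, 60-day thinning after a 150-day burn-in, ≈2400 samples) so
  the estimator's sampling error (~3 % per entry) is well below the 15 %
  agreement tolerance; with single end-states per replicate the estimator
  noise (~10 %) would dominate the comparison.
- The basin-label oracle is a fixed-step RK4 ensemble integrator
  (`h = 0.01`, `t = 1500`, nearest-attractor assignment), independent of
  the separatrix construction it audits.

## Known limitations

- **Gaussian validity range of the cycle band.** The reference cycle is
  small (radius ≈ 0.01) and close to its Hopf point. At `ε = 5e−4` the
  simulated transverse spread exceeds the SSF prediction by ~2× (measured
  variance ratios 1.6–3.3) and band coverage drops to ≈0.83; the ratio
  converges to 1 and coverage to ≈0.96 by `ε = 1e−4`. The scalar `μ` was
  verified against the periodic matrix Lyapunov equation (agreement to 3
  decimals) and a linearized-SDE simulation, so this is a validity limit
  of the linear theory, not of the implementation. Coverage checks are
  therefore run at `ε = 1e−4`.
- **Strong-noise extinction.** Under the faithful multiplicative-noise
  discretisation, `ε₁ = 0.15` produces no extinction (0/50 runs below
  `1e−3` by `t = 500`); the Itô growth-suppression scale `ε²/2 ≈ 0.011`/day
  is negligible against `b = 1.2`/day, and extinction only sets in near
  `ε ≈ 1.2`. The corresponding acceptance test is kept at the stated
  intensity and is expected to fail; it is not weakened.
- The cycle-breakup capacity `K*` is not located; cycle existence is only
  detected at the configured `K`.
- Printed sensitivity matrices for the reference equilibria could not be
  reproduced from their own defining equations (two independent solution
  routes agree with each other and with Monte-Carlo covariance, not with
  the printed values); the package never hard-codes them, and downstream
  printed ellipse coefficients and the 0.002 tangency estimate are treated
  as qualitative (the computed threshold is of the same order, 0.0033).
- Only Holling type II ingestion; no continuation in `K`; no heteroclinic
  connections; no higher-order SDE schemes; the alternative
  ingestion-rate-perturbation noise entry is out of scope.
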