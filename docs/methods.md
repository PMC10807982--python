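# Methods

## Model and assumptions

The package implements a three-compartment mean-field model of cultural
transmission on the 2-simplex: fractions n (naïve), i (inefficient), e
(efficient) with n + i + e = 1.  Mass-action encounters occur at the
product of compartment frequencies; no encounter-rate constant is
introduced because the dynamics are defined directly at the level of the
frequency products.  The modelled assumptions are:

- constant population size (turnover replaces, it does not add);
- no cultural loss: e → i only through social learning from an inefficient
  demonstrator, never spontaneously;
- naïve individuals always attempt to learn on encounter; knowledgeable
  individuals attempt with probability 1 − c;
- encounters with naïve individuals teach nothing;
- processes are concurrent in continuous time — no ordering within a
  "round" is assumed.

Parameters (all per unit model time, dimensionless probabilities where
noted): μ innovation rate (default 0.01), m turnover rate, c conservatism
probability in [0, 1], s_e and s_i learning success rates (defaults
s_i = 0.1; s_e has no default since it is the primary swept parameter).
The canonical starting condition is an all-inefficient population
(n, i, e) = (0, 1, 0).  One model time unit is the scale on which a single
social-learning event can occur (days-to-weeks in most natural systems, so
realistic turnover satisfies m << 0.1 per step).

s_e > s_i is the standing assumption ("the better solution attracts more
learners"); violating it is allowed but logged, since the boundary
s_e = s_i is useful for symmetry tests.

## Equilibria and regimes

With μ > 0 the inefficient compartment always empties.  The surviving
balance gives e* = 1 − m/s_e with n* = m/s_e and i* = 0 for m < s_e
(persistence); for m ≥ s_e the all-naïve state is the attractor
(extinction).  m = 0 gives e* = 1.  The closed form requires μ > 0: at
μ = 0 the model has a continuum of fixed points and `equilibrium_analytic`
rejects it explicitly rather than guessing.  The i component of any
persistent equilibrium is exactly 0 and is encoded structurally, not solved
for.  The boundary m = s_e is assigned to the extinction regime (the
formula gives e* = 0 there by continuity).

The all-naïve vertex is an exact fixed point for every parameter set and is
the one exception to independence from starting conditions; the robustness
check therefore samples Dirichlet(1,1,1) starts with rejection of points
with i0 + e0 < 0.01, with a mandatory seed.

## Numerical choices

- Trajectory integration: adaptive 8th-order Runge-Kutta (DOP853),
  rtol 1e-8 / atol 1e-10.  The state is the full triple (n, i, e); the
  simplex sum is *asserted* (drift < 1e-7 along trajectories), never
  renormalized, so solver defects cannot be masked.
- Threshold crossing: terminal event on e − threshold with the solver's
  root-finding on the dense interpolant; crossing-time error is far below
  the documented 1e-6 tolerance.
- Unreachable vs. horizon-too-small is decided by the closed-form e*, not
  guessed: no crossing with e* ≤ threshold is "unreachable"; with
  e* > threshold the horizon doubles (opt-in) or an explicit error is
  raised.
- Transversality margin: trajectories can overshoot e* only by ~1e-11 (the
  approach is essentially monotone near equilibrium at the study
  parameters), which is below solver noise (~1e-7).  At the razor edge
  e* = threshold the event detector can therefore fire spuriously.  A
  detected crossing with e* ≤ threshold is accepted only if the trajectory
  later clears threshold + 1e-6; otherwise it is classified unreachable.
  The margin is far above solver noise and far below any genuine transient
  overshoot (which requires strong innovation and is macroscopic when it
  occurs).  Consequence: cells with m = s_e/2 exactly are unreachable for a
  one-half threshold, consistent with their asymptotic-from-below approach.
- Numeric equilibrium: LSODA at rtol 1e-10 / atol 1e-12 with horizon
  doubling from 1e3 to a 1e7 cap, stopping when max |rhs| < 1e-9 at the
  endpoint; non-convergence is reported with the achieved residual, never
  silently truncated.  Near m = s_e the approach slows (the slow eigenvalue
  is m − s_e) and at m = s_e exactly the decay is algebraic: the residual
  tolerance is then met while e is still ~1e-5, so numeric regime labels
  use e > 1e-4 for persistence, placing the boundary with extinction.
  Tiny negative components within 1e-10 at the endpoint are clamped to 0
  at the output boundary only.
- Sensitivity of t_h to m: central finite difference with dm = 1e-3
  (forward at m < dm) — well below plotted grid spacings, well above the
  crossing-time tolerance, so discretization scales stay separated.
- Critical curve: for each m, a coarse scan over c in [0, 1] brackets sign
  changes of the sensitivity; bisection narrows the bracket to half the
  c tolerance, making the returned root reproducible to the stated 1e-4
  regardless of the initial scan density.  Multiple sign changes keep the
  root nearest the previous m's root (curve continuity) and are logged;
  m values without a sign change are omitted with a log entry.
- Critical ratio: Brent root-finding on m for e*_numeric(m) = threshold
  (bracketed around the closed-form root, which is also logged as a
  cross-check); the returned quantity is s_e/m at the root, equal to
  1/(1 − threshold) analytically.

## Stochastic counterpart

The finite-N model is a continuous-time Markov chain on integer occupancies
with seven channels (innovation, turnover ×2, naïve learning ×2,
conservatism-gated exchange ×2).  A pairwise channel between classes with
fractions x and y fires at total rate N·x·y·s, so the expected drift of
fractions equals the ODE vector field *exactly* (verified term-by-term in
tests); self-encounter corrections (N/(N−1)) are deliberately omitted to
keep the lift drift-exact.  Simulation is Gillespie's direct method —
exact, event-driven, reproducible given a seed; replicate seeds derive from
a SeedSequence.  This makes the chain a genuinely independent oracle: it
shares no integration machinery with the ODE path.

Finite-size behaviour the ODE cannot show: the all-naïve state is absorbing,
so at small N the trait can be lost by drift even when m < s_e (observed
extinction frequency ~20% at N = 20 vs 0 at N = 2000 over the tested
horizon).

## Problem sizes

The shipped analyses use sizes chosen to make each check decisive while
keeping a full run in the minutes range: a 20×20 (m, s_e) equilibrium grid;
5-point critical-curve grids with 11–21-point c scans; 10 random parameter
draws for the fixed-step oracle (RK4 step 1e-3, Euler step 1e-4, sup-norm
on [0, 100] at 101 sample points); 200 stochastic replicates at N = 1000
for the mean-field check (the Euler comparison is the binding one: its
first-order error is ~1e-5 at that step, the RK4 reference is ~1e-7).

## What the checks do and do not show

All validation runs are against the model's own independent re-encodings
(hand-reduced special cases, fixed-step integrators, the drift-exact CTMC)
and closed forms.  They establish that the implementation solves these
equations correctly — not that the equations describe any particular
natural population.  The model omits spatial and network structure, age
structure, individual heterogeneity in c or learning rates, more than two
trait variants, vertical transmission, and cultural loss; conclusions about
systems where those matter require extending the model, not re-tuning it.

## Known limitations

- `equilibrium_analytic` (and everything that classifies reachability
  through it) requires μ > 0; μ = 0 trajectories integrate fine but
  threshold verdicts then rely on event detection alone.
- Exactly at m = s_e the numeric equilibrium's algebraic decay means the
  reported e (~1e-5) is tolerance-limited rather than converged to the
  true 0.
- The CTMC event loop is pure Python; ensembles beyond ~10^7 events (e.g.
  N = 10^5 populations over long horizons) get slow.
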