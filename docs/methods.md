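# Methods

## Model class and scope

`odeident` analyses deterministic state-space ODE models

    dx/dt = f(x(t), u(t), p),   y(t, p) = g(x(t), p),   x(0) = x0,

with `n` states, `m` observed outputs, `p` unknown parameters and known
inputs `u` restricted to constants and piecewise-constant tables.  The
time symbol is reserved as `t`; autonomous systems need not mention it.
Initial conditions are numeric and known by default; a state may instead
declare a named unknown IC, which then joins the unknown vector and is
treated like a parameter by every analysis.  Units are carried as
metadata only and never checked dimensionally (the bundled case studies
freely mix a.u., mM and 10^6 cells/mL).  Delay, stochastic and PDE
models, events, and SBML import are out of scope.

## Structural identifiability

### Taylor-series method

Outputs are expanded about t0 = 0.  Successive derivatives are generated
by the Lie derivative along the vector field, D(h) = Σ_i (∂h/∂x_i) f_i +
∂h/∂t, and evaluated at the initial conditions, which are substituted in
exact rational arithmetic (2.5 becomes 5/2) so that worked derivations
come out as exact rationals rather than floats.

Every coefficient y^(k)(0) is treated as a known, measurable quantity.
An alternative parameter vector p* is output-indistinguishable from p
exactly when c_k(p*) = c_k(p) for all retained coefficients, so the
classifier solves that system for p* symbolically.  This formulation is
always consistent (p* = p is a solution), which matters: equating
coefficients to fresh "observed" symbols instead makes underdetermined
systems look contradictory to a symbolic solver, because the surplus
equations become relations among the observed symbols.  Per parameter:

* a single branch (necessarily p*_i = p_i) → globally identifiable;
* finitely many branches, none involving other starred unknowns →
  locally identifiable, with the branch count reported; branches are
  counted over the complex numbers, and a real-branch count under a
  generic positive parameter point is reported alongside, since realness
  affects practical interpretation only (the classic y = 2a² case has
  two branches ±a, both real);
* a branch left free or tied to another starred unknown →
  unidentifiable.

The number of coefficients defaults to 2n − 1 per output — for systems
linear in the states that many coefficients exhaust the information; for
nonlinear systems the same count is only a heuristic, the cap is flagged
non-strict, and the caller can raise it (the protein-only scenario of
the regulation model, for instance, needs five).  Symbolic solving is
guarded by a wall-clock timeout (default 60 s, SIGALRM-based, main
thread only); on timeout the verdict is *inconclusive*, never a
classification, and the report points at the rank test.

### Jacobian rank method

Rows are all output derivatives of orders 0..K (Lie derivatives, known
constants substituted exactly); columns are ∂row/∂p_i for every unknown.
Full column rank at a generic point means no parameter direction leaves
all output derivatives unchanged, i.e. at-least-local identifiability;
the deficiency counts the free directions.  Implementation choices:

* **Exact arithmetic at random rational points.**  States and parameters
  are specialized to rationals with numerator and denominator uniform on
  1..10^4, and the rank is computed exactly over Q — no floating-point
  rank thresholds.  Specialization can only lower rank (off a
  measure-zero set it attains the generic value), so the maximum over 3
  independent trials is reported; verdicts are checked stable across
  seeds in the test suite.  States are substituted *before*
  differentiating with respect to parameters — valid because states and
  parameters enter the derivative rows as independent symbols — which
  keeps expression swell manageable for the rational-function rows of
  the Monod-type models.
* **Generic states by default.**  The generic-point rank is the standard
  local test; an option substitutes the declared initial conditions
  instead, reproducing the fixed-experiment setting (this can only lower
  the rank, e.g. when an IC of zero freezes part of the dynamics).  The
  cross-method test compares the Taylor classifier with the fixed-IC
  rank variant, since the Taylor coefficients are themselves evaluated
  at the declared ICs.
* **Order selection.**  With `order="auto"` the derivative order grows
  until the rank is unchanged between consecutive orders or full rank is
  reached, capped at n_states + n_unknowns with a warning on a cap hit.
* **Known-parameter suggestions.**  Fixing a parameter deletes its
  column, so minimal fixing sets are found by exhaustive subset search
  over column submatrices (intended for ≤ 12 unknowns; beyond that the
  result is flagged partial).

The two methods disagree by design in one situation worth knowing about:
with degenerate initial conditions (e.g. an empty compartment) an
experiment can carry less information than the generic model structure.
The Taylor verdict describes *this experiment*; the generic-point rank
verdict describes the *model*.  Both are reported side by side by the
workflow and neither is adjudicated.

## Simulation and estimation

Trajectories come from `scipy.integrate.solve_ivp` with LSODA
(stiff-capable, adaptive) at rtol 1e-8 / atol 1e-10 by default; the
symbolic right-hand side and output map are compiled once per model with
common-subexpression elimination.  A divergence guard aborts integration
cleanly when any state exceeds 1e100 in magnitude, reporting the time —
without it a finite-time blow-up drives the step-size controller into an
effectively unbounded shrink loop.

The objective is the Gaussian −2 log-likelihood up to an additive
constant, J(p) = Σ ((y_obs − y_sim)/σ)², so profile thresholds add χ²
quantiles directly.  When records carry no σ, a constant per-observable
σ is profiled out analytically (σ̂² = mean squared residual) and the
n·log σ̂² term is retained.  Fitting is multi-start local least squares
(`scipy.optimize.least_squares`, TRF, tolerances 1e-8): the first start
is the user's guess, the rest are log-uniform in the box bounds (default
a factor of 10³ either side of the guess), and parameters are optimised
on the log scale by default since every parameter in the bundled models
is a positive rate or constant.  Fits are deterministic given (data,
init, bounds, n_starts, seed).

## Profile likelihood

For each parameter in turn, the parameter is stepped away from its MLE
in both directions and the nuisance parameters are refitted at every
grid value:

* threshold J_min + χ²(1−α, df), with three df conventions: *pointwise*
  (df = 1, the default — the standard per-parameter likelihood-ratio
  interval), *residual* (df = n_obs − n_params, matching the
  degrees-of-freedom arithmetic some practitioners use, e.g. nine for
  ten observations and one parameter), and *simultaneous*
  (df = n_params).  Plotted thresholds of third-party tools are
  tool-internal and are not reproduced;
* adaptive stepping: initial step 1% of |MLE| (0.01 if the MLE is ≈ 0),
  rescaled ×2 / ×0.5 to target an objective increment of ~10% of the χ²
  quantile per step, clamped to [1e-4, 0.5]·|MLE|, at most 100 steps per
  direction;
* warm starts: each refit starts from its neighbour's nuisance optimum,
  with a cold-start retry from the global MLE whenever a refit lands
  more than one quantile above its neighbour (a symptom of a lost local
  optimum);
* a direction ends by threshold *crossing* (the CI bound is interpolated
  linearly between the bracketing grid points), at a parameter *bound*,
  or at the step cap (*max-steps*); non-crossing sides report their halt
  reason rather than an "infinite" bound;
* a profile whose total rise is below 1% of the quantile is declared
  *flat*;
* a refit failure at a grid point is flagged and skipped; a refit at the
  MLE that cannot reproduce the fitted optimum (beyond tolerance) is an
  error, since every later comparison would be meaningless.

A parameter is practically identifiable iff both bounds are finite; the
model verdict is the conjunction.  The profile objective can never drop
below the global minimum (refits only add constraints), profile CIs
widen as α decreases, and pointwise intervals carry ~95% coverage — all
three are enforced in the test suite, the last by a 200-replicate
calibration study on synthetic regulation-model data checking each
parameter's coverage against the 95% ± 4% band.

## Synthetic data

The generator stands in for digitised literature time courses: sparse
grids (10–20 points per observable), additive Gaussian noise with a
recorded per-record σ (default: 5% of each observable's dynamic range
over the design grid), or proportional noise with a constant CV.
Presets mirror the three case studies: `model1_like` (both outputs, 16
points over 0–20 h, three replicate series — a single series leaves the
translation rate's small steady-state signal marginal against the
range-scaled protein noise), `model2_like` (all three bioreactor states,
15 points over a 120 h culture), `model3_like` (cells only, denser
during the first 12 h of growth).  What the generator does *not*
emulate: digitisation bias (systematic, not Gaussian), irregular
operator-chosen sampling, and correlated errors between observables read
off the same figure — so passing tests demonstrate correctness of the
machinery and calibration under the assumed error model, not robustness
to real digitisation artefacts.

## Case-study fixtures

The three bundled models keep the published constants: regulation model
ICs (2.5, 6.5 a.u.); bioreactor ICs (1.01 mM, 3.98 mM, 0.46·10^6
cells/mL) with dilution rate and feed glucose either as published
(0.033 hr⁻¹, 7 mM) or re-estimated (0.017 hr⁻¹, 0.131 mM — the
published pair drives simulated glucose negative on the re-digitised
data, so the re-estimated pair is the default); growth-inhibition ICs
(4.45·10^6 cells/mL, 0) with only the cell count observed.  The
growth-inhibition model's exponent follows the corrected sign convention
e^{a(I−b)}; the reversed-sign variant from the original publication is
available under `form="original_sign"` for comparison but excluded from
the headline checks.  Its augmented form introduces φ = e^{aI} (φ(0) =
e^0 = 1, unobserved) and r_ab = e^{−ab}, making the system rational so
the rank method applies; the substitution identity is verified
numerically in the tests.  Reference parameter points for simulations
and synthetic data use the published estimates (regulation: k1 = k3 =
0.25, k2 = k4 = 0.5; bioreactor: r_glu 0.032, r_lac 0.020, μ_max 0.078,
km_glu 0.221, ki_lac 10.954; growth inhibition: r_g 0.057, r_d 0.005,
a 2.6, b 3.4).

## Problem sizes in the shipped checks

The calibration study uses 200 replicates of the 96-record preset
design; the bioreactor case-study check uses one synthetic replicate (45
records), profile stepping capped at 20 steps per direction with a ~25%
quantile increment per step and integrator tolerances 1e-7/1e-9 — the
coarser profile changes interval endpoints by well under the interval
width and leaves every crossing/no-crossing verdict unchanged.  The
cross-method agreement study uses 50 random two-state linear
compartmental models.

## Known limitations

* The Taylor classifier inherits the limits of symbolic solving: for
  strongly nonlinear models the coefficient system may time out
  (reported as inconclusive).  The rank method always answers but only
  at local resolution, and for very complex models a rank deficit at the
  searched orders can understate identifiability.
* Input–output (differential-algebra) elimination methods are not
  implemented; general time-varying inputs are deferred.
* Profile CIs are likelihood-ratio intervals under the declared Gaussian
  error model; model misspecification (e.g. the bioreactor model's
  inability to track lactate) is not detected by identifiability
  analysis and needs separate goodness-of-fit scrutiny.
* Estimates and intervals are reported independently and never
  reconciled: an estimate outside its own CI in a source table is
  reproduced as such, not "corrected".
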