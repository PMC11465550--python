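# odeident

Structural and practical identifiability analysis for parametrised ODE
models, with the weighted least-squares fitting and synthetic-data
machinery needed to run the full model-development loop:

> declare model → structural identifiability → fit to data → practical
> identifiability → (redesign / fix parameters) → repeat.

It is aimed at modellers in systems biology and bioprocess engineering
who fit kinetic models (gene regulation, bioreactor cultures, growth
inhibition) to sparse time-course data and want to know, *before*
trusting an estimate, whether the data could have determined it at all.

## The two questions, and how they are answered

A model is declared in state-space form

```
dx/dt = f(x(t), u(t), p),    y(t, p) = g(x(t), p),    x(0) = x0,
```

with states `x`, known inputs/constants `u`, unknown parameters `p`, and
observed outputs `y`.  A parameter `p_i` is **structurally
identifiable** when equal output trajectories force equal values,
`y(t, p) = y(t, p*) ⇒ p_i = p_i*` — globally if the value is unique,
locally if finitely many values are consistent.  Two independent methods
are implemented:

* **Taylor-series method** (`odeident.taylor`) — the output derivatives
  `y^(k)(0)` are, in principle, measurable, so they are treated as known
  quantities; solving the coefficient system `c_k(p*) = c_k(p)` for the
  alternative vector `p*` classifies every parameter (unique branch →
  global; finitely many branches → local, with the branch count; a free
  direction → unidentifiable).  For systems linear in the states at most
  `2n − 1` coefficients carry information (`n` = number of states); for
  nonlinear systems the same count is used as a heuristic and flagged as
  such.
* **Jacobian rank method** (`odeident.rank`) — the Jacobian of the
  stacked output derivatives with respect to `p`, evaluated in exact
  rational arithmetic at random specializations, has full column rank
  exactly when the model is at least locally identifiable; a rank
  deficit counts the free directions, and an exhaustive column-subset
  search reports the minimal parameter sets whose prior knowledge
  restores full rank.

A parameter is **practically identifiable** (`odeident.profiling`) when
its likelihood-based confidence interval from an actual dataset is
finite: the parameter is stepped away from its maximum-likelihood
estimate, all other (nuisance) parameters are refitted at every step,
and the resulting profile is compared with the threshold
`J_min + χ²(1−α, df)` on the −2 log L scale.  Crossing on both sides
gives a finite interval; a flat or one-sided profile means the data do
not pin the parameter down even when the structure does.

## Worked example

Three case-study models ship with the package (`models/*.yaml` and
`odeident.examples`): a two-state mRNA/protein regulation model, a
three-state perfusion bioreactor with Monod growth and lactate
inhibition, and an erythroblast growth-inhibition model with an
exponential inhibition term (plus its polynomialised "augmented" form).

```python
import odeident as oi

model = oi.model1("both")          # both states observed
print(oi.analyze_taylor(model).summary())
print(oi.rank_test(model).summary())

truth  = oi.reference_params("model1")
design = oi.case_study_designs()["model1_like"]
data   = oi.generate(model, truth, design, seed=11)

results  = oi.OdeMLE(model, data).fit(init=truth, n_starts=1)
print(results.summary())
profiles = results.profile_all()
print(profiles.summary())
```

prints

```
Taylor-series structural identifiability (ok)
  k1: globally identifiable
  k2: globally identifiable
  k3: globally identifiable
  k4: globally identifiable
  overall: globally identifiable

Jacobian rank test: rank 4 of 4 unknowns (order 2, 3 specializations) -> at-least-locally-identifiable

OdeMLE results: model1
  records: 96   objective (-2 log L): 81.4139   starts: 1   converged: True
  parameter        estimate
  k1                  0.242985
  k2                  0.480835
  k3                  0.184183
  k4                  0.464567

Profile likelihood (95% CI, pointwise convention)
  parameter        estimate        lower        upper  verdict
  k1                  0.242985     0.207947     0.283253  practically identifiable
  k2                  0.480835      0.43382     0.535191  practically identifiable
  k3                  0.184183     0.063576     0.339934  practically identifiable
  k4                  0.464567     0.397673     0.550732  practically identifiable
  model: practically identifiable
```

Reading it: with both outputs observed, all four rates are structurally
(indeed globally) identifiable; on one synthetic replicate of the preset
design (96 records, additive noise at 5% of each observable's range) the
fit lands near the generating values (k1=0.25, k2=0.5, k3=0.25, k4=0.5)
and every 95% profile interval is finite and contains them.  Repeat with
`oi.model1("mrna_only")` and the Taylor method reports k3 and k4
unidentifiable, the rank test finds two free directions, and
`oi.suggest_known(...)` answers `{k3, k4}` — the workflow then refuses
to profile until you fix or measure them.

The same analyses run from the shell:

```bash
odeident sia-taylor models/model1.yaml --report taylor.json
odeident sia-rank   models/model1_mrna_only.yaml --suggest-known 2
odeident make-data  models/model1.yaml --params k1=0.25,k2=0.5,k3=0.25,k4=0.5 \
                    --design model1_like --seed 11 --out data.csv
odeident fit        models/model1.yaml data.csv --init k1=1,k2=1,k3=1,k4=1 --starts 20
odeident workflow   models/model1.yaml --design model1_like \
                    --params k1=0.25,k2=0.5,k3=0.25,k4=0.5 --report report.json
```

`workflow` exits 0 on success, 3 if the model is structurally
unidentifiable (stopping before any fitting), 4 if practically
unidentifiable, 1 on execution errors.

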