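# testtreat

Design, power and blinded adaptive sample-size re-estimation for
**randomized test-treatment trials** — RCTs that compare two binary
diagnostic tests *A* and *B* not by their accuracy but by the patient
outcomes produced when each test's result drives a management decision.

Intended for biostatisticians and trialists planning diagnostic RCTs
(including biomarker-strategy trials): the package turns assumptions
about disease prevalence, test accuracy, conditional test dependence and
subgroup outcomes into effect sizes, sample sizes, and simulated
operating characteristics for four trial designs.

## The model

A patient has true disease status `D ∈ {+, −}` with prevalence `P(D=+)`.
Each test yields `R_τ ∈ {+, −}` (τ = A, B) with given sensitivity and
specificity; within each disease stratum the two results may be
conditionally dependent, parameterized by the covariance of the
positive-result indicators, `P(R_A=+, R_B=+ | D=d) = p_A(d) p_B(d) + cov_d`,
bounded by the Fréchet limits. A deterministic link rule maps the
followed result to a management, `m(+) = I`, `m(−) = II`, and the
expected outcome `e(m, t_A, t_B, d)` is specified for every management ×
result × disease stratum (binary: event probability; continuous: mean
with residual sd).

Two equivalent expansions of the planning effect `Δ = θ_A − θ_B`
(with `θ_τ = E(Y | followed test = τ)`) are implemented:

* **unpaired**: `θ_τ = Σ_{t,d} μ^τ_{m(t),t,d} P(R_τ=t|D=d) P(D=d)`, with
  `μ^τ_{mtd} = E(Y | M=m, R_τ=t, D=d)` derived from `e` by marginalizing
  over the unobserved test;
* **paired**: concordant strata cancel (same result ⇒ same management)
  and `Δ` reduces to a probability-weighted sum over the four
  reclassification *moves* when strategy B is replaced by A —
  `Δ = Δ(FP→TN)P(FP→TN) + Δ(TN→FP)P(TN→FP) + Δ(FN→TP)P(FN→TP) + Δ(TP→FN)P(TP→FN)`.

The discordant-pairs design targets the conditional effect
`Δ^disc = Δ / P(R_A ≠ R_B)`; its screened cohort is the randomized
discordant count divided by the discordance fraction.

Supported designs: **classical** (randomize which test is applied),
**discordant pairs** (both tests applied; only disagreements randomized),
**random disclosure** (both applied, one result revealed at random), and
the **single-test disclosure** variant. A blinded adaptive procedure
re-estimates the sample size mid-trial from the prevalence observed via
a blinded reference standard — using no outcome or arm information, so
the type I error of the final unadjusted analysis is preserved.

## Worked example

The packaged dysphagia scenario reproduces a published classical
test-treatment trial in which outpatients with dysphagia were randomized
to a modified barium swallow study (MBS) or endoscopic swallowing
evaluation (FEESST), with pneumonia as the outcome: 14 of 76 MBS
patients (18.4%) and 6 of 50 FEESST patients (12%) developed pneumonia —
a non-significant difference (chi-squared p = 0.335). Detecting the
observed 6.4-percentage-point difference with 80% power requires:

```bash
$ testtreat samplesize --p1 0.184 --p2 0.12
{
  "allocation_ratio": 1.0,
  "alpha": 0.05,
  "n_disc": null,
  "n_per_arm": 493,
  "n_screened": null,
  "n_total": 986,
  "power": 0.8,
  "sides": 2
}
```

i.e. 493 patients per arm, 986 in total — roughly eight times the
original trial. The same number comes from the full scenario route
(`n_classical_from_scenario(get_preset("dysphagia_worked_example"))`).

The paired planning route, for prevalence 0.30 and tests with
sensitivity/specificity 0.90/0.80 (A) and 0.70/0.90 (B), conditionally
independent:

```python
>>> from testtreat import *
>>> s = get_preset("paired_worked_example")
>>> summarize_effects(s)
EffectSummary(theta_a=0.855, theta_b=0.850, delta=0.005,
              discordance_fraction=0.284, delta_disc=0.0176...)
```

28.4% of patients are discordant; the tiny population-level effect
Δ = 0.005 concentrates into Δ^disc = 0.0176 among them — the lever the
discordant-pairs design exploits.

## Scenario configs

Scenarios are YAML files (all probabilities as decimals):

```yaml
population: {prevalence: 0.3}
tests:
  A: {sensitivity: 0.9, specificity: 0.8}
  B: {sensitivity: 0.7, specificity: 0.9}
  covariance: {diseased: 0.0, non_diseased: 0.0}
link: {positive: I, negative: II}
outcomes:
  scale: binary        # or continuous (then sd is required)
  sd: null
  table:               # 16 entries "management,t_A,t_B,d"
    "I,+,+,+": 0.7
    # ...
```

`testtreat presets write <name> <path>` exports any packaged preset as a
starting point. CLI subcommands: `effect`, `samplesize`, `simulate`,
`adaptive`, `presets`. Patient-level exports use the column dictionary
documented in `testtreat.simulator`.

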