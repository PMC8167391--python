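# Methods

## Generative model

A scenario is the full joint law of `(D, R_A, R_B, M, Y)`:

* `D ~ Bernoulli(prevalence)`;
* `(R_A, R_B) | D = d` from the 2×2 table fixed by the marginal positive
  probabilities (sensitivity in the diseased stratum, 1 − specificity in
  the non-diseased) and the conditional covariance `cov_d` of the
  positive indicators. The covariance parameterization (rather than an
  odds ratio or kappa) was chosen because feasibility is exactly the
  Fréchet–Hoeffding box `max(0, p_A+p_B−1) − p_A p_B ≤ cov_d ≤
  min(p_A, p_B) − p_A p_B`, and the boundary cases have direct design
  meaning: the lower bound maximizes, the upper bound minimizes, the
  discordance fraction. Convenience constructors accept conditional
  correlations and convert.
* `M = m(R_τ)` for the followed test τ, with the deterministic link
  `m(+) = I`, `m(−) = II` (overridable but always total and
  deterministic; looser, partially discretionary links are out of
  scope).
* `Y | (M, R_A, R_B, D)` with expectation `e(m, t_A, t_B, d)` — a
  16-cell table. Binary outcomes are Bernoulli(e); continuous outcomes
  are Normal(e, sd) with one residual sd shared across strata.

The 16-cell table is the single source of truth. The per-test planning
table `μ^τ_{mtd}` and the four move effects are *derived views*
(marginalizing over the unobserved test's result, or differencing
discordant cells), so the unpaired and paired effect expansions agree by
construction; the test suite asserts this identity to 1e-10 on randomly
drawn scenarios rather than trusting it. Conditioning the outcome on
both latent results — even in designs that observe only one — is
deliberate: a test result can carry prognostic value beyond the true
disease state, and simulating from the marginal table would silently
assume it does not.

Move semantics: a "move" (FP→TN, TN→FP, FN→TP, TP→FN) describes what
changes in one patient when strategy B is *replaced by* strategy A. The
sign of Δ flips under the reverse convention; the docstrings state the
direction wherever it matters. Under the default sign-symmetry
assumption only Δ(FP→TN) and Δ(FN→TP) need eliciting; both negations can
be overridden. Move effects are not further stratified beyond the four
categories.

## Sample-size formulas

Binary outcomes: normal-approximation size for the chi-squared test of
two independent proportions, variance pooled under H0 and unpooled under
H1, no continuity correction, per-arm n rounded up. This is the variant
that reproduces the packaged worked example: arm rates 0.184 vs 0.12 at
two-sided α = 0.05 and power 0.80 give 493 per arm, 986 total. (The
unrounded fractions 14/76 vs 6/50 give 980 under the same formula; the
package pins the rounded rates, which also match the quoted
6.4-percentage-point difference exactly.) Continuous outcomes use the
z-based two-sample formula `n₁ = (z_{1−α/s} + z_{pow})² σ² (1+1/r) / Δ²`
— z rather than t quantiles, for symmetry with the binary case; the
simulation benchmark (below) guards the adequacy of both
approximations. Defaults: two-sided α = 0.05, power 0.80, 1:1
allocation.

When sizing *from a scenario* on the continuous scale, σ is the marginal
outcome sd of an arm — residual sd plus the between-stratum spread of
the conditional means — not the residual sd alone; using the residual sd
understates the variance whenever strata differ (the planning guess
"variation of Y" refers to the observable arm-level variation). The
binary path needs no such correction because `θ(1−θ)` is already
marginal.

Discordant design: the matching two-sample formula applied to the
conditional arm quantities in the discordant subpopulation gives
`n_disc`; the screened cohort is `ceil(n_disc / P(R_A ≠ R_B))`.

## Simulator

All four designs share one array core: draw `(d, r_a, r_b)` for the
cohort, apply the design's randomization and disclosure rules, draw
outcomes from the 16-cell table, analyze. Analyses are the Pearson
chi-squared test without continuity correction (matching the sizing
formula family) and Welch's t test. Randomization is simple Bernoulli
1:1 — the simplest scheme consistent with the designs, which specify no
restriction. Concordant patients in the discordant design are simulated
and stored (for cost/feasibility accounting) but excluded from the
primary analysis; the discordant analysis uses the same two-sample tests
on the discordant subset. All randomness flows through one seeded
`numpy` Generator; identical seeds give identical trials. Replicates
with a degenerate analysis (empty arm, no discordance) count as
non-rejections in Monte-Carlo summaries and raise in single-trial runs.

## Blinded adaptive re-estimation

The interim rule reads exactly one statistic: the fraction of
reference-standard positives among the first `ceil(f · n_initial)`
patients (default f = 0.5). The planning scenario's prevalence is
replaced by this estimate, accuracy / dependence / outcome tables are
held at their planning values, and the closed-form n is recomputed.
Decision rule: stop for futility if the re-estimated n exceeds the
pre-specified cap `n_max`; continue as planned if it does not exceed the
initial n (the target is never shrunk by default — conservative,
overridable via `allow_decrease`); otherwise increase the target. All
recruited patients, interim ones included, count toward the final
target. The final analysis runs at the unadjusted α: the interim uses no
outcome values and no arm labels (a contract the tests check by adding,
removing and permuting those columns), so it is a blinded
nuisance-parameter re-estimation and does not inflate the type I error —
verified by simulation rather than assumed. A degenerate interim
estimate (0 or 1) warns; if the re-planned effect vanishes the trial
stops for futility. Re-estimation through sensitivity/specificity or
subgroup outcomes, and unblinded interims with α-spending, are out of
scope.

## Verification problem sizes

The benchmark suites in `testtreat.presets` define the conditions under
which the formulas are verified by simulation; they are package choices,
stated here once:

* `power_benchmark_suite`: five scenarios spanning binary/continuous
  outcomes and the classical/discordant designs, with effects placed so
  the formula-returned totals fall between ~550 and ~1500 patients —
  the regime these normal-approximation formulas are intended for
  (tiny trials would instead probe the approximation's known small-sample
  error). Power is checked at 10,000 replicates against the 0.80 target
  within 3 Monte-Carlo standard errors.
* `null_scenario`: identical tests with a non-trivial
  management-by-disease outcome table — an exact null for every design
  simultaneously, with treatment effects present (so the null is not
  trivially "nothing happens"). Type I error checked the same way.
* the adaptive check plans under a wrong prevalence (0.50 planned, 0.30
  true) chosen so the interim look genuinely moves the target (the
  re-planned n grows as prevalence falls in that scenario), with a
  generous cap (10× initial n) so futility stops do not confound the
  size comparison.

## Known limitations

* Exactly two tests, binary results, a perfect reference standard, and
  deterministic links; no dropout, non-adherence, measurement timing, or
  clustered randomization.
* The generator draws i.i.d. patients from the stated scenario; real
  trials add calendar-time drift, site heterogeneity and
  misspecification of the accuracy model itself, none of which the
  passing benchmarks speak to.
* The closed-form sizes are normal approximations; for very small
  discordant cohorts (tens of patients) exact methods would be
  preferable and are not provided.
* Presets for the tubal-patency (FOAM-style) and Doppler-US examples are
  synthetic sketches: their accuracy and outcome parameters are
  invented, as the underlying reports print none.
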