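# Methods

This note documents the models, numerical choices and known limitations
of `moralddm`, in enough detail to judge what a passing test suite does
and does not establish.

## The decision model

A response is modelled as the first passage of a Brownian motion with
drift `v` (evidence units per second, signed toward the upper boundary)
and unit diffusion coefficient, started at `z_rel·a` between absorbing
boundaries at 0 and `a`, plus a non-decision offset `τ` (seconds).  The
diffusion coefficient is a pure scale convention; fixing `s = 1`
matches the convention of widely used hierarchical-DDM software and is
not configurable.  The starting point is parameterized relatively
(`z_rel = z/a`) so that "one starting point shared across groups" is
meaningful when groups differ in `a`; the conversion to absolute `z`
happens inside the density.

**Density evaluation.**  Two series expansions of the defective
first-passage density exist; the large-time form converges slowly for
small scaled time `t/a²` and vice versa.  The evaluator computes the
number of terms each expansion needs for a requested absolute
truncation error (default `1e-7`) and uses the cheaper one — the
standard small-/large-time selection rule.  The upper-boundary density
is obtained from the lower-boundary evaluation by the reflection
`v → −v`, `z_rel → 1 − z_rel`.  The zero-drift case is handled by the
same series (no ε-perturbation is needed; only the closed-form
absorption probability has a removable singularity at `v = 0`, where
the analytic limit `P_upper = z_rel` is returned).

**Absorption before a deadline.**  The probability of absorbing at
either boundary before time `t` is computed by term-wise integration of
the large-time series.  The truncation test uses the sin-free envelope
of the terms, because the sine factor vanishes at periodic indices
(exactly at every second term for `z_rel = 0.5`) and testing the term
itself would stop the series far too early.  The envelope is only
guaranteed monotone past `k = |v|a/π`, so no break is taken before
that index.  Against adaptive quadrature of the density the result is
exact to ~1e-12 over the parameter ranges that occur in fitting.

**Simulation.**  Trials are simulated by Euler–Maruyama with step `dt`
(default 1e-4 s).  A discretely monitored path systematically
overshoots a continuous boundary, biasing absorption times and choice
probabilities by O(√dt); the simulator applies the standard continuity
correction (boundaries pulled inward by 0.5826·σ√dt).  With the
correction, 10⁵-trial samples match the analytic RT distribution with
KS < 0.008 at dt = 1e-4 and < 0.005 at dt = 1e-3; without it the KS
distance violates 0.01 already at dt = 1e-4.

## The hierarchical model

Each of the 12 valence groups (word type × populated cell of the
emotional×moral intensity grid) has participant-level `v`, `a`, `τ`
drawn from group-level Normal distributions (mean + spread per group);
the starting point is one value per participant, shared across all 12
groups, drawn from a single group-level distribution.  "Shared" is
interpreted per participant rather than as one global scalar because
the hierarchical framework estimates individual parameters.  The
`no_bias` variant fixes `z_rel = 0.5` and removes the starting-point
family from the free parameters.

**Likelihood.**  Each trial contributes the defective density of its
response boundary at `rt − τ`.  The density is defective with respect
to *choice* (no normalization by the choice probability).  Because the
procedure imposes a 1600 ms response deadline and timeout trials are
excluded, each kept trial is additionally conditioned on absorption
before the deadline (division by the analytic absorption-before-`t`
probability); without this correction boundary separation is
underestimated by ~0.1 in the slowest cells.  The correction can be
disabled (`deadline_ms=None`) for un-censored data.

By default the pipeline fits correct responses only, mirroring the
common practice of excluding error RTs.  This convention is fine for
the qualitative contrasts but is *outcome-dependent selection*: with
only correct trials the likelihood rewards any parameter change that
drives the correct-choice probability toward 1, inflating `|v|` (by
roughly +1 at a 5% error rate) and `a`.  Quantitative
parameter-recovery validation therefore fits all response trials
(`include_errors=True`), which is the correctly specified likelihood
for the generative process.

**Priors** (weakly informative, chosen to match common
hierarchical-DDM defaults): group drift means Normal(0, 2); boundary
means Gamma(shape 1.5, rate 0.75) truncated above 0.3; non-decision
means Uniform(0.05 s, deadline); starting-point mean Beta(2, 2); all
group spreads Half-Normal(1).  The non-decision group mean is *not*
bounded by the fastest observed trial: that would clamp the mean below
every participant's non-decision time whenever any single trial is
fast, which measurably biases `τ` and, through the speed–caution
trade-off, `a`.  Participant-level `τ` is still bounded by each cell's
fastest RT through the likelihood (`rt ≤ τ` has zero density).

**Sampler.**  Blocked Metropolis-within-Gibbs with seeded determinism:

- All participant×group values of one family are proposed jointly and
  accepted cell-wise (their full conditionals are independent given the
  group level), with per-group adaptive random-walk scales.
- Drift group means are conjugate Normal draws; boundary, non-decision
  and starting-point group means use adaptive random walks; spreads use
  random walks on the log scale.
- Two interweaving-style joint moves per family — a *location* move
  shifting all participant values together with their group mean, and a
  *scale* move rescaling the deviations together with the spread —
  traverse the `sd → 0` funnel that traps centered hierarchical
  samplers.  (For the scale move with `x' = μ + c(x−μ)`, `sd' = c·sd`,
  the participant-prior terms cancel against the Jacobian up to a
  single factor `c`.)
- Start values come from per-cell moment (EZ-style) estimates, so
  burn-in begins near the posterior bulk.
- Proposal scales adapt only during burn-in (clipped to a fixed range),
  leaving the post-burn-in chain a valid fixed-kernel MCMC.

Default schedule 60,000 draws with 5,000 burn-in; the desk-scale test
profile (3,000 / 500, used throughout the test suite and examples)
finishes a 30-participant moral-task fit in ~30 s on one CPU.
Convergence is reported per group-level parameter as split-chain R-hat
(4 segments), effective sample size and lag-1 autocorrelation; any
R-hat above 1.1 raises a `RuntimeWarning` and is recorded in the chain
object — never silent.  A frozen chain segment reports `R-hat = inf`
rather than NaN.  For publication-grade numbers the gate is R-hat <
1.05 at the full schedule.

**Inference.**  Group-level contrasts are posterior difference
distributions summarized by their mean and the percentages below/above
zero; a contrast is significant when ≥ 95% of the mass is on one side.
Draws exactly at zero (measure-zero in practice) are split half to each
side.  Model comparison uses DIC = D̄ + p_D with D = −2·log-likelihood
and p_D = D̄ − D(θ̄), θ̄ the posterior mean of all participant-level
parameters; lower is better.  (Published DIC pairs are occasionally
reported with the higher value labelled the winner; this package always
takes lower-is-better.)  Posterior predictive checks simulate replicate
datasets from stored posterior draws and compare observed per-group RT
quantiles (10/30/50/70/90%) and choice proportions against 95%
predictive intervals.

## The synthetic study

The generator reproduces the full design: 230 candidate words rated by
31 raters on two 1–9 scales (emotional and moral valence), intensity
transform `|rating − 5|`, selection of words with intensity > 2 on
either dimension (strict inequality), equal-width three-level binning
per dimension (a word on an exact edge goes to the upper bin;
equal-frequency binning available behind a flag), 12 populated cells of
8 words each, 30 participants × 2 tasks × 192 trials (each word twice,
shuffled; task order and key mapping counterbalanced), 1600 ms
deadline.

Rating noise has two components — per-rater leniency (shared across a
rater's answers on a scale) and independent item noise — tuned once so
Cronbach's alpha of the 230-item matrix lands near 0.94–0.95.  Design
words are placed comfortably inside their intensity level so the
norming → selection → binning round trip reconstructs the design from
noisy means (≥ 90% cell agreement; occasional edge words land in a
neighboring level, as they would in a real norming study).

Ground-truth DDM parameters follow the qualitative pattern the package
is built to detect: for moral words, drift rises with emotional level
(`v = 1.5/2.2/2.9`); for immoral words, boundary separation falls with
emotional level (`a = 1.8/1.5/1.2`, drift −2.2); moral level has no
effect; `τ = 0.33 s`, `z_rel = 0.45` (0.5 in the no-bias scenario, 0.35
in the strong-bias scenario used for model-selection studies).
Between-participant SDs are 0.25 (v), 0.12 (a), 0.04 (τ and z).  These
values were calibrated by closed-form computation — not fitted to any
test outcome — so that the simulated study matches the behavioral
profile of deadline-limited word evaluation: ~4–6% errors, <1%
timeouts, mean correct RTs 550–770 ms.  Round-number alternatives with
slower drifts produce mean RTs near 1 s and several percent timeouts,
which contradict the 1600 ms deadline regime.  The emotional task is
simulated from the same parameters with boundaries re-labelled
(upper = "positive") and small per-word-type non-decision offsets
(+7 ms moral, −16 ms immoral) to reproduce the task×word RT
interaction; these emotional-task values are conventions, since the
model is only ever fitted to the moral task.

**What the generator does not emulate:** sequential effects, practice
and fatigue, trial-to-trial parameter variability (sv, sz, st —
deliberately absent from the model too), lexical properties of real
words, and rater response-time behavior (the excluded slow rater is
emulated only as the final 31-rater matrix).  Passing recovery tests
therefore show that the estimator is correct for the model class, not
that real data satisfy the model.

## Validation at desk scale

- Density: normalization `∫(f_upper+f_lower) = 1` within 1e-6 over the
  grid v ∈ {−3…3}, a ∈ {0.5…3}, z_rel ∈ {0.2…0.8}; reflection identity
  to 1e-10; simulator-vs-density KS < 0.01 at n = 10⁵.
- Absorption: closed form vs. density integral (1e-6) and vs. Monte
  Carlo (3 binomial SEs, 20 parameter sets).
- Recovery: across 10 seeded 30-participant cohorts at the test MCMC
  profile, group-level `v` within ±0.3, `a` within ±0.2 and both
  monotone orderings hold jointly in ≥ 8/10 cohorts (orderings alone:
  10/10).  The per-seed max error over 12 groups is dominated by
  posterior dispersion (group-mean posterior SDs ≈ 0.13–0.15 for v),
  i.e. the bound sits near the information limit of 16 trials per cell.
- Model selection: DIC prefers the bias variant on strong-bias data in
  20/20 replicates at a shortened schedule (900/300).
- Statistics: ANOVA/simple effects match independent implementations to
  1e-10; BH-FDR matches the step-up definition on 1,000 random
  p-vectors; the ANOVA's null type-I error over 2,000 cohorts is
  binomially consistent with 0.05; the noncentral-F sample-size rule
  returns n = 26 at f = 0.25, α = 0.05, power = 0.85, m = 4, ρ = 0.5.

Problem sizes in the test suite (3,000/500 MCMC draws, 10 recovery
seeds, 20 DIC replicates, 10⁵-trial KS samples) are the package's
desk-scale validation profile; all of them scale up by changing one
argument.

## Known limitations

- The likelihood treats trials as exchangeable within participant ×
  group; no lapse/contaminant component is included, so real datasets
  with fast guesses will bias `τ` downward.
- Correct-only fitting (the default pipeline convention) is suitable
  for contrasts but not for absolute parameter values; see above.
- DIC is computed from participant-level posterior means; with strongly
  skewed participant posteriors p_D can be noisy at short schedules.
- The equal-width binning of intensity levels follows the observed
  range and is therefore sensitive to single extreme words; the
  tertile option is more robust but changes cell occupancy.
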