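# moralddm

Hierarchical Bayesian drift-diffusion analysis of valence-evaluation
reaction-time experiments.

`moralddm` is built for a common design in moral/affective psychology: a
two-choice word-evaluation experiment in which participants judge
two-character words as *moral vs. immoral* (or *positive vs. negative*)
under a response deadline, with the stimuli organized into a grid of
emotional-valence × moral-valence intensity levels.  The package covers
the entire analysis chain — stimulus norming and selection, trial
filtering, the behavioral ANOVA/t-test battery, and a 12-group
hierarchical Bayesian drift-diffusion model (DDM) with posterior-
difference inference and DIC model comparison — together with a
synthetic-data generator that reproduces the full study design with
known ground truth, so every stage can be validated end to end.

## The model

Each decision is a Wiener diffusion with drift `v`, boundary separation
`a`, relative starting point `z` and non-decision time `τ` (diffusion
coefficient fixed at `s = 1`).  Evidence accumulates from `z·a` until it
hits the upper boundary `a` ("moral") or the lower boundary 0
("immoral"); observed RT = first-passage time + `τ`.  The defective
first-passage density at the upper boundary is

```
f(t | z, a, v) = (π/a²) · exp((a−z)v) · Σₙ n · sin(πn(a−z)/a) · exp(−½(v² + π²n²/a²) t)
```

evaluated with the standard small-time/large-time series switch; the
lower-boundary density follows by reflection (v → −v, z → a−z), and the
upper-boundary choice probability has the closed form
`P = (1 − e^(−2vz)) / (1 − e^(−2va))`.

The hierarchical model gives each of the 12 valence groups (2 word
types × 6 populated grid cells) its own drift rate, boundary separation
and non-decision time at both the group and the participant level,
while all groups share one starting point per participant drawn from a
single group-level distribution.  A `no_bias` variant fixes `z = 0.5`;
comparing the two by DIC tests for a prior response bias.  Group-level
effects are read off posterior *difference distributions*: a contrast is
significant when at least 95% of its mass falls on one side of zero,
reported in the `M = …, x% < 0 < y%` style.

## Worked example

```python
from moralddm import SCENARIOS, HierarchicalDDM
from moralddm.simulate import generate_design, generate_true_params, simulate_dataset

scenario = SCENARIOS["emotional-dominance"]          # v rises with emotional valence
stim, sched = generate_design(seed=1, n_participants=30)
truth = generate_true_params(scenario, 30, seed=2)
trials = simulate_dataset((stim, sched), truth, seed=3, scenario=scenario)

model = HierarchicalDDM(draws=3000, burn_in=500, seed=7,
                        include_errors=True).fit(trials)
print(model.diff("v", "moral_2V1M", "moral_0V1M"))
print(model.diff("a", "immoral_2V1M", "immoral_0V1M"))
print(round(model.dic_, 1))
```

prints

```
M = 1.61, 0.0% < 0 < 100.0% *
M = -0.74, 100.0% < 0 < 0.0% *
-3286.4
```

i.e. on this synthetic cohort the drift rate for moral words rises with
emotional valence by 1.61 evidence units/s (the whole difference
distribution above zero, starred as significant), the boundary
separation for immoral words falls by 0.74 as emotional valence rises,
and the fitted bias model attains a DIC of −3286.4 (lower is better).
Both effects match the scenario the data were generated from.

The same pipeline is scriptable from the shell:

```bash
moralddm all --seed 1 --participants 30 --samples 3000 --burn-in 500 --out out/
```

writes `trials.csv`, `behavior.json`, `chains_{bias,no_bias}.csv`,
`fit.json` and a markdown `report.md`; `moralddm report` regenerates the
summary from the persisted JSON without refitting.

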