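# clampdecay

Simulation and decay-rate analysis of motor-memory loss during error-clamp
trials in force-field reaching experiments.

## The problem

When people reach through a velocity-dependent curl field (force
`F = B v`, `B = [[0, g], [-g, 0]]`, clockwise for `g = 15` N·s/m), they
adapt: they learn a lateral compensatory force. The strength of that motor
memory is measured with *error-clamp* (EC) trials, in which a stiff virtual
channel (spring 5000 N/m, damper 30 N·s/m) constrains the hand to the
straight start-target line; the lateral force pressed into the channel wall
at peak velocity, normalized by peak speed (N·s/m), reads out the learned
compensation. Over a run of EC trials the memory decays — and the *rate* of
that decay depends on what the participant sees: an expanding arc with no
direction information (slow decay), a veridical straight cursor (fast
decay), or a cursor artificially curved 1 cm leftward, which injects an
extra visual error (fast decay toward overcorrection). This package exists
to generate such cohorts synthetically and to estimate and compare decay
rates between feedback conditions with a statistically careful procedure,
for researchers studying error-driven unlearning in motor adaptation.

## What it computes

Per averaged 30-trial EC series the decay model is a single exponential

```
y = a·exp(b·x) + c,  x = 1..30
```

with initial state `a + c`, per-trial decay rate `b`, and asymptote `c`.
Because nonlinear fits to single participants are unstable, uncertainty
comes from an exhaustive subsampling bootstrap: all C(15, 12) = 455
twelve-participant subsets of each 15-participant group are averaged and
fit. Pairwise group differences are tested by permutation: on each of the
455 iterations the 24 selected participants are randomly reassigned to two
pseudo-groups and refit; the proportion of permutation differences
exceeding the mean bootstrap difference is the p-value.

The package is organized as fit-and-results objects: `CohortDecayModel`
is built from a trial table, and its `fit()` returns `CohortDecayResults`
carrying the per-group estimates, subsample distributions, pairwise
p-values, a `summary()` table and a `plot()` method. Around this core sit
the protocol builder (617 post-familiarization trials in 22 alternating
blocks), a two-tier synthetic cohort generator (full 1 kHz point-mass
trajectory simulation, or a fast metric-level tier sharing the same
two-state learner), trajectory metrics (movement time, directional error,
force at peak velocity, success classification), and block-level summaries
exported as tidy CSV for external repeated-measures statistics.

## Worked example

```python
from clampdecay import simulate_cohort, CohortDecayModel

records = simulate_cohort(seed=1, mode="fast")   # 3 groups x 15 participants
model = CohortDecayModel(records, groups=("arc", "cursor", "augmented"))
print(model.fit(seed=1).summary())
```

prints

```
Motor-memory decay: exponential fit y = a*exp(b*x) + c

group              a+c         b         c     sd(b)   min r2  n_sub
arc             -3.460    -0.065    -1.198     0.013    0.913    455
cursor          -2.870    -0.268    -0.136     0.015    0.892    455
augmented       -2.361    -0.260     0.732     0.009    0.941    455

pairwise comparison            p(a+c)     p(b)     p(c)
arc vs. cursor                 0.0945   0.0000   0.0000
arc vs. augmented              0.0044   0.0000   0.0000
cursor vs. augmented           0.2110   0.8484   0.0000
```

Reading this: all three groups enter the EC blocks with a similar memory
(initial state −2.4 to −3.5 N·s/m; negative = compensating the clockwise
field). The no-direction-feedback (arc) group decays slowly
(b = −0.065/trial) toward a still-negative plateau, while the two groups
with directional visual feedback unlearn about four times faster
(b ≈ −0.26); the curved-cursor group overshoots to a positive asymptote
(pushing against the fictitious visual error). The permutation test flags
the rate difference for arc-vs-cursor and arc-vs-augmented but not
cursor-vs-augmented, and asymptote differences for all pairs.

The same pipeline runs from the shell:

```
clampdecay run --seed 1 --out results/run1 --fast     # full report bundle
clampdecay validate                                    # check a config
```

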