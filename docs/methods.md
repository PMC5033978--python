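# Methods

## Protocol

A session is a familiarization period of 192 unperturbed reaches followed
by 617 trials in 22 blocks: a 72-trial null baseline (66 null + 6
interspersed clamp trials), ten force-field blocks of 20 trials (18 field +
2 interspersed clamps), nine 30-trial error-clamp assessment blocks
alternating with the first nine field blocks, a 45-trial null washout, and
a final 30-trial error-clamp recall probe. Only the totals (617 trials, 22
blocks, 30-trial clamp blocks, 18 field trials per adaptation block, 192
familiarization trials) are fixed by the study design; the split of the
remaining trials between the two null blocks and the interspersed-clamp
density are package defaults chosen to satisfy those totals exactly, and
every count is configurable. Interspersed clamps are placed uniformly at
random within their host block but never on its first three trials, so
block entry is always probed under the block's own field; their placement
uses a dedicated seed (`ProtocolConfig.iec_seed`) so that the schedule is
identical across participants and across cohort seeds.

## Reach simulation

The hand/robot is a planar unit point mass. The motor command is the sum of
(i) inverse-dynamics feedforward along a minimum-jerk reference from the
start dot to the target 15 cm ahead, (ii) a PD correction around the
reference (kp = 200 N/m, kd = 15 N·s/m — arm-like stiffness, an order of
magnitude softer than the channel), and (iii) the learned lateral
compensation `-z·g·vy`, applied on every trial. Environments: nothing on
null trials; the curl force `(g·vy, -g·vx)` with g = 15 N·s/m on field
trials; a spring-damper channel (5000 N/m, 30 N·s/m) acting on lateral
position/velocity on clamp trials. Integration is semi-implicit Euler at
1 kHz; the trial ends when the hand is within 0.75 cm of the target center
or is flagged failed at a 1200 ms timeout.

Movement time is measured between the 2.25 cm onset and 0.75 cm end
thresholds, which cut a minimum-jerk profile at fixed phase fractions
(0.521 of the reference duration lies between them). The reference duration
is therefore derived from the instructed movement time
(`target_movement_time_ms = 400`) by dividing by that fraction, so a
noiseless null reach measures 400 ms; per-trial (10%) and per-participant
(5%) lognormal duration jitter then produce a success probability
(350–450 ms window, endpoints inclusive) near 0.73, the intended ~0.70
operating point of the task.

On clamp trials the wall force at peak velocity equals the feedforward push
`-z·g·vy` attenuated by the stiffness ratio `k/(k + kp)` = 0.96, because
the arm's own stiffness absorbs a small share; the readout is therefore
within 4% of `-z·g` across the whole state range, and the channel confines
the hand to well under a millimeter.

## Learner

Adaptation is a standard two-state model:
`z_i <- retention_i · z_i + learn_i · error`, with a fast state
(retention 0.92, learning rate 0.08) and a slow state (0.996, 0.01), and
behavioral compensation `z = z_fast + z_slow` (clipped to [−0.5, 1.5]).

The error signal on field and null trials is the signed lateral deviation
at peak velocity normalized by reach length (measured from the trajectory
in the trajectory tier; its state expectation `(1−z)·0.20` for field and
`−z·0.20` for null trials in the fast tier, 0.20 being the naive deviation
the simulated plant actually produces). On clamp trials the hand moves
straight, so the only error is visual: the mismatch between the trajectory
predicted from the current compensation and the rendered feedback, which
grows with the adapted state. It is modeled as
`-gain · ec_error_scale · (z + offset)`, with gain 0 for the arc condition
(no direction information, hence retention-only decay), 1 for the veridical
cursor, and 1.1 for the curved cursor, whose 1 cm leftward bulge adds the
offset term (1/15 of reach length). This form makes the compensation decay
geometrically toward zero during clamp runs, faster for larger gains, and
drives the curved-cursor group below zero — the overcorrection seen in the
data.

`ec_error_scale = 1.8` and `ff_error_scale = 0.20` were calibrated once so
that (a) adaptation is partial, entering clamp blocks at −2.5 to −3.5 N·s/m
of normalized force, and (b) the fitted per-trial decay rates fall near
−0.07 (arc) and −0.26 (cursor/augmented) with the arc condition clearly
slowest. Noise: Gaussian state noise (sd 0.02 fast, 0.002 slow per trial),
motor noise of sd 1.5 N·s/m on the force readout (a per-trial lateral force
bias in the trajectory tier), and 10% lognormal participant-level jitter on
learning rates and error scales. Together these give trial-to-trial force
variability of 1.5–2 N·s/m.

The fast tier generates per-trial metrics directly from the learner state
(force = `−z·g` + noise; directional error proportional to the expected
deviation). It reproduces the trajectory tier's clamp-force statistics up
to the 4% stiffness-ratio attenuation and does not model the field's
slowing of movements, so field-block movement times and success rates are
more optimistic in the fast tier; all decay-rate analyses depend only on
the clamp-force series, which the tiers share.

## Decay estimation and inference

Each participant's nine post-adaptation clamp blocks are averaged
position-wise into one 30-point series (failed trials imputed with the mean
of the same position across the remaining blocks; imputations are logged).
The exponential `y = a·exp(b·x) + c` is fit by variable projection: for
fixed `b` the model is linear in `(a, c)` and solved in closed form, so the
fit is a 1-D profile search over `b` on a deterministic 121-point grid in
[−5, 0.5] followed by bounded refinement (xatol 1e−12) in the bracketing
interval. This is deterministic, has no starting-point sensitivity, and
recovers noiseless parameters to better than 1e−6 relative error. `x` is
1-based (this choice rescales `a` by `e^b` but leaves `b` and `c`
untouched). A constant series leaves `b` unidentifiable; the fit then
returns `a ≈ 0` with `c` at the series mean.

Group uncertainty comes from the exhaustive subsampling bootstrap over all
C(15, 12) = 455 subsets; subset i of group A is paired with subset i of
group B (lexicographic order) to form iteration i of a pairwise comparison.
The permutation test reassigns that iteration's 24 participants at random
into two pseudo-groups and refits. The p-value is the proportion of
permutation differences whose absolute value exceeds the absolute mean
bootstrap difference — a two-sided reading of "larger than the mean
difference"; the literal one-sided rule is available via
`AnalysisConfig.permutation_rule`. p-values are therefore multiples of
1/455 and can be exactly 0 or 1. For replicated experiments the subset list
can be thinned to a seeded random subset (`max_subsets`).

This procedure is mildly conservative under the null: the mean bootstrap
difference is a 15-vs-15 contrast while the permutation distribution is
built from 12-vs-12 splits, which have larger spread. Measured over
hundreds of same-generator replicate experiments, the rejection rate at
p ≤ 0.05 for the rate parameter is about 0.02–0.05.

## Problem sizes used in tests

The test suite and acceptance script run the fast tier throughout: full
default cohorts (45 participants × 809 trials) for the group analyses, 20
seeded cohorts for the effect-detection property, and 200 replicate
30-participant experiments (thinned to 100 subset iterations each) for the
null calibration. Trajectory-tier tests integrate single trials and a
four-participant miniature session; a full trajectory-tier cohort takes on
the order of a minute per 10 000 trials and is exercised through the same
code paths.

## Known limitations

- The learner's clamp-trial error is a one-parameter abstraction of visual
  prediction-error; it pulls the veridical-cursor asymptote close to zero
  (≈ −0.15 N·s/m) because the slow state also unlearns from visual error in
  this form; real participants plateau with more residual compensation. Group orderings and rate
  contrasts are unaffected.
- The plant has no biomechanics, no visuomotor delay, and no within-trial
  feedback adaptation; field trials therefore keep a larger steady-state
  directional error than trained humans show.
- No reinforcement-learning pathway is modeled (success feedback does not
  alter the states), consistent with treating decay as error-driven.
- Repeated-measures ANOVA/ANCOVA batteries are out of scope; block
  summaries are exported as tidy CSV for external statistics software.
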