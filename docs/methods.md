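# Methods

## The task and the measures

`wagertrack` models and analyzes a short serial reaction time (SRT) task with
mouse tracking. A participant sees 48 stimuli appear one at a time at four
circular targets (35 px diameter) arranged in a 2×2 grid inside a 500×500-px
canvas, clicks each as fast as possible, and the cursor is sampled at ~40 Hz.
A 750-ms inter-stimulus interval (ISI) separates each click from the next
onset — long enough for an *anticipatory* movement. Afterwards the
participant free-generates a 24-click recall sequence and rates pattern
awareness on a continuous 100–400 scale.

Two measures are computed from the cursor position at the 750-ms mark (the
last sample at or before onset, linearly interpolated if sampling jitter
leaves a gap):

- **initial distance to next** — Euclidean distance to the upcoming target
  center; 0 under a perfect prediction;
- **initial distance from previous** — axis-max (Chebyshev) distance
  max(|Δx|, |Δy|) from the previous target center; large whenever the cursor
  has committed to *some* other target, correct or not.

A trial is **predictive** when distance-from-previous ≥ 275 px and **correct**
when, in addition, distance-to-next ≤ 100 px (both thresholds inclusive).
Trial 1 has no previous target and is excluded from classification. The 48
trials form eight 6-trial blocks; each block's predictive proportion lies on
the 7-point lattice {0, 1/6, …, 1}, and its **excess score** (#predictive −
#correct, an integer in [0, 6]) indexes prediction that precedes accurate
knowledge.

### Reading of "maximum horizontal/vertical distance"

The distance-from-previous measure is implemented as Chebyshev distance
max(|Δx|, |Δy|). With the layout below, any committed between-target movement
reaches ≥ 330 px on at least one axis while a move to canvas center reaches
only 165 px, so the 275-px threshold cleanly separates the two. A Euclidean
variant is available (`distance_metric: euclidean`) for sensitivity analysis.

### Target layout

Target centers are at (85, 85), (415, 85), (85, 415), (415, 415), labels 1–4
in reading order (origin top-left, y down). The corner-ward placement is a
deliberate geometric constraint: the axis spacing between targets must exceed
the 275-px predictive threshold, otherwise no ideal between-target movement
could ever classify as predictive. A naive quarter-point grid (125/375,
spacing 250 px) fails that requirement; 330-px spacing satisfies it with
margin on both sides (165 px for a center move, 330 px for a wager).

## Sequence regularity G

Each training sequence is 48 positions long, never repeats a position
consecutively, and uses each position exactly 12 times. Its redundancy is

    G = 1 − (1/4) Σ_s H(s) / log2(4),

where H(s) is the base-2 entropy of the maximum-likelihood successor
distribution of symbol s (row s of the first-order transition table) and
rows with no observed successor contribute zero. G = 1 iff every observed
row is deterministic; the no-repeat constraint bounds G ≥ 1 − log2(3)/2 ≈
0.2075 for valid training sequences. Values are carried at full precision
and rounded half-up to two decimals only for display.

The package ships the 11 stimulus sequences with their published regularity
values as a CSV fixture. Ten of the eleven recompute exactly at two decimals;
the row published as .68 computes to 0.6872 (rounds to .69). The loader
flags this row (`printed_matches = False`) rather than silently forcing
either value; the discrepancy is consistent with truncation or a one-symbol
transcription difference in the printed sequence.

Recall sequences (24 items, unbalanced) are scored with the same statistic.

Sequence synthesis (`generate_sequence`) runs a seeded stochastic local
search: start from a random valid sequence, propose constraint-preserving
position swaps, accept moves that reduce |G − target| with a small annealed
probability of uphill moves, stop within ±0.02 of the target. A target of
1.0 short-circuits to a repeated 4-cycle. Unreachable targets (below the
constraint floor, or not found within the iteration budget) raise a
`SearchFailure` carrying the best G found.

## The synthetic cohort

No behavioral data are distributed with the task, so every downstream stage
runs against a simulator whose defaults emulate the reported study
conditions: 143 participants (11 sequences × 13), 48 trials, 750-ms ISI,
~40-Hz sampling with ±2 ms jitter.

The agent maintains additively smoothed (pseudocount 0.1) first-order
transition counts over the symbols it has seen. During each ISI it is in one
of two modes:

- **reactive** — it waits at the just-clicked target or, with probability
  `centering_propensity` (0.5), moves to canvas center, the equidistant
  "readying" position;
- **predictive** — it wagers: it moves toward a target drawn by probability
  matching from its smoothed successor distribution (exponent
  `guess_sharpness`, default 1; the previous position is excluded since the
  task never repeats). Early wagers are therefore often incorrect and sharpen
  as evidence accumulates — this is what produces the early positive excess
  scores, and probability matching is the standard account of human choice
  under partial knowledge. Large `guess_sharpness` recovers a pure argmax
  wager with uniform tie breaking.

The agent enters predictive mode when the maximum smoothed successor
probability of the current symbol reaches `wager_threshold` (0.75) and stays
there with probability `wager_stickiness` (0.95) per trial; setting the
threshold to the sentinel 1.01 disables wagering entirely. Movement is
straight-line at `motor_speed` (700 px/s) with isotropic per-sample jitter
(`motor_noise_sd`, 8 px).

Reaction time is *emergent*, never injected as a function of G:

    RT = base_latency (250 ms)
       + distance-to-target at onset / motor_speed
       − expectancy_gain (120 ms) × (p̂(observed symbol) − 1/4)
       + Gaussian noise (SD 30 ms),   floored at 0.

The proximity term makes overt prediction fast; the expectancy term makes
*covert* learning fast too, so agents that never wager (the low-awareness
subset) still show G-modulated RT facilitation across trials — the
implicit-learning signature the analysis pipeline tests for. Without the
expectancy term that signature could not arise in reactive agents, whose
onset proximity is independent of G.

Recall is free generation from the learned table (uniform start symbol),
matching an "inclusion" instruction that draws on whatever the agent has
internalized; it yields recall regularity and training match that increase
with training G. Awareness is 100 + 300·logistic(5·p − 2.5) + noise
(SD 150 on the 100–400 scale, then clipped), where p is the agent's
predictive-mode proportion over the final two blocks. The noise default was
chosen so that awareness correlates ≈ 0.5 with predictive proportion, the
magnitude reported for the human cohort; because awareness depends on G only
through p, the mediation asymmetry (prediction survives partialling out G;
G does not survive partialling out prediction) is a structural property of
the generator, and the analysis stage is expected to recover it, not
assume it.

### What the simulator does not emulate

No biomechanics (minimum-jerk velocity profiles, Fitts'-law speed–accuracy
trade-offs), no oculomotor behavior, no fatigue or attention lapses, no
between-participant variation in strategy parameters beyond seeded
stochasticity. Passing tests therefore show that the *pipeline* recovers the
qualitative structure a cohort of this design would produce — not that the
generator reproduces human kinematics.

## Statistical stage

The learning model is `response ~ G + trial + G:trial` with a subject-level
random intercept (statsmodels `MixedLM`, REML), applied to RT, distance to
next, and distance from previous. Per-term F statistics are Wald z² on 1
numerator df with denominator df approximated as n_obs − rank, and are
flagged as approximate in the output; published denominator-df conventions
are not reproducible without the original data, and only coefficient signs
and significance patterns are asserted on synthetic cohorts. A singular or
non-converged mixed fit falls back to OLS with subject-clustered standard
errors, flagged in the `ModelFit`.

Block histograms of predictive proportions are tested against uniformity
over the 7 attainable values with Pearson's chi-square (df = 6). Excess
scores are tested against zero with a one-sample t (zero-variance inputs
return a flagged t = 0 or ±∞). Recall analyses use Pearson correlations and
OLS with training G as covariate. Mediation is residual-based: regress
awareness on G, correlate residuals with prediction, and symmetrically.
The low-awareness subset refits the RT model on participants reporting
awareness strictly below 250, the midpoint of the 100–400 scale ("somewhat
patterned" sits mid-scale); a cutoff at the scale ceiling is inclusive so
that it selects the full cohort. All correlations are Pearson; no
multiple-testing correction is applied.

The recall match score is the best single-diagonal alignment of the 48×24
cross-recurrence matrix over non-negative lags, denominator 24 — the
simplest operationalization of "percentage of positions that are the same"
for a 24-item recall scored against a 48-item stream. Negative lags and a
normalized longest-common-subsequence variant (`match_method: lcs`) are
config-exposed for sensitivity analysis since the published description does
not pin down lag range or denominator.

## Problem sizes and numerical choices

Property and acceptance tests use 20 independently seeded full cohorts
(143 participants each) for the stochastic signatures, 1,000 random
instances per oracle-equivalence family, and 10,000 random valid sequences
for the G bounds — sizes at which every check completes in well under two
minutes on one core while leaving the stochastic assertions far from their
thresholds. Ties in argmax wagers are broken uniformly at random under the
participant's seed; cursor positions are clipped to the canvas; the ISI-end
position interpolates linearly and never extrapolates; trials with no ISI
samples raise `MissingISIData` and are excluded, never imputed.

## Known limitations

- The mixed-model F statistics use approximate denominator df (see above).
- The published behavioral statistics (exact F, t, r values) depend on the
  original human data, which were never deposited; the pipeline asserts the
  direction and significance structure on synthetic cohorts instead.
- Agent parameters are homogeneous across the cohort; individual-difference
  distributions (e.g., mixed wager thresholds) are not modeled, although the
  reactive/predictive bimodality still emerges through sequence assignment
  and seeded learning trajectories.
- The simulator assumes free cursor placement between clicks (no return-to-
  home requirement), matching the task description.
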