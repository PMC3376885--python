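# wagertrack

Analysis pipeline for **predictive vs. reactive behavior in short-sequence
statistical learning**, measured with computer-mouse tracking.

In a mouse-tracked serial reaction time (SRT) task, stimuli appear one at a
time at four positions of a 2×2 grid following a 48-item sequence of varying
regularity, with a 750-ms inter-stimulus interval. Because the cursor is
sampled continuously (~40 Hz), anticipatory movements are directly
observable: a participant who has picked up the sequence structure will
*wager* — commit the cursor toward an expected target before it appears —
while a reactive participant waits at the previous target or "readies" at
the canvas center. `wagertrack` implements the full analysis chain for such
data, plus a synthetic-cohort generator so the chain runs end-to-end with no
external data.

## The quantities at the core

**Sequence regularity.** For a sequence over positions {1,2,3,4} with
first-order transition table rows *p*(·|*s*),

> G = 1 − (1/4) Σ_s H(s) / log₂4,  H(s) = − Σ_t p(t|s) log₂ p(t|s)

so G = 1 for fully deterministic transitions and G ≈ 0.21 at the no-repeat
floor. Training sequences (48 items, balanced, no consecutive repeats) and
24-item free-recall outputs are scored with the same statistic.

**Trajectory measures.** At the 750-ms mark of each ISI: *initial distance
to next* (Euclidean, px, to the upcoming target) and *initial distance from
previous* (axis-max, px, from the previous target). A trial is *predictive*
when the latter ≥ 275 px, *correct* when also within 100 px of the upcoming
target. Per 6-trial block: predictive proportion (7-point lattice 0…1) and
*excess score* = #predictive − #correct ∈ [0,6].

**Statistics.** A linear mixed model `measure ~ G + trial + G:trial` with a
subject random intercept; χ²(6) tests of block predictive-proportion
histograms against uniformity; one-sample t-tests of excess scores; recall
regularity and cross-recurrence match (best-diagonal % of 24) regressions
with G as covariate; residual-based mediation among G, prediction, and
awareness; and a low-awareness-subset refit (implicit learning check).

## Worked example

```python
import wagertrack as wt

# score one shipped stimulus sequence
seq = wt.stimulus_sequences()[6]          # the sequence published with G = .79
g = wt.redundancy_G(seq)
print(f"G = {g.G:.4f} (display: {g.rounded:.2f})")

# simulate the full synthetic cohort: 11 sequences x 13 agents
table = wt.load_stimulus_table()
cohort = wt.simulate_cohort(wt.stimulus_sequences(), n_per_sequence=13,
                            seed=42, sequence_ids=list(table["id"]))
feats  = wt.features_table(cohort)
blocks = wt.blocks_table(cohort)
scores = wt.score_cohort(cohort, blocks)

from wagertrack.stats import (fit_learning_model, learning_table,
                              proportion_histogram, uniformity_chisq)
fit = fit_learning_model(learning_table(feats, scores), response="rt_ms")
print(f"RT ~ G: {fit.terms['G']:.1f} ms,  trial: {fit.terms['trial']:.2f} ms,"
      f"  G x trial: {fit.terms['G:trial']:.2f} ms")

final = blocks[blocks.block == 8]
hist = proportion_histogram(final["prop_predictive"])
chi2, df, p = uniformity_chisq(hist)
print(f"final-block histogram {hist.tolist()}  chi2({df}) = {chi2:.1f}, p = {p:.3g}")
```

prints

```
G = 0.7929 (display: 0.79)
RT ~ G: -318.2 ms,  trial: 3.36 ms,  G x trial: -9.87 ms
final-block histogram [21, 0, 1, 0, 1, 12, 108]  chi2(6) = 456.7, p = 1.77e-95
```

Reading the output: the sequence's successor entropy leaves 79% redundancy.
In the simulated cohort a unit increase in G speeds responses by ~320 ms and
steepens the per-trial learning slope by ~10 ms/trial (the negative G×trial
interaction — more regular sequences are learned faster). The final-block
histogram of per-participant predictive proportions is sharply bimodal (21
participants fully reactive at 0, 108 fully predictive at 1), which the
χ²(6) test rejects as uniform at any conventional level.

A command-line interface mirrors the library:

```sh
wagertrack score-sequences                 # G for the 11 shipped sequences
wagertrack generate --target-g 0.8 --seed 7
wagertrack run-all --seed 42 --out results/
```

`run-all` writes the cohort CSVs (events, samples, participants), the
feature/block/recall tables, `analysis.json` with every fitted model and
test, and a plain-text report; reruns with the same seed and config are
byte-identical.

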