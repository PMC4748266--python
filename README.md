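# ccnorm

Noise-ceiling-aware performance metrics for models that predict neural
responses.

## The problem

Sensory neurons respond variably even to identical stimuli. The target a
stimulus-response model is scored against — the PSTH *y*, the per-bin mean
spike count over *N* repeated trials — is therefore only a noisy estimate
of the neuron's true underlying firing rate. Standard scores (Pearson
correlation, variance explained) conflate two very different failure
modes: a genuinely poor model, and an excellent model of an intrinsically
noisy neuron. A correlation of 0.5 may be either.

`ccnorm` implements the metrics that separate the two, for anyone fitting
encoding models (STRFs, LN models, neural networks) to repeated-trial
spike data:

* **Signal/noise power decomposition.** The total power
  *TP* = (1/N) Σₙ Var(Rₙ) — the average single-trial variance — splits
  into the stimulus-locked **signal power**

  *SP* = (Var(Σₙ Rₙ) − Σₙ Var(Rₙ)) / (N(N−1))

  and the **noise power** *NP = TP − SP*. Only *SP* is explainable by any
  model in principle.

* **SPE**, the signal power explained:

  *SPE* = (Var(y) − Var(y−ŷ)) / SP = (2 Cov(y,ŷ) − Var(ŷ)) / SP.

  A perfect model scores 100%; but SPE has no lower bound — a prediction
  with zero covariance to the data scores −Var(ŷ)/SP, so large, badly
  scaled predictions are punished arbitrarily while any constant
  prediction scores exactly 0.

* **CC_max**, the noise ceiling — the best correlation any model could
  achieve against an N-trial PSTH — by two routes: the classical
  split-half resampling extrapolation CC_max = √(2/(1 + 1/CC_half)), and
  the closed form CC_max = √(SP / (SP + NP/N)).

* **CC_norm**, the normalized correlation coefficient:

  *CC_norm* = CC_abs / CC_max = Cov(y,ŷ) / √(Var(ŷ)·SP)

  — Pearson's correlation with the target's variance replaced by the
  signal power. Effectively bounded in [−1, 1], insensitive to bias and
  scaling, and computable directly from SP with no resampling.

A Poisson spike-train simulator with known ground-truth rate makes every
metric verifiable end to end, and degenerate inputs (non-positive SP
estimates, constant predictions, negative split-half correlations) yield
flagged undefined results instead of exceptions or silent NaNs.

## Worked example

Simulate 20 trials of a half-rectified 2 Hz sinusoid (peak 100 spikes/s,
1 s in 5 ms bins) and score the *true* rate as the prediction — a perfect
model of a noisy neuron:

```python
from ccnorm import SimulationSpec, simulate_trials, evaluate

trials, true_rate = simulate_trials(SimulationSpec(seed=0))
report = evaluate(trials, true_rate, seed=0)
print(report.summary())
```

```
metric              value      flags
--------------------------------------------
cd                     0.8708
ve                     0.8006
spe                    0.9740
cc_abs                 0.8950
cc_half                0.7038
cc_max_split           0.9089
cc_max_direct          0.9066
cc_norm                0.9871
cc_norm_via_split      0.9846
--------------------------------------------
TP=0.2135  SP=0.04004  NP=0.1735  N=20  sp_is_valid=True
```

Although the prediction is exactly the rate that generated the data,
CC_abs reaches only 0.90: trial noise caps attainable correlation at
CC_max ≈ 0.91. Dividing out that ceiling, CC_norm ≈ 0.99 — the model is
recognized as (nearly) perfect. SPE tells the same story here (0.97), and
the split-half route agrees with the closed form to two decimals while
needing 126 resampled partitions instead of one formula.

The two metrics part ways as prediction quality falls. Mixing the
prediction with white noise (`degrade_prediction`, ŷ_α = α·w + (1−α)·ŷ,
rectified at 0) and averaging over five noise draws:

```
alpha=0.6:  mean SPE =  0.330   mean CC_norm = 0.577   CC_norm² = 0.333
alpha=0.95: mean SPE = -0.471   mean CC_norm = 0.061   CC_norm² = 0.004
```

For decent predictions SPE ≈ CC_norm²; for poor ones CC_norm² settles
near 0 while SPE plunges negative without bound — the behaviour that
makes small or negative SPE values uninterpretable and CC_norm the safer
headline metric.

The same operations are available from the shell:

```bash
ccnorm simulate -o sim --n-trials 20 --seed 0
ccnorm evaluate sim_trials.csv sim_rate.csv -o report.json
ccnorm sweep sim_trials.csv sim_rate.csv -o sweep.csv --plot sweep.png
ccnorm agreement -o agree.csv --n-sims 50
```

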