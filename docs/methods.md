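# Methods

## Model of the data

A unit's recording is `N` repeated trials × `T` time bins of spike counts
(`TrialMatrix`). The working assumption throughout is rate coding with
additive, stimulus-independent trial noise: each trial is a deterministic,
stimulus-locked rate function plus noise that is independent across trials.
The PSTH `y` (per-bin mean count) estimates that rate; its accuracy grows
with `N`. All scores compare a prediction `ŷ` (a `RateSeries` on the same
bin grid) against `y`.

Under this model the average single-trial variance over time bins — the
total power `TP = (1/N) Σₙ Var(Rₙ)` — decomposes into signal power `SP`
(variance of the deterministic part) and noise power `NP = TP − SP`.
`SP` is estimated from inter-trial agreement:

    SP = (Var(Σₙ Rₙ) − Σₙ Var(Rₙ)) / (N (N − 1))
       = (N·Var(y) − TP) / (N − 1)

This estimator is unbiased (verified by Monte-Carlo in the test suite) but
has sampling variance; on weakly driven or under-sampled units it can come
out ≤ 0, in which case it is flagged invalid.

## Scores

| score | formula | sensitive to |
|---|---|---|
| CD | 1 − Σ(y−ŷ)²/Σy² | covariance, scale, bias |
| VE | 1 − Var(y−ŷ)/Var(y) | covariance, scale |
| SPE | (2 Cov(y,ŷ) − Var(ŷ))/SP | covariance, scale |
| CC_abs | Cov(y,ŷ)/√(Var(y)Var(ŷ)) | covariance only |
| CC_norm | Cov(y,ŷ)/√(Var(ŷ)·SP) | covariance only |

The noise ceiling is computed two ways. The split-half route correlates
PSTHs from two disjoint halves of the trials, averages over splits, and
extrapolates `CC_max = √(2/(1 + 1/CC_half))` (stated for `CC_half > 0`).
The direct route is `CC_max = √(SP/(SP + NP/N))` — the square root of the
expected coherence between the true rate and an `N`-trial average — which
requires no resampling. `CC_norm = CC_abs/CC_max` equals the closed form
`Cov(y,ŷ)/√(Var(ŷ)·SP)` exactly when the direct route is used; the
resampling route is retained to demonstrate its imprecision.

SPE and CC_norm² coincide when `ŷ → y` (both reduce to `Var(y)/SP`), and
diverge as quality falls: CC_norm² → 0 for uncorrelated predictions while
SPE → −Var(ŷ)/SP, unbounded below. The `noise_sweep` experiment
reproduces this divergence; `population_summary` reports the raw mean SPE
and the mean of `max(SPE, 0)` side by side, because a few very negative
units can drag the raw population mean far down — neither summary is
substituted for the other.

## Conventions and numerical choices

* **Variance/covariance**: sample statistics (denominator `T − 1`,
  mean-subtracted) everywhere. The headline scores are ratios of
  same-convention statistics, so a consistent population convention would
  give identical values (property-tested); the sample convention matches
  common practice.
* **Units**: the PSTH is kept in mean counts per bin; spikes/s is display
  only (`RateSeries.as_hz`). All scores are invariant to a *common*
  rescaling of data and prediction. SPE is not invariant to rescaling the
  prediction alone, so a ground-truth prediction must be supplied in
  counts per bin — the simulator returns the true rate in those units for
  exactly this reason.
* **SPE route**: the covariance form `(2 Cov(y,ŷ) − Var(ŷ))/SP` is the
  implementation; it makes the constant-prediction null *exactly* zero
  (deviations of a constant are identically 0), where the
  variance-difference form could leave a rounding residue. The two forms
  agree to 1e−10 relative tolerance on randomized inputs (tested).
* **Binning**: half-open `[start, end)` bins, 0-based; a spike exactly on
  a boundary goes to the later bin. Default width 5 ms. A final partial
  bin is dropped with a logged warning — padding would distort variances.
* **Splits**: halves of size ⌊N/2⌋ and ⌈N/2⌉. Distinct unordered
  partitions are enumerated exhaustively when their number
  (C(N, N/2)/2 for even N, C(N, ⌊N/2⌋) for odd) is at most
  max(n_splits, 1000); otherwise `n_splits` random partitions are drawn
  without duplicates. Defaults: 126 splits, seed 0. Aggregation is the
  arithmetic mean of per-split correlations; Fisher-z averaging is
  available (`fisher_z=True`) but not the default, matching the practice
  the split-half estimator comes from. Splits with a constant half-PSTH
  are dropped and counted.
* **Degenerate inputs**: metrics that divide by `SP` return an undefined
  `MetricValue` carrying the raw numerator and the `SP_NONPOSITIVE` flag
  when `SP ≤ 0`; constant predictions/PSTHs, non-positive `CC_half`, and
  all-zero targets likewise yield flagged undefined values. Nothing in
  batch evaluation raises; JSON reports contain explicit nulls. Negative
  SPE is returned as computed with a `NEGATIVE_SPE` flag — it is the
  metric's documented failure mode. |CC_norm| > 1 is flagged
  (`CCNORM_EXCEEDS_ONE`, plus `CCNORM_IMPLAUSIBLE` beyond 1.5, the
  signature of a noise-dominated SP estimate); values are never clamped
  or hidden.

## Synthetic data

`SimulationSpec` defines a ground-truth rate (rectified sinusoid, constant,
or smoothed "filtered-noise" rate, all in spikes/s), and `simulate_trials`
draws independent Poisson counts per trial and bin with mean
`rate·bin_width`. Each trial consumes its own child stream of the spec
seed, so matrices are bit-reproducible and extending `N` preserves earlier
trials. The reference condition — used as the spec's defaults and by the
acceptance script — is a half-rectified 2 Hz sinusoid peaking at
100 spikes/s (0.5 counts per 5 ms bin), 20 trials of 1 s (T = 200): a
realistic desk-scale firing regime where the noise ceiling is well below 1
but SP is estimated reliably.

Poisson noise gives Fano factor 1 (tested) and analytically known
variances, which is what makes parameter-recovery oracles possible: the
mean SP over simulations converges on the variance of the true
counts-per-bin rate, and a prediction equal to the true rate recovers
SPE ≈ 100% and CC_norm ≈ 1 on average.

Predictions of graded quality are made by mixing with white noise,
`ŷ_α = max(0, α·w + (1−α)·ŷ)`, where `w` is Gaussian with the mean and
standard deviation of the clean prediction — matched scale keeps the
α-sweep comparable across noise levels. α = 0 is the identity (the sweep's
α = 0 entry equals the clean score exactly); α = 1 is rectified pure noise.

What the simulator does **not** emulate: refractoriness or renewal
statistics, correlated or non-Poisson trial noise, slow drifts in
excitability, and stimulus-to-rate structure (no receptive-field
generation). Passing tests therefore certify the estimators under the
additive, stimulus-independent noise model they assume — not robustness to
violations of it. On real recordings, non-Poisson or correlated noise
changes the SP estimator's sampling distribution (not its target), and
excessively noisy units still require the SP-validity caveats above.

## Problem sizes

The test suite and acceptance script run Monte-Carlo checks at 200–1000
simulations of the reference condition (N = 20 × T = 200 counts each),
enough to pin mean SPE to a fraction of a percentage point (observed
standard error ≈ 0.1 pp at 1000 simulations) while keeping the whole suite
fast. The sine-model example uses a 100,000-point grid over one 1 s
period, where discretization error on the extrema is far below the
quantities' scale.

## Known limitations

* `CC_half` aggregation by plain averaging is slightly biased relative to
  Fisher-z for small split counts; the closed-form route avoids the issue
  entirely and is the recommended estimator.
* For odd `N` the two half-PSTHs average different numbers of trials; the
  split-half extrapolation formula assumes equal halves, so exhaustive
  enumeration for odd `N` carries a small systematic error (the direct
  route does not).
* Segment exclusion (e.g. removing silence around stimuli before
  analysis) is left to the caller; the package scores whatever bins it is
  given.
* No confidence intervals on CC_norm beyond the per-split diagnostics.
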