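"""Correlation-based scores: CC_abs, split-half CC_half, CC_max, CC_norm.

The Pearson correlation ``CC_abs`` between PSTH and prediction is bounded
and scale/bias-insensitive, but trial-to-trial variability caps the value
even a perfect model can reach. That cap, ``CC_max``, is the correlation
between the N-trial PSTH and the true underlying rate, and can be obtained
two ways:

* **split-half route** — correlate PSTHs built from two disjoint halves of
  the trials (``CC_half``), average over splits, and extrapolate:
  ``CC_max = sqrt(2 / (1 + 1/CC_half))``. A resampling estimate: laborious
  and imprecise.
* **direct route** — from the signal/noise power decomposition:
  ``CC_max = sqrt(SP / (SP + NP/N))``, the square root of the expected
  coherence between the true rate and an N-trial average.

The noise-ceiling-corrected score is then

    CC_norm = CC_abs / CC_max = Cov(y, ŷ) / sqrt(Var(ŷ) · SP)

whose closed form needs no resampling at all. CC_norm is Pearson's
correlation with the target's variance replaced by the signal power — the
part of the variance a model could in principle explain. Values can
exceed 1 only when SP is underestimated on noisy data; they are flagged,
never silently returned as valid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence, Tuple

import numpy as np

from . import results as R
from .power_metrics import PowerDecomposition, sample_cov, sample_var, signal_power
from .results import MetricValue, defined, undefined
from .trial_data import RateSeries, TrialMatrix, compute_psth

__all__ = [
    "SplitHalfResult",
    "CCMaxResult",
    "cc_abs",
    "n_distinct_half_splits",
    "split_half_cc",
    "cc_max_from_split",
    "cc_max_direct",
    "expected_coherence",
    "cc_norm",
    "cc_norm_via_split",
]

DEFAULT_N_SPLITS = 126
EXHAUSTIVE_LIMIT = 1000


def _pearson(x: np.ndarray, y: np.ndarray) -> Optional[float]:
    """Pearson r, or None if either input is constant."""
    vx, vy = sample_var(x), sample_var(y)
    if vx == 0.0 or vy == 0.0:
        return None
    return sample_cov(x, y) / math.sqrt(vx * vy)


def cc_abs(y: RateSeries, yhat: RateSeries) -> MetricValue:
    """Pearson correlation between target and prediction, in [−1, 1]."""
    if len(y) != len(yhat):
        raise ValueError(
            f"series length mismatch: target has {len(y)} bins, prediction {len(yhat)}"
        )
    flags = []
    if sample_var(y.values) == 0.0:
        flags.append(R.CONSTANT_PSTH)
    if sample_var(yhat.values) == 0.0:
        flags.append(R.CONSTANT_PREDICTION)
    if flags:
        return undefined(*flags)
    r = _pearson(y.values, yhat.values)
    return defined(min(1.0, max(-1.0, r)))


def n_distinct_half_splits(n_trials: int) -> int:
    """Number of distinct unordered partitions of N trials into halves.

    For even N the two halves have equal size, so each partition is
    counted twice among the C(N, N/2) subsets: the count is
    C(N, N/2) / 2 (92,378 for N = 20). For odd N the halves differ in
    size and the count is C(N, ⌊N/2⌋).
    """
    if n_trials < 2:
        raise ValueError("need at least 2 trials to split")
    k = n_trials // 2
    c = math.comb(n_trials, k)
    return c // 2 if n_trials % 2 == 0 else c


@dataclass(frozen=True)
class SplitHalfResult:
    """CC_half: mean correlation between half-trial PSTHs across splits."""

    cc_half: Optional[float]
    per_split: Tuple[float, ...]
    n_splits_used: int
    exhaustive: bool
    seed: int
    n_dropped: int = 0
    flags: Tuple[str, ...] = ()

    @property
    def is_defined(self) -> bool:
        return self.cc_half is not None


def _iter_partitions(n: int, n_splits: int, rng: np.random.Generator):
    """Yield (half_a_indices, half_b_indices) distinct unordered partitions.

    Exhaustive when the partition count is small enough, otherwise
    ``n_splits`` uniform random partitions without duplicates. Halves have
    sizes ⌊N/2⌋ and ⌈N/2⌉.
    """
    k = n // 2
    total = n_distinct_half_splits(n)
    all_idx = np.arange(n)
    if total <= max(n_splits, EXHAUSTIVE_LIMIT):
        for combo in combinations(range(n), k):
            # for even N, keep only partitions whose first half contains
            # trial 0 — each unordered partition then appears exactly once
            if n % 2 == 0 and 0 not in combo:
                continue
            a = np.array(combo)
            yield a, np.setdiff1d(all_idx, a, assume_unique=True), True
    else:
        seen = set()
        while len(seen) < min(n_splits, total):
            a = np.sort(rng.choice(n, size=k, replace=False))
            key = tuple(a)
            if n % 2 == 0 and 0 not in key:
                key = tuple(np.setdiff1d(all_idx, a, assume_unique=True))
                a = np.array(key)
            if key in seen:
                continue
            seen.add(key)
            yield a, np.setdiff1d(all_idx, a, assume_unique=True), False


def split_half_cc(
    trials: TrialMatrix,
    n_splits: int = DEFAULT_N_SPLITS,
    seed: int = 0,
    fisher_z: bool = False,
) -> SplitHalfResult:
    """Correlate PSTHs from two disjoint halves of the trials.

    Distinct unordered partitions are enumerated exhaustively whenever
    their count is at most ``max(n_splits, 1000)``; otherwise ``n_splits``
    random partitions are drawn without duplicates. Splits where either
    half-PSTH is constant are dropped and counted. Aggregation is the
    arithmetic mean of per-split correlations (``fisher_z=True`` averages
    in the Fisher-z domain instead).
    """
    n = trials.n_trials
    if n < 2:
        raise ValueError(f"split-half needs at least 2 trials, got {n}")
    rng = np.random.default_rng(seed)
    per_split: list[float] = []
    n_dropped = 0
    exhaustive = True
    for a, b, exh in _iter_partitions(n, n_splits, rng):
        exhaustive = exh
        psth_a = trials.counts[a].mean(axis=0)
        psth_b = trials.counts[b].mean(axis=0)
        r = _pearson(psth_a, psth_b)
        if r is None:
            n_dropped += 1
            continue
        per_split.append(min(1.0, max(-1.0, r)))
    flags = (R.SPLITS_DROPPED,) if n_dropped else ()
    if not per_split:
        return SplitHalfResult(None, (), 0, exhaustive, seed, n_dropped,
                               flags + (R.CONSTANT_PSTH,))
    if fisher_z:
        z = np.arctanh(np.clip(per_split, -1 + 1e-15, 1 - 1e-15))
        mean_r = float(np.tanh(np.mean(z)))
    else:
        mean_r = float(np.mean(per_split))
    return SplitHalfResult(
        mean_r, tuple(per_split), len(per_split), exhaustive, seed, n_dropped, flags
    )


@dataclass(frozen=True)
class CCMaxResult:
    """The noise ceiling CC_max, with its estimation route and flags."""

    value: Optional[float]
    route: str  # "split_half" | "direct"
    flags: Tuple[str, ...] = ()
    detail: dict = field(default_factory=dict)

    @property
    def is_defined(self) -> bool:
        return self.value is not None


def cc_max_from_split(cc_half: Optional[float]) -> CCMaxResult:
    """Extrapolate CC_max from a split-half correlation.

    ``CC_max = sqrt(2 / (1 + 1/CC_half))``; stated for CC_half > 0.
    Monotone increasing, 1 at CC_half = 1, → 0 as CC_half → 0⁺.
    """
    if cc_half is None or cc_half <= 0:
        return CCMaxResult(None, "split_half", (R.CCHALF_NONPOSITIVE,),
                           {"cc_half": cc_half})
    value = math.sqrt(2.0 / (1.0 + 1.0 / cc_half))
    return CCMaxResult(min(1.0, value), "split_half", (), {"cc_half": cc_half})


def cc_max_direct(
    trials: TrialMatrix,
    decomposition: Optional[PowerDecomposition] = None,
) -> CCMaxResult:
    """CC_max straight from the power decomposition: sqrt(SP/(SP + NP/N)).

    Equivalently 1/CC_max² = 1 + (1/N)(NP/SP). No resampling involved.
    """
    dec = decomposition if decomposition is not None else signal_power(trials)
    if dec.sp <= 0:
        return CCMaxResult(None, "direct", (R.SP_NONPOSITIVE,), dec.to_dict())
    flags: Tuple[str, ...] = ()
    if dec.np < 0:
        # SP estimate overshot TP; ceiling estimate exceeds 1
        flags = (R.NP_NEGATIVE,)
    value = math.sqrt(dec.sp / (dec.sp + dec.np / dec.n_trials))
    return CCMaxResult(value, "direct", flags, dec.to_dict())


def expected_coherence(sp: float, np_: float, n: int) -> MetricValue:
    """Expected coherence γ² = SP/(SP + NP/n) between true rate and n-trial PSTH.

    Equals ``cc_max_direct`` squared on the same decomposition; → 1 as
    n → ∞ or NP → 0.
    """
    if n < 1:
        raise ValueError("n must be ≥ 1")
    if sp <= 0:
        return undefined(R.SP_NONPOSITIVE, sp=sp)
    return defined(sp / (sp + np_ / n))


def _ccnorm_flags(value: float) -> Tuple[str, ...]:
    flags: list[str] = []
    if abs(value) > 1.0:
        flags.append(R.CCNORM_EXCEEDS_ONE)
    if abs(value) > 1.5:
        # symptom of a noise-dominated SP estimate
        flags.append(R.CCNORM_IMPLAUSIBLE)
    return tuple(flags)


def cc_norm(
    trials: TrialMatrix,
    yhat: RateSeries,
    decomposition: Optional[PowerDecomposition] = None,
) -> MetricValue:
    """Closed-form normalized correlation: Cov(y,ŷ)/sqrt(Var(ŷ)·SP).

    Equals CC_abs/CC_max (direct route) whenever both are defined.
    Negative values indicate anticorrelation and are not clamped.
    """
    y = compute_psth(trials)
    if len(y) != len(yhat):
        raise ValueError(
            f"series length mismatch: PSTH has {len(y)} bins, prediction {len(yhat)}"
        )
    dec = decomposition if decomposition is not None else signal_power(trials)
    var_yhat = sample_var(yhat.values)
    flags = []
    if dec.sp <= 0:
        flags.append(R.SP_NONPOSITIVE)
    if var_yhat == 0.0:
        flags.append(R.CONSTANT_PREDICTION)
    if flags:
        return undefined(*flags, sp=dec.sp)
    value = sample_cov(y.values, yhat.values) / math.sqrt(var_yhat * dec.sp)
    return defined(value, *_ccnorm_flags(value))


def cc_norm_via_split(
    trials: TrialMatrix,
    yhat: RateSeries,
    n_splits: int = DEFAULT_N_SPLITS,
    seed: int = 0,
) -> MetricValue:
    """CC_norm by the resampling route: CC_abs / CC_max(split-half).

    Retained to demonstrate agreement with (and the imprecision relative
    to) the closed form.
    """
    y = compute_psth(trials)
    abs_r = cc_abs(y, yhat)
    split = split_half_cc(trials, n_splits=n_splits, seed=seed)
    ceiling = cc_max_from_split(split.cc_half)
    flags = tuple(abs_r.flags) + tuple(split.flags) + tuple(ceiling.flags)
    if not (abs_r.is_defined and ceiling.is_defined):
        return undefined(*flags, cc_half=split.cc_half)
    value = abs_r.value / ceiling.value
    return defined(value, *(flags + _ccnorm_flags(value)), cc_half=split.cc_half)
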