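"""Signal/noise power decomposition and variance-based scores (CD, VE, SPE).

A repeated-trial recording is modelled as a deterministic, stimulus-locked
rate plus additive trial noise that is independent of the stimulus. Under
that model the variance of a single trial (over time bins) splits into

* **total power** ``TP`` — the average single-trial variance,
* **signal power** ``SP`` — the variance of the deterministic part, the
  only part a stimulus-response model can explain in principle,
* **noise power** ``NP = TP − SP``.

``SP`` is estimated from inter-trial agreement:

    SP = (Var(Σₙ Rₙ) − Σₙ Var(Rₙ)) / (N (N − 1))

which is algebraically ``(N·Var(y) − TP) / (N − 1)`` with ``y`` the PSTH.
The estimator is unbiased but noisy: on unreliable units it can come out
non-positive, in which case every score that divides by SP is reported as
undefined rather than as a spurious (or imaginary) number.

**SPE**, the signal power explained, scores a prediction ŷ against the
PSTH y as explained over explainable power:

    SPE = (Var(y) − Var(y − ŷ)) / SP = (2 Cov(y, ŷ) − Var(ŷ)) / SP

The covariance form is the implementation route: it makes the
constant-prediction null exactly zero. SPE has no lower bound — a
prediction with zero covariance to the data scores −Var(ŷ)/SP, which is
the pathology the normalized correlation coefficient avoids.

All variances/covariances are sample statistics (denominator ``T − 1``).
The headline scores are ratios of same-convention statistics, so the
choice is immaterial to their values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import results as R
from .results import MetricValue, defined, undefined
from .trial_data import RateSeries, TrialMatrix, compute_psth

__all__ = [
    "PowerDecomposition",
    "total_power",
    "signal_power",
    "coefficient_of_determination",
    "variance_explained",
    "spe",
    "spe_covariance_form",
]


def sample_var(x: np.ndarray) -> float:
    """Sample variance over time bins (ddof=1)."""
    return float(np.var(np.asarray(x, dtype=float), ddof=1))


def sample_cov(x: np.ndarray, y: np.ndarray) -> float:
    """Sample covariance over time bins (ddof=1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx = x - x.mean()
    dy = y - y.mean()
    return float(dx @ dy / (x.size - 1))


@dataclass(frozen=True)
class PowerDecomposition:
    """TP/SP/NP for one trial matrix; ``tp == sp + np`` by construction."""

    tp: float
    sp: float
    np: float
    n_trials: int

    @property
    def sp_is_valid(self) -> bool:
        return self.sp > 0

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "sp": self.sp,
            "np": self.np,
            "n_trials": self.n_trials,
            "sp_is_valid": self.sp_is_valid,
        }


def total_power(trials: TrialMatrix) -> float:
    """Average over trials of the per-trial variance across time bins."""
    return float(np.mean([sample_var(row) for row in trials.counts]))


def signal_power(trials: TrialMatrix) -> PowerDecomposition:
    """Estimate SP from inter-trial agreement; NP = TP − SP.

    Requires N ≥ 2 (the estimator divides by N − 1). SP ≤ 0 is legal
    output — it flags a unit whose stimulus-locked signal is buried in
    sampling noise — and is marked invalid for downstream ratios.
    """
    n = trials.n_trials
    if n < 2:
        raise ValueError(f"signal power needs at least 2 trials, got {n}")
    summed = trials.counts.sum(axis=0)
    sum_of_vars = float(sum(sample_var(row) for row in trials.counts))
    sp = (sample_var(summed) - sum_of_vars) / (n * (n - 1))
    tp = sum_of_vars / n
    return PowerDecomposition(tp=tp, sp=sp, np=tp - sp, n_trials=n)


def _check_lengths(y: RateSeries, yhat: RateSeries) -> None:
    if len(y) != len(yhat):
        raise ValueError(
            f"series length mismatch: target has {len(y)} bins, prediction {len(yhat)}"
        )


def coefficient_of_determination(y: RateSeries, yhat: RateSeries) -> MetricValue:
    """CD = 1 − Σ(y−ŷ)² / Σy²: residuals relative to raw signal energy.

    Sensitive to bias: a constant offset in the prediction accumulates
    over every bin. Undefined for an all-zero target.
    """
    _check_lengths(y, yhat)
    yv, pv = y.values, yhat.values
    denom = float(yv @ yv)
    if denom == 0.0:
        return undefined(R.ALL_ZERO_PSTH)
    resid = yv - pv
    return defined(1.0 - float(resid @ resid) / denom)


def variance_explained(y: RateSeries, yhat: RateSeries) -> MetricValue:
    """VE = 1 − Var(y−ŷ)/Var(y): like CD but bias-insensitive."""
    _check_lengths(y, yhat)
    var_y = sample_var(y.values)
    if var_y == 0.0:
        return undefined(R.CONSTANT_PSTH)
    return defined(1.0 - sample_var(y.values - yhat.values) / var_y)


def spe_covariance_form(y: RateSeries, yhat: RateSeries, sp: float) -> MetricValue:
    """SPE from its covariance form (2 Cov(y,ŷ) − Var(ŷ)) / SP.

    Exactly 0 for any constant prediction. ``sp ≤ 0`` gives an undefined
    result carrying the raw numerator for diagnosis.
    """
    _check_lengths(y, yhat)
    numerator = 2.0 * sample_cov(y.values, yhat.values) - sample_var(yhat.values)
    if sp <= 0:
        return undefined(R.SP_NONPOSITIVE, numerator=numerator, sp=sp)
    value = numerator / sp
    if value < 0:
        return defined(value, R.NEGATIVE_SPE)
    return defined(value)


def spe(
    trials: TrialMatrix,
    yhat: RateSeries,
    decomposition: Optional[PowerDecomposition] = None,
) -> MetricValue:
    """Signal power explained of a prediction against a trial matrix.

    The PSTH and power decomposition are computed from ``trials`` (pass
    ``decomposition`` to reuse one). Negative values are returned as
    computed, with the ``NEGATIVE_SPE`` flag — they are the metric's
    documented failure mode, not an error.
    """
    y = compute_psth(trials)
    dec = decomposition if decomposition is not None else signal_power(trials)
    return spe_covariance_form(y, yhat, dec.sp)
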