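"""Synthetic trial matrices and degraded predictions with known ground truth.

The simulator embodies the rate-coding noise model the metrics assume: a
deterministic time-varying firing rate drives every trial, and
trial-to-trial variability enters as independent Poisson count noise per
trial and bin. Because the true rate is known, every quantity the metrics
estimate (SP, NP, CC_max, the perfect-model scores) has an analytic
reference, making the whole toolkit testable without recordings.

Predictions of varying quality are manufactured by mixing a clean
prediction with white noise and half-rectifying:

    ŷ_α = max(0, α·w + (1 − α)·ŷ),  0 ≤ α ≤ 1

where ``w`` is Gaussian noise matched in mean and standard deviation to
the clean prediction, so the sweep stays comparable in scale across α.

Units: rate functions are specified in spikes/s; the returned true-rate
series is in mean counts per bin (the PSTH's units), because a
"perfect-model" prediction must live on the same scale as the PSTH for
SPE (which is not invariant to rescaling the prediction alone).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, Tuple

import numpy as np

from .trial_data import RateSeries, TrialMatrix

__all__ = [
    "SimulationSpec",
    "DegradedPrediction",
    "rate_function",
    "simulate_trials",
    "sine_models",
    "degrade_prediction",
]


def _sinusoid(t: np.ndarray, mean: float, amplitude: float, frequency: float) -> np.ndarray:
    return mean + amplitude * np.sin(2.0 * np.pi * frequency * t)


def _constant(t: np.ndarray, rate: float) -> np.ndarray:
    return np.full_like(t, float(rate))


def _filtered_noise(
    t: np.ndarray, mean: float, sd: float, smooth_bins: int, seed: int
) -> np.ndarray:
    """Gaussian noise smoothed by a boxcar; a rough stand-in for naturalistic
    rate fluctuations. Half-rectification happens downstream."""
    rng = np.random.default_rng(seed)
    raw = rng.normal(0.0, 1.0, size=t.size)
    kernel = np.ones(max(1, smooth_bins)) / max(1, smooth_bins)
    smooth = np.convolve(raw, kernel, mode="same")
    smooth = (smooth - smooth.mean()) / (smooth.std() or 1.0)
    return mean + sd * smooth

_RATE_FUNCTIONS: Dict[str, Callable[..., np.ndarray]] = {
    "sinusoid": _sinusoid,
    "constant": _constant,
    "filtered_noise": _filtered_noise,
}


@dataclass(frozen=True)
class SimulationSpec:
    """Ground-truth rate + sampling scheme for one synthetic experiment.

    Defaults describe the reference condition used throughout the test
    suite: a half-rectified 2 Hz sinusoid peaking at 100 spikes/s
    (0.5 counts per 5 ms bin), 20 trials of 1 s. The rate is clipped at
    zero after evaluation, so a "sinusoid" with mean 0 is a half-rectified
    sinusoid.
    """

    rate_fn: str = "sinusoid"
    rate_params: Dict[str, float] = field(
        default_factory=lambda: {"mean": 0.0, "amplitude": 100.0, "frequency": 2.0}
    )
    n_trials: int = 20
    duration: float = 1.0
    bin_width: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_fn not in _RATE_FUNCTIONS:
            raise ValueError(
                f"unknown rate function {self.rate_fn!r}; "
                f"choose from {sorted(_RATE_FUNCTIONS)}"
            )
        if self.n_trials < 1:
            raise ValueError("n_trials must be ≥ 1")
        if self.duration / self.bin_width < 2:
            raise ValueError("duration/bin_width must give at least 2 bins")

    @property
    def n_bins(self) -> int:
        return int(round(self.duration / self.bin_width))

    def to_dict(self) -> dict:
        return {
            "rate_fn": self.rate_fn,
            "rate_params": dict(self.rate_params),
            "n_trials": self.n_trials,
            "duration": self.duration,
            "bin_width": self.bin_width,
            "seed": self.seed,
        }


def rate_function(spec: SimulationSpec) -> np.ndarray:
    """Evaluate the spec's rate (spikes/s) at bin centers, rectified at 0."""
    t = (np.arange(spec.n_bins) + 0.5) * spec.bin_width
    params = dict(spec.rate_params)
    if spec.rate_fn == "filtered_noise":
        params.setdefault("seed", spec.seed)
    rate = _RATE_FUNCTIONS[spec.rate_fn](t, **params)
    return np.maximum(rate, 0.0)


def simulate_trials(spec: SimulationSpec) -> Tuple[TrialMatrix, RateSeries]:
    """Draw N independent Poisson trials around the spec's rate.

    counts[n, t] ~ Poisson(rate(t) · bin_width), independent across trials
    and bins. Each trial consumes its own child stream of the spec seed,
    so matrices are bit-reproducible and extending N leaves earlier trials
    unchanged. Returns the trial matrix and the true rate in mean counts
    per bin.
    """
    rate_hz = rate_function(spec)
    mean_counts = rate_hz * spec.bin_width
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_trials)
    counts = np.stack(
        [np.random.default_rng(c).poisson(mean_counts) for c in children]
    )
    return TrialMatrix(counts, spec.bin_width), RateSeries(mean_counts, spec.bin_width)


def sine_models(
    n_points: int = 100_000, duration: float = 1.0
) -> Tuple[RateSeries, RateSeries, RateSeries]:
    """The worked two-model sine example, sampled on a fine grid (spikes/s).

    The observed response is a 1 Hz sinusoid, ±1 spikes/s around
    10 spikes/s. Model A predicts 2 Hz, ±2 spikes/s around 10 spikes/s;
    model B predicts 2 Hz, ±1 spikes/s around 100 spikes/s. Over whole
    periods the predictions are orthogonal to the response (different
    frequencies), so both models have zero covariance with the data and
    negative SPE — yet model A's worst-case discrepancy is ~3 spikes/s
    while model B's best case is ~88 spikes/s.
    """
    if abs(duration - round(duration)) > 1e-12:
        warnings.warn(
            "duration should cover an integer number of 1 Hz periods; "
            "orthogonality of the sinusoids is only exact over whole periods",
            stacklevel=2,
        )
    t = np.linspace(0.0, duration, n_points, endpoint=False)
    bw = duration / n_points
    y = RateSeries(10.0 + np.sin(2.0 * np.pi * t), bw)
    yhat_a = RateSeries(10.0 + 2.0 * np.sin(2.0 * np.pi * 2.0 * t), bw)
    yhat_b = RateSeries(100.0 + np.sin(2.0 * np.pi * 2.0 * t), bw)
    return y, yhat_a, yhat_b


@dataclass(frozen=True)
class DegradedPrediction:
    """A prediction mixed with matched white noise and rectified."""

    alpha: float
    values: RateSeries
    noise_seed: int


def degrade_prediction(
    yhat: RateSeries, alpha: float, seed: int = 0
) -> DegradedPrediction:
    """Mix a prediction with matched white noise: max(0, α·w + (1−α)·ŷ).

    ``w`` is drawn once per call, i.i.d. Gaussian per bin with the mean and
    sample standard deviation of the clean prediction. α = 0 returns the
    prediction bit-for-bit; α = 1 is rectified pure noise.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    if alpha == 0.0:
        return DegradedPrediction(0.0, yhat, seed)
    rng = np.random.default_rng(seed)
    mu = float(np.mean(yhat.values))
    sigma = float(np.std(yhat.values, ddof=1))
    w = rng.normal(mu, sigma, size=len(yhat))
    mixed = np.maximum(0.0, alpha * w + (1.0 - alpha) * yhat.values)
    return DegradedPrediction(float(alpha), RateSeries(mixed, yhat.bin_width), seed)
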