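import numpy as np
import pytest

from ccnorm import SimulationSpec, TrialMatrix, simulate_trials


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def poisson_unit():
    """One simulated unit at the reference conditions (N=20, T=200, 5 ms bins)
    with its ground-truth rate in counts/bin."""
    trials, true_rate = simulate_trials(SimulationSpec(seed=7))
    return trials, true_rate


def random_trial_matrix(rng, n_trials=8, n_bins=40, lam=2.0):
    """A generic Poisson-ish trial matrix with a structured mean rate."""
    t = np.arange(n_bins)
    rate = lam * (1.0 + 0.5 * np.sin(2 * np.pi * t / n_bins))
    counts = rng.poisson(rate, size=(n_trials, n_bins))
    return TrialMatrix(counts, 0.005)
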