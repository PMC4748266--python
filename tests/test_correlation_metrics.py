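"""CC_abs, split-half reliability, CC_max (both routes), CC_norm (both routes)."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ccnorm import (
    RateSeries,
    SimulationSpec,
    TrialMatrix,
    cc_abs,
    cc_max_direct,
    cc_max_from_split,
    cc_norm,
    cc_norm_via_split,
    compute_psth,
    expected_coherence,
    n_distinct_half_splits,
    signal_power,
    simulate_trials,
    spe,
    split_half_cc,
)
from ccnorm.power_metrics import sample_var
from conftest import random_trial_matrix

count_matrices = arrays(
    np.int64,
    st.tuples(st.integers(3, 8), st.integers(4, 16)),
    elements=st.integers(0, 8),
)


class TestCcAbs:
    def test_identity_and_affine_invariance(self, rng):
        y = RateSeries(rng.uniform(0, 5, 60))
        assert cc_abs(y, y).value == pytest.approx(1.0)
        scaled = RateSeries(3.0 * y.values + 7.0)
        assert cc_abs(y, scaled).value == pytest.approx(1.0)

    def test_orthogonal_sinusoids(self):
        t = np.linspace(0, 1, 10000, endpoint=False)
        y = RateSeries(10 + np.sin(2 * np.pi * t))
        yhat = RateSeries(10 + np.sin(2 * np.pi * 2 * t))
        assert abs(cc_abs(y, yhat).value) < 1e-10

    def test_constant_series_flagged(self):
        const = RateSeries([2.0, 2.0, 2.0])
        varying = RateSeries([1.0, 2.0, 3.0])
        r = cc_abs(varying, const)
        assert not r.is_defined and "CONSTANT_PREDICTION" in r.flags
        r = cc_abs(const, varying)
        assert not r.is_defined and "CONSTANT_PSTH" in r.flags


class TestSplitHalf:
    @pytest.mark.parametrize("n, expected", [(2, 1), (4, 3), (20, 92378), (5, 10)])
    def test_partition_counts(self, n, expected):
        assert n_distinct_half_splits(n) == expected

    def test_two_identical_trials(self):
        result = split_half_cc(TrialMatrix([[0, 2, 1], [0, 2, 1]]))
        assert result.cc_half == pytest.approx(1.0)
        assert result.exhaustive
        assert result.n_splits_used == 1  # (1/2)·C(2,1) = 1 split for N=2

    def test_exhaustive_enumeration_below_limit(self, rng):
        tm = random_trial_matrix(rng, n_trials=8, n_bins=30)  # 35 partitions
        result = split_half_cc(tm, n_splits=10)
        assert result.exhaustive
        assert result.n_splits_used == 35

    def test_random_sampling_above_limit(self, rng):
        tm = random_trial_matrix(rng, n_trials=20, n_bins=30)  # 92378 partitions
        result = split_half_cc(tm, n_splits=50, seed=3)
        assert not result.exhaustive
        assert result.n_splits_used == 50
        assert len(set(result.per_split)) > 1  # distinct partitions sampled

    def test_seed_reproducibility(self, rng):
        tm = random_trial_matrix(rng, n_trials=20, n_bins=30)
        a = split_half_cc(tm, n_splits=30, seed=9)
        b = split_half_cc(tm, n_splits=30, seed=9)
        assert a.per_split == b.per_split

    def test_odd_n_uses_floor_ceil_halves(self, rng):
        tm = random_trial_matrix(rng, n_trials=5, n_bins=30)
        result = split_half_cc(tm)
        assert result.exhaustive
        assert result.n_splits_used == 10  # C(5,2)

    def test_constant_half_psths_dropped(self):
        tm = TrialMatrix([[1, 1, 1], [1, 1, 1], [0, 1, 2], [2, 1, 0]])
        result = split_half_cc(tm)
        assert result.n_dropped > 0
        assert "SPLITS_DROPPED" in result.flags


class TestCcMax:
    @pytest.mark.parametrize(
        "cc_half, expected",
        [(1.0, 1.0), (1 / 3, math.sqrt(0.5)), (1e-6, None)],
    )
    def test_split_route_formula(self, cc_half, expected):
        result = cc_max_from_split(cc_half)
        if expected is None:
            assert result.value == pytest.approx(0.0, abs=2e-3)  # → 0 as cc_half → 0⁺
        else:
            assert result.value == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_cc_half_undefined(self):
        for bad in [0.0, -0.2, None]:
            result = cc_max_from_split(bad)
            assert not result.is_defined
            assert "CCHALF_NONPOSITIVE" in result.flags

    def test_noiseless_trials_hit_ceiling_one(self):
        tm = TrialMatrix([[0, 3, 1, 2]] * 4)
        assert cc_max_direct(tm).value == pytest.approx(1.0)

    def test_monotone_in_n(self):
        values = [expected_coherence(1.0, 1.0, n).value for n in [1, 2, 5, 20, 100]]
        assert values[0] == pytest.approx(0.5)  # SP = NP, single trial
        assert all(a < b for a, b in zip(values, values[1:]))
        assert values[-1] < 1.0 and expected_coherence(1.0, 0.0, 3).value == 1.0

    def test_coherence_matches_direct_route_squared(self, rng):
        tm = random_trial_matrix(rng, n_trials=12, n_bins=60)
        dec = signal_power(tm)
        gamma2 = expected_coherence(dec.sp, dec.np, dec.n_trials).value
        assert cc_max_direct(tm).value ** 2 == pytest.approx(gamma2, rel=1e-12)

    @given(count_matrices)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_three_algebraic_routes_agree(self, counts):
        """sqrt(SP/(SP+NP/N)), the 1 + (1/N)(NP/SP) form, and the closed
        form in Var(ΣRₙ) and ΣVar(Rₙ) agree to 1e−10."""
        tm = TrialMatrix(counts)
        dec = signal_power(tm)
        if dec.sp <= 0:
            assert not cc_max_direct(tm).is_defined
            return
        route1 = cc_max_direct(tm).value
        route2 = 1.0 / math.sqrt(1.0 + (1.0 / dec.n_trials) * (dec.np / dec.sp))
        n = tm.n_trials
        summed = tm.counts.sum(axis=0)
        sum_vars = sum(sample_var(r) for r in tm.counts)
        denom = sample_var(summed) - sum_vars
        inv_sq = (1 - 1 / n) + (1 - 1 / n) * sum_vars / denom
        route3 = 1.0 / math.sqrt(inv_sq)
        assert route1 == pytest.approx(route2, rel=1e-10)
        assert route1 == pytest.approx(route3, rel=1e-10)


class TestCcNorm:
    def test_noiseless_perfect_prediction(self):
        tm = TrialMatrix([[0, 3, 1, 2]] * 3)
        y = compute_psth(tm)
        assert cc_norm(tm, y).value == pytest.approx(1.0)
        assert cc_norm_via_split(tm, y).value == pytest.approx(1.0)

    def test_orthogonal_prediction_scores_zero(self):
        t = np.arange(100)
        counts = np.tile(np.round(5 + 4 * np.sin(2 * np.pi * t / 100)), (6, 1))
        tm = TrialMatrix(counts.astype(int))
        yhat = RateSeries(10 + np.cos(2 * np.pi * t / 100), tm.bin_width)
        y = compute_psth(tm)
        dy, dh = y.values - y.values.mean(), yhat.values - yhat.values.mean()
        assert abs(dy @ dh) < 1e-8 * np.linalg.norm(dy) * np.linalg.norm(dh)
        assert cc_norm(tm, yhat).value == pytest.approx(0.0, abs=1e-10)

    def test_equals_ccabs_over_ccmax(self, rng):
        tm = random_trial_matrix(rng, n_trials=16, n_bins=80)
        y = compute_psth(tm)
        yhat = RateSeries(y.values + rng.normal(0, 0.3, tm.n_bins), tm.bin_width)
        direct = cc_norm(tm, yhat).value
        ratio = cc_abs(y, yhat).value / cc_max_direct(tm).value
        assert direct == pytest.approx(ratio, rel=1e-10)

    def test_affine_equivariance(self, rng):
        """cc_norm(trials, a·ŷ + b) = sign(a)·cc_norm(trials, ŷ)."""
        tm = random_trial_matrix(rng, n_trials=12, n_bins=60)
        y = compute_psth(tm)
        yhat = RateSeries(y.values + rng.normal(0, 0.2, tm.n_bins), tm.bin_width)
        base = cc_norm(tm, yhat).value
        up = cc_norm(tm, RateSeries(2.5 * yhat.values + 4.0, tm.bin_width)).value
        down = cc_norm(tm, RateSeries(-1.5 * yhat.values + 9.0, tm.bin_width)).value
        assert up == pytest.approx(base, rel=1e-10)
        assert down == pytest.approx(-base, rel=1e-10)

    def test_spe_equals_ccnorm_squared_at_perfection(self, rng):
        """When ŷ = y both reduce to Var(y)/SP (squared for CC_norm)."""
        tm = random_trial_matrix(rng, n_trials=20, n_bins=100)
        y = compute_psth(tm)
        assert spe(tm, y).value == pytest.approx(cc_norm(tm, y).value ** 2, rel=1e-12)

    def test_sp_nonpositive_and_constant_prediction_flags(self):
        bad = TrialMatrix([[0, 2], [2, 0]])
        r = cc_norm(bad, RateSeries([1.0, 2.0]))
        assert not r.is_defined and "SP_NONPOSITIVE" in r.flags
        good = TrialMatrix([[0, 2, 1], [0, 2, 1]])
        r = cc_norm(good, RateSeries([3.0, 3.0, 3.0]))
        assert not r.is_defined and "CONSTANT_PREDICTION" in r.flags

    def test_out_of_range_value_is_warned_not_hidden(self):
        """A barely-positive SP inflates CC_norm past 1.5; the value is
        returned with the implausibility warning."""
        counts = np.array(
            [[2, 2, 3, 2, 2, 0, 1, 2], [5, 2, 0, 4, 2, 3, 4, 3], [2, 4, 0, 3, 2, 2, 3, 5]]
        )
        tm = TrialMatrix(counts)
        dec = signal_power(tm)
        assert 0 < dec.sp < 0.05 * dec.tp  # noise-dominated unit
        r = cc_norm(tm, compute_psth(tm))
        assert r.is_defined and abs(r.value) > 1.5
        assert "CCNORM_IMPLAUSIBLE" in r.flags
        assert "CCNORM_EXCEEDS_ONE" in r.flags

    def test_negative_cc_half_propagates_undefined(self):
        # alternating anticorrelated trials force a negative CC_half
        tm = TrialMatrix([[5, 0, 5, 0], [0, 5, 0, 5], [5, 0, 5, 0], [0, 5, 0, 5]])
        result = cc_norm_via_split(tm, RateSeries([1.0, 2.0, 1.0, 2.0]), seed=0)
        assert not result.is_defined
        assert "CCHALF_NONPOSITIVE" in result.flags


class TestSplitDirectConsistency:
    def test_split_route_tracks_direct_route_on_simulated_data(self):
        """The resampling estimate of CC_max converges on the closed form:
        with exhaustive splits the two routes agree within sampling error."""
        diffs = []
        for child in np.random.SeedSequence(11).spawn(30):
            seed = int(child.generate_state(1)[0] % 2**31)
            trials, _ = simulate_trials(SimulationSpec(seed=seed))
            direct = cc_max_direct(trials).value
            split = cc_max_from_split(split_half_cc(trials, n_splits=200, seed=seed).cc_half)
            diffs.append(split.value - direct)
        assert abs(np.mean(diffs)) < 0.03
        assert np.mean(np.abs(diffs)) < 0.05

    def test_more_splits_reduce_estimator_scatter(self):
        """Across units, the split estimate's deviation from the closed form
        shrinks as the number of splits grows."""
        spread = {}
        for n_splits in (10, 500):
            devs = []
            for child in np.random.SeedSequence(13).spawn(25):
                seed = int(child.generate_state(1)[0] % 2**31)
                trials, _ = simulate_trials(SimulationSpec(seed=seed))
                direct = cc_max_direct(trials).value
                est = cc_max_from_split(
                    split_half_cc(trials, n_splits=n_splits, seed=seed).cc_half
                ).value
                devs.append(abs(est - direct))
            spread[n_splits] = np.mean(devs)
        assert spread[500] <= spread[10] + 0.01
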