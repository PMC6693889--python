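"""Rate estimation, Z-scoring, PSTH alignment and behavioral event detection."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from prepcirc.errors import (
    DegenerateUnitError,
    EmptyAlignmentError,
    InsufficientDataError,
)
from prepcirc.rates import (
    Psth,
    RateTrace,
    ZScoreParams,
    align_psth,
    crosscov_rate_behavior,
    detect_decelerations,
    detect_lick_bout_starts,
    estimate_rate,
    group_trials_by_dip,
    zscore,
    zscore_psth,
)
from prepcirc.session import BehaviorTrace


class TestEstimateRate:
    def test_sigma_is_median_isi(self):
        spikes = np.concatenate([[10.0], 20.0 + np.arange(30)])  # 1 Hz regular train
        trace = estimate_rate(spikes, 60.0)
        assert trace.kernel_sigma == pytest.approx(1.0)

    def test_kernel_mass_conservation(self):
        rng = np.random.default_rng(0)
        spikes = np.sort(rng.uniform(5.0, 55.0, 200))
        trace = estimate_rate(spikes, 60.0)
        integral = trace.rate.sum() / trace.fs
        assert integral == pytest.approx(200, rel=0.01)

    def test_homogeneous_poisson_rate(self):
        rng = np.random.default_rng(1)
        lam, T = 20.0, 100.0
        spikes = np.sort(rng.uniform(0, T, rng.poisson(lam * T)))
        trace = estimate_rate(spikes, T)
        se = np.sqrt(lam / T)
        assert abs(trace.rate[5000:-5000].mean() - lam) < 3 * se

    def test_too_few_spikes(self):
        with pytest.raises(InsufficientDataError):
            estimate_rate(np.array([1.0]), 10.0)


class TestZScore:
    def test_whole_recording_normalization_exact(self):
        rng = np.random.default_rng(2)
        z, params = zscore(rng.gamma(2.0, 3.0, 5000))
        assert abs(z.mean()) < 1e-9
        assert abs(z.std(ddof=0) - 1.0) < 1e-9
        assert params.sd > 0

    def test_constant_trace_errors(self):
        with pytest.raises(DegenerateUnitError):
            zscore(np.full(100, 7.0))

    def test_baseline_mode_zero_mean_in_window(self):
        # per-trial jitter around the baseline mean -> mean Z over the window is 0
        row = np.concatenate([np.full(50, 4.0), np.linspace(4, 9, 70)])
        mat = np.vstack([row - 0.1, row + 0.1, row - 0.2, row + 0.2])
        psth = Psth("reward", (-12.0, 0.0), 0.1, mat)
        z = zscore_psth(psth, ZScoreParams(mode="baseline_window", baseline_window=(-11.0, -8.0)))
        c = z.bin_centers
        m = (c >= -11.0) & (c < -8.0)
        assert abs(z.matrix[:, m].mean()) < 1e-12


class TestAlignPsth:
    def test_identity_ramp_closed_form(self):
        fs = 1000.0
        trace = RateTrace(np.arange(int(200 * fs)) / fs, fs)
        psth = align_psth(trace, np.array([100.0]), (-1.0, 1.0), 0.5)
        np.testing.assert_allclose(
            psth.matrix[0], [99.25, 99.75, 100.25, 100.75], atol=1e-3
        )

    def test_identical_trials_have_zero_sd(self):
        fs = 100.0
        sig = np.tile(np.sin(np.arange(1000) / 50), 3)
        trace = RateTrace(np.concatenate([sig, sig]), fs)
        psth = align_psth(trace, np.array([10.0, 40.0]), (-2.0, 2.0), 0.1)
        np.testing.assert_allclose(psth.sd(), 0.0, atol=1e-12)

    def test_truncated_events_dropped_and_counted(self):
        trace = RateTrace(np.ones(1000), 100.0)
        psth = align_psth(trace, np.array([0.5, 5.0, 9.9]), (-1.0, 1.0), 0.5)
        assert psth.matrix.shape[0] == 1
        assert psth.n_dropped == 2

    def test_no_event_errors(self):
        trace = RateTrace(np.ones(100), 100.0)
        with pytest.raises(EmptyAlignmentError):
            align_psth(trace, np.array([0.1]), (-2.0, 2.0), 0.5)

    def test_constant_signal_gives_constant_psth(self):
        trace = RateTrace(np.full(10000, 3.3), 1000.0)
        psth = align_psth(trace, np.array([3.0, 6.0]), (-1.0, 1.0), 0.1)
        np.testing.assert_allclose(psth.matrix, 3.3)


class TestDecelerations:
    @staticmethod
    def _square_wave():
        # 40 cm/s for 5 s, 0 for 2 s, repeated
        block = np.concatenate([np.full(500, 40.0), np.zeros(200)])
        v = np.tile(block, 4)
        return BehaviorTrace(100.0, v, np.zeros_like(v))

    def test_square_wave_one_event_per_falling_edge(self):
        events = detect_decelerations(self._square_wave(), [])
        assert events.size == 4

    def test_constant_speed_no_events(self):
        b = BehaviorTrace(100.0, np.full(2000, 40.0), np.zeros(2000))
        assert detect_decelerations(b, []).size == 0

    def test_exclusion_window_invariance(self):
        b = self._square_wave()
        base = detect_decelerations(b, [])
        # exclude the second dip; remaining events unchanged
        t2 = base[1]
        kept = detect_decelerations(b, [(t2 - 0.5, t2 + 0.5)])
        np.testing.assert_allclose(kept, np.delete(base, 1))


class TestLickBouts:
    def test_train_start_rule(self):
        starts = detect_lick_bout_starts(np.array([10.0, 10.1, 10.2, 15.0]), [], min_gap=1.0)
        np.testing.assert_allclose(starts, [10.0, 15.0])

    def test_empty(self):
        assert detect_lick_bout_starts(np.array([]), []).size == 0

    def test_exclusion(self):
        starts = detect_lick_bout_starts(
            np.array([10.0, 10.1, 15.0]), [(14.0, 16.0)], min_gap=1.0
        )
        np.testing.assert_allclose(starts, [10.0])


class TestCrossCovariance:
    def test_shifted_signal_peaks_at_shift(self, rng):
        fs = 1000.0
        n = int(120 * fs)
        base = np.repeat(rng.standard_normal(n // 100), 100)  # slow signal
        shift = int(0.5 * fs)
        rate = RateTrace(base, fs)
        behavior = np.roll(base, shift)[:: int(fs / 100)]  # behavior lags the rate
        lags, cov, peak = crosscov_rate_behavior(rate, behavior)
        assert peak == pytest.approx(0.5, abs=0.02)

    def test_negated_signal_trough_at_zero(self, rng):
        fs = 1000.0
        base = np.repeat(rng.standard_normal(6000), 100)
        rate = RateTrace(base, fs)
        lags, cov, peak = crosscov_rate_behavior(rate, -base[:: int(fs / 100)])
        assert peak == pytest.approx(0.0, abs=0.02)
        assert cov[np.argmin(np.abs(lags))] < 0

    def test_antisymmetry_under_swap(self, rng):
        fs = 1000.0
        a = np.repeat(rng.standard_normal(3000), 100)
        b = np.repeat(rng.standard_normal(3000), 100)
        dec = int(fs / 100)
        _, cov_ab, _ = crosscov_rate_behavior(RateTrace(a, fs), b[::dec])
        _, cov_ba, _ = crosscov_rate_behavior(RateTrace(b, fs), a[::dec])
        np.testing.assert_allclose(cov_ab, cov_ba[::-1], atol=1e-10)

    def test_independent_white_sequences_stay_small(self, rng):
        fs = 1000.0
        n_fail = 0
        for _ in range(20):
            a = np.repeat(rng.standard_normal(12000), 100)
            b = rng.standard_normal(12000)
            _, cov, _ = crosscov_rate_behavior(RateTrace(a, fs), b)
            se = 1.0 / np.sqrt(12000)
            n_fail += int(np.max(np.abs(cov)) >= 4 * se)
        assert n_fail <= 2  # |cov| < 4 SE at all lags in ~95% of runs (2.5%/run familywise)


class TestDipGrouping:
    @staticmethod
    def _behavior_with_dips(dips, fs=100.0, reward_gap=20.0):
        # speed 40 except a dip to 10 at (reward + dip) for each trial
        n = int(len(dips) * reward_gap * fs)
        v = np.full(n, 40.0)
        rewards = []
        for k, d in enumerate(dips):
            r = (k + 1) * reward_gap - 5.0
            rewards.append(r)
            i = int((r + d) * fs)
            v[i : i + 20] = 10.0
        return BehaviorTrace(fs, v, np.zeros(n)), np.array(rewards)

    def test_three_dips_one_per_group(self):
        b, rewards = self._behavior_with_dips([-3.0, -2.0, -1.0])
        groups, excluded = group_trials_by_dip(b, rewards)
        assert [len(g) for g in groups] == [1, 1, 1]
        assert excluded == 0

    def test_ties_split_stably_by_trial_order(self):
        b, rewards = self._behavior_with_dips([-2.0] * 6)
        groups, _ = group_trials_by_dip(b, rewards)
        assert [sorted(g.tolist()) for g in groups] == [[0, 1], [2, 3], [4, 5]]

    def test_no_dip_trials_excluded(self):
        b, rewards = self._behavior_with_dips([-3.0, -2.0, -1.0, -2.5])
        # remove the last dip by overwriting with cruise speed
        b.running_speed[int((rewards[3] - 4) * 100) :] = 40.0
        groups, excluded = group_trials_by_dip(b, rewards)
        assert excluded == 1

    def test_too_few_dips_error(self):
        b, rewards = self._behavior_with_dips([-2.0, -1.0])
        with pytest.raises(InsufficientDataError):
            group_trials_by_dip(b, rewards)


@given(
    st.lists(st.floats(min_value=0.1, max_value=99.0), min_size=0, max_size=30),
    st.floats(min_value=0.2, max_value=3.0),
)
def test_lick_bout_property_gap_rule(licks, gap):
    """Every returned start is a lick preceded by >= gap without licks."""
    licks = np.sort(np.asarray(licks, dtype=float))
    starts = detect_lick_bout_starts(licks, [], min_gap=gap)
    for s in starts:
        prior = licks[(licks < s) & (licks >= s - gap)]
        assert prior.size == 0
        assert s in licks
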