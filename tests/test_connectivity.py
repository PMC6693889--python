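"""Cross-correlograms, modulation calls, shuffle correction, pair covariance."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from prepcirc.connectivity import (
    Ccg,
    brute_force_ccg,
    compute_ccg,
    crosscov_pair,
    detect_modulation,
    shuffle_corrected_ccg,
    strength_vs_profile_regression,
)
from prepcirc.errors import InsufficientDataError
from prepcirc.rates import RateTrace


class TestComputeCcg:
    def test_single_pair_lands_in_3ms_bin(self):
        ccg = compute_ccg(np.array([1.0]), np.array([1.003]))
        assert ccg.counts.sum() == 1
        assert ccg.lags_ms[np.argmax(ccg.counts)] == 3.0

    def test_symmetry_under_swap(self, rng):
        a = np.sort(rng.uniform(0, 30, 400))
        b = np.sort(rng.uniform(0, 30, 400))
        ab = compute_ccg(a, b).counts
        ba = compute_ccg(b, a).counts
        np.testing.assert_array_equal(ab, ba[::-1])

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(4):
            a = np.sort(rng.uniform(0, 40, 600))
            b = np.sort(rng.uniform(0, 40, 600))
            np.testing.assert_array_equal(compute_ccg(a, b).counts, brute_force_ccg(a, b))

    def test_count_conservation(self, rng):
        a = np.sort(rng.uniform(0, 20, 300))
        b = np.sort(rng.uniform(0, 20, 300))
        total = compute_ccg(a, b).counts.sum()
        manual = sum(int(np.sum(np.abs(b - r) < 0.05)) for r in a)
        # bin-edge membership may shift a lag across the +-50 ms boundary only
        assert abs(total - manual) <= np.sum(np.isclose(np.abs(a[:, None] - b), 0.05))

    def test_translation_invariance(self, rng):
        a = np.sort(rng.uniform(0, 20, 200))
        b = np.sort(rng.uniform(0, 20, 200))
        np.testing.assert_array_equal(
            compute_ccg(a, b).counts, compute_ccg(a + 123.4, b + 123.4).counts
        )

    def test_autocorrelation_excludes_self_pairs(self, rng):
        a = np.sort(rng.uniform(0, 10, 100))
        acg = compute_ccg(a, a)
        zero_bin = acg.counts[np.flatnonzero(acg.lags_ms == 0.0)[0]]
        # ordered pairs with 0 <= lag < 1 ms, self-pairs excluded
        expected = (np.sum(np.abs(a[:, None] - a) < 1e-3) - 100) / 2
        assert zero_bin == pytest.approx(expected)

    def test_empty_train_errors(self):
        with pytest.raises(InsufficientDataError):
            compute_ccg(np.array([]), np.array([1.0]))


class TestDetectModulation:
    @staticmethod
    def _ccg_with(zvals: dict, base_mean=100.0, base_sd=10.0):
        lags = -50.0 + np.arange(100)
        counts = np.full(100, base_mean)
        counts[: 40 : 2] += base_sd  # baseline variance in [-50, -10)
        counts[1:40:2] -= base_sd
        m = counts[:40].mean()
        sd = counts[:40].std(ddof=0)
        for lag, z in zvals.items():
            counts[np.flatnonzero(lags == lag)[0]] = m + z * sd
        return Ccg(lags, counts)

    def test_flat_z_not_modulated(self):
        ccg = Ccg(-50.0 + np.arange(100), np.full(100, 5.0))
        call = detect_modulation(ccg)
        assert not call.modulated and call.undecidable

    def test_two_consecutive_troughs_inhibited(self):
        call = detect_modulation(self._ccg_with({2.0: -4.0, 3.0: -4.0}))
        assert call.modulated and call.sign == "inhibited"
        assert call.strength < 0
        assert call.first_lag_ms == 2.0

    def test_single_bin_not_enough(self):
        call = detect_modulation(self._ccg_with({2.0: -5.0}))
        assert not call.modulated

    def test_one_sided_option_ignores_troughs(self):
        call = detect_modulation(self._ccg_with({2.0: -4.0, 3.0: -4.0}), two_sided=False)
        assert not call.modulated
        call = detect_modulation(self._ccg_with({2.0: 4.0, 3.0: 4.0}), two_sided=False)
        assert call.modulated and call.sign == "excited"

    def test_strength_window_is_1_to_7ms(self):
        # deviation outside (1,7] must not affect the strength
        a = detect_modulation(self._ccg_with({0.0: -6.0, 2.0: -4.0, 3.0: -4.0}))
        b = detect_modulation(self._ccg_with({2.0: -4.0, 3.0: -4.0}))
        assert a.strength == pytest.approx(b.strength)


class TestShuffleCorrection:
    def test_identical_trains_every_trial_cancel(self):
        rng = np.random.default_rng(3)
        rewards = 15.0 * (np.arange(12) + 1.0)
        pat_a = np.sort(rng.uniform(-10, 0, 120))
        pat_b = np.sort(rng.uniform(-10, 0, 120))
        ref = np.sort(np.concatenate([r + pat_a for r in rewards]))
        tgt = np.sort(np.concatenate([r + pat_b for r in rewards]))
        sc = shuffle_corrected_ccg(ref, tgt, rewards)
        ok = np.isfinite(sc.corrected)
        np.testing.assert_allclose(sc.corrected[ok], 0.0, atol=1e-9)

    def test_connected_pair_trough_survives_correction(self):
        from prepcirc.synth import Connection, GenConfig, UnitSpec, generate_session

        roster = [
            UnitSpec("pc", "CRUS1", "pc",
                     tuning={"kind": "linear", "a": 40.0, "b": 0.2}, suppression=0.3),
            UnitSpec("dn", "DN", "dn", baseline=25.0, amp=10.0),
        ]
        cfg = GenConfig(n_trials=60, roster=roster, connections=[Connection("pc", "dn", 0.7)])
        session, _, _ = generate_session(cfg, 19)
        sc = shuffle_corrected_ccg(
            session.spikes["pc"], session.spikes["dn"], session.events.reward_times
        )
        trough = (sc.lags_ms >= 1.0) & (sc.lags_ms < 5.0)
        base = (sc.lags_ms >= -50.0) & (sc.lags_ms < -10.0)
        assert np.nanmean(sc.corrected[trough]) < -0.5
        assert abs(np.nanmean(sc.corrected[base])) < 0.3

    def test_too_few_trials_errors(self):
        with pytest.raises(InsufficientDataError):
            shuffle_corrected_ccg(np.array([1.0]), np.array([2.0]), np.array([5.0]))


class TestCrossCovPair:
    @staticmethod
    def _trace(values, fs=200.0):
        return RateTrace(np.asarray(values, dtype=float), fs)

    def test_antiphase_rates_negative_at_zero(self, rng):
        # anti-correlation that is NOT trial-locked survives the shuffle correction
        fs = 200.0
        n = int(400 * fs)
        slow = np.repeat(rng.standard_normal(n // 40), 40)
        a = self._trace(30 + 5 * slow, fs)
        b = self._trace(30 - 5 * slow, fs)
        rewards = 20.0 * (np.arange(15) + 1.0)
        lags, cov = crosscov_pair(a, b, rewards)
        assert cov[np.argmin(np.abs(lags))] < -0.5

    def test_normalization_bounded(self, rng):
        fs = 200.0
        n = int(300 * fs)
        a = self._trace(np.repeat(rng.standard_normal(n // 20), 20), fs)
        b = self._trace(np.repeat(rng.standard_normal(n // 20), 20), fs)
        rewards = 15.0 * (np.arange(15) + 1.0)
        _, cov = crosscov_pair(a, b, rewards)
        assert np.max(np.abs(cov)) <= 1.0 + 0.2

    def test_independent_rates_near_zero(self, rng):
        fs = 200.0
        n = int(500 * fs)
        rewards = 15.0 * (np.arange(30) + 1.0)
        maxima = []
        for _ in range(5):
            a = self._trace(np.repeat(rng.standard_normal(n // 20), 20), fs)
            b = self._trace(np.repeat(rng.standard_normal(n // 20), 20), fs)
            _, cov = crosscov_pair(a, b, rewards)
            maxima.append(np.max(np.abs(cov)))
        # shuffle-corrected covariance of independent pairs: small at all lags
        assert np.median(maxima) < 0.1


class TestStrengthRegression:
    def test_collinear_recovers_slope(self, rng):
        centers = np.linspace(-7.95, 1.95, 100)
        pcs, dns, strengths = [], [], []
        for i in range(10):
            p = rng.standard_normal(100)
            q = rng.standard_normal(100)
            w = i / 9.0
            d = w * p + (1 - w) * q  # rho increases with w
            from scipy.stats import spearmanr

            m = (centers >= -5.0) & (centers < 0.0)
            rho = spearmanr(p[m], d[m]).statistic
            pcs.append(p)
            dns.append(d)
            strengths.append(2.0 * rho)
        res = strength_vs_profile_regression(np.array(strengths), pcs, dns, centers)
        assert res["slope"] == pytest.approx(2.0, abs=1e-6)
        assert res["intercept"] == pytest.approx(0.0, abs=1e-6)

    def test_constant_profiles_dropped(self, rng):
        centers = np.linspace(-7.95, 1.95, 100)
        pcs = [np.zeros(100)] + [rng.standard_normal(100) for _ in range(4)]
        dns = [rng.standard_normal(100) for _ in range(5)]
        res = strength_vs_profile_regression(np.ones(5), pcs, dns, centers)
        assert 0 not in res["pairs_used"]

    def test_null_strengths_nonsignificant_mostly(self, rng):
        centers = np.linspace(-7.95, 1.95, 80)
        n_sig = 0
        for _ in range(30):
            pcs = [rng.standard_normal(80) for _ in range(12)]
            dns = [rng.standard_normal(80) for _ in range(12)]
            strengths = np.full(12, -3.0) + rng.normal(0, 0.1, 12)
            res = strength_vs_profile_regression(strengths, pcs, dns, centers)
            n_sig += int(res["f_pvalue"] <= 0.05)
        assert n_sig <= 3  # p > 0.05 in >= 90% of null simulations


@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_ccg_oracle_property(seed):
    rng = np.random.default_rng(seed)
    a = np.sort(rng.uniform(0, 5, 40))
    b = np.sort(rng.uniform(0, 5, 40))
    np.testing.assert_array_equal(compute_ccg(a, b).counts, brute_force_ccg(a, b))
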