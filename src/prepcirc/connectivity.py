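"""Pairwise cross-correlogram analysis and monosynaptic connection calls.

The cross-correlogram (CCG) between a reference train (a Purkinje cell) and
a target train (a dentate-nucleus neuron) counts target spikes at 1-ms lags
within +-50 ms of each reference spike.  A pair is called modulated when at
least two consecutive bins in the 10 ms after the reference spike deviate by
more than 3 SD from a baseline computed in the [-50, -10) ms window; the
connection strength is the mean Z-scored count between 1 and 7 ms, its sign
splitting pairs into excited and inhibited.  Slow, stimulus-locked
co-modulation is removed with an adjacent-trial shuffle predictor,
(CC_raw - CC_shuffled) / sqrt(CC_shuffled), computed in the last 10 s before
each reward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from .errors import DegenerateUnitError, InsufficientDataError, PrepcircError


@dataclass
class Ccg:
    lags_ms: np.ndarray          # left bin edges, ms
    counts: np.ndarray
    bin_ms: float = 1.0
    baseline_window_ms: tuple = (-50.0, -10.0)

    def zscored(self) -> np.ndarray:
        m, sd = self.baseline_stats()
        if sd <= 0:
            raise DegenerateUnitError("zero baseline SD in CCG")
        return (self.counts - m) / sd

    def baseline_stats(self) -> tuple[float, float]:
        a, b = self.baseline_window_ms
        mask = (self.lags_ms >= a) & (self.lags_ms < b)
        base = self.counts[mask]
        return float(base.mean()), float(base.std(ddof=0))


@dataclass
class ConnectionCall:
    modulated: bool
    sign: str | None             # 'inhibited' | 'excited' | None
    strength: float              # mean Z over (1, 7] ms
    first_lag_ms: float | None   # left edge of the first significant bin
    undecidable: bool = False


@dataclass
class ShuffleCcg:
    lags_ms: np.ndarray
    cc_raw: np.ndarray
    cc_shuffled: np.ndarray
    corrected: np.ndarray        # (raw - shuf)/sqrt(shuf); NaN where shuf == 0
    n_trials: int


def _pair_lags(ref: np.ndarray, target: np.ndarray, half_window: float, same_train: bool):
    """All (target - ref) lags within +-half_window, vectorized via searchsorted."""
    lo = np.searchsorted(target, ref - half_window, side="left")
    hi = np.searchsorted(target, ref + half_window, side="left")
    counts = hi - lo
    total = int(counts.sum())
    if total == 0:
        return np.empty(0)
    # expand [lo_i, hi_i) index ranges without a python loop
    rep_ref = np.repeat(ref, counts)
    starts = np.repeat(lo, counts)
    within = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
    tgt_idx = starts + within
    lags = target[tgt_idx] - rep_ref
    if same_train:
        ref_idx = np.repeat(np.arange(ref.size), counts)
        lags = lags[ref_idx != tgt_idx]
    return lags


def compute_ccg(
    ref_spikes: np.ndarray,
    target_spikes: np.ndarray,
    bin_ms: float = 1.0,
    half_window_ms: float = 50.0,
) -> Ccg:
    """Count target spikes in 1-ms lag bins [k, k+1) ms around each reference spike.

    Equals the brute-force double loop exactly.  When the same array is passed
    for both trains, identical-spike (zero-lag self) pairs are excluded.
    """
    ref = np.asarray(ref_spikes, dtype=float)
    target = np.asarray(target_spikes, dtype=float)
    if ref.size == 0 or target.size == 0:
        raise InsufficientDataError("CCG requires two non-empty spike trains")
    hw = half_window_ms * 1e-3
    lags = _pair_lags(ref, target, hw, same_train=ref is target_spikes or ref is target)
    n_bins = int(round(2 * half_window_ms / bin_ms))
    edges_ms = -half_window_ms + bin_ms * np.arange(n_bins + 1)
    k = np.floor(lags * 1e3 / bin_ms + 1e-6).astype(int) + n_bins // 2
    k = k[(k >= 0) & (k < n_bins)]
    counts = np.bincount(k, minlength=n_bins).astype(float)
    return Ccg(lags_ms=edges_ms[:-1], counts=counts, bin_ms=bin_ms)


def detect_modulation(
    ccg: Ccg,
    n_sd: float = 3.0,
    search_ms: tuple = (0.0, 10.0),
    strength_ms: tuple = (1.0, 7.0),
    two_sided: bool = True,
) -> ConnectionCall:
    """Monosynaptic modulation call from a single CCG.

    Modulated iff >= 2 consecutive bins in the 10 ms after the reference
    spike have |Z| > ``n_sd`` (Z against the raw-count baseline in
    [-50, -10) ms).  ``two_sided=False`` restores a purely excitatory
    (upward) criterion.
    """
    m, sd = ccg.baseline_stats()
    if sd <= 0:
        return ConnectionCall(False, None, float("nan"), None, undecidable=True)
    z = (ccg.counts - m) / sd
    sm = (ccg.lags_ms >= search_ms[0]) & (ccg.lags_ms < search_ms[1])
    zz = z[sm]
    dev = np.abs(zz) if two_sided else zz
    hits = dev > n_sd
    consec = hits[:-1] & hits[1:]
    modulated = bool(consec.any())
    # (1, 7] ms with 1-ms bins -> left edges 1..6
    st_m = (ccg.lags_ms >= strength_ms[0]) & (ccg.lags_ms < strength_ms[1])
    strength = float(z[st_m].mean())
    if not modulated:
        return ConnectionCall(False, None, strength, None)
    first = float(ccg.lags_ms[sm][np.flatnonzero(consec)[0]])
    sign = "inhibited" if strength < 0 else "excited"
    return ConnectionCall(True, sign, strength, first)


def shuffle_corrected_ccg(
    ref_spikes: np.ndarray,
    target_spikes: np.ndarray,
    reward_times: np.ndarray,
    window_s: float = 10.0,
    bin_ms: float = 1.0,
    half_window_ms: float = 50.0,
) -> ShuffleCcg:
    """Adjacent-trial shuffle-corrected CCG in the last ``window_s`` before reward.

    CC_raw averages the within-trial CCG; CC_shuffled pairs the reference
    train of trial n with the target train of trial n+1 (both re-referenced
    to their own reward), removing stimulus-locked co-modulation.
    """
    rewards = np.asarray(reward_times, dtype=float)
    rewards = rewards[np.isfinite(rewards)]
    if rewards.size < 2:
        raise InsufficientDataError("shuffle correction needs >= 2 trials")
    hw = half_window_ms * 1e-3
    n_bins = int(round(2 * half_window_ms / bin_ms))
    edges_ms = -half_window_ms + bin_ms * np.arange(n_bins + 1)

    def _rel(spk: np.ndarray, r: float) -> np.ndarray:
        s = spk[(spk >= r - window_s) & (spk < r)]
        return s - r

    refs = [_rel(np.asarray(ref_spikes, float), r) for r in rewards]
    tgts = [_rel(np.asarray(target_spikes, float), r) for r in rewards]

    def _counts(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        if a.size == 0 or b.size == 0:
            return np.zeros(n_bins)
        lags = _pair_lags(a, b, hw, same_train=False)
        k = np.floor(lags * 1e3 / bin_ms + 1e-6).astype(int) + n_bins // 2
        k = k[(k >= 0) & (k < n_bins)]
        return np.bincount(k, minlength=n_bins).astype(float)

    raw = np.mean([_counts(refs[i], tgts[i]) for i in range(len(rewards))], axis=0)
    shuf = np.mean([_counts(refs[i], tgts[i + 1]) for i in range(len(rewards) - 1)], axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        corrected = np.where(shuf > 0, (raw - shuf) / np.sqrt(shuf), np.nan)
    return ShuffleCcg(edges_ms[:-1], raw, shuf, corrected, int(rewards.size))


def crosscov_pair(
    pc_rate,
    dn_rate,
    reward_times: np.ndarray,
    window_s: float = 10.0,
    bin_s: float = 0.005,
    max_lag: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Shuffle-corrected, variance-normalized PC-DN rate cross-covariance.

    ``pc_rate`` / ``dn_rate`` are RateTrace-like objects with a ``sample``
    method.  Per trial, both rates are binned at 5 ms over the last
    ``window_s`` before reward; the trial-wise cross-covariance minus the
    adjacent-trial (shuffled) cross-covariance is normalized by
    sqrt(var(pc) * var(dn)).  Returns (lags_s, covariance).
    """
    rewards = np.asarray(reward_times, dtype=float)
    rewards = rewards[np.isfinite(rewards)]
    if rewards.size < 2:
        raise InsufficientDataError("pair cross-covariance needs >= 2 trials")
    n_bins = int(round(window_s / bin_s))
    rel = -window_s + bin_s * (np.arange(n_bins) + 0.5)
    P = np.vstack([pc_rate.sample(r + rel) for r in rewards])
    D = np.vstack([dn_rate.sample(r + rel) for r in rewards])
    P = P - P.mean(axis=1, keepdims=True)
    D = D - D.mean(axis=1, keepdims=True)
    var_p = float(P.var())
    var_d = float(D.var())
    if var_p <= 0 or var_d <= 0:
        raise DegenerateUnitError("zero rate variance in cross-covariance")
    k_max = int(round(max_lag / bin_s))
    lags = np.arange(-k_max, k_max + 1) * bin_s
    raw = np.zeros(lags.size)
    shuf = np.zeros(lags.size)
    nt = rewards.size
    for i, k in enumerate(range(-k_max, k_max + 1)):
        if k >= 0:
            a = slice(0, n_bins - k)
            b = slice(k, n_bins)
        else:
            a = slice(-k, n_bins)
            b = slice(0, n_bins + k)
        raw[i] = np.mean(P[:, a] * D[:, b])
        shuf[i] = np.mean(P[: nt - 1, a] * D[1:, b])
    return lags, (raw - shuf) / np.sqrt(var_p * var_d)


def strength_vs_profile_regression(
    strengths: np.ndarray,
    pc_profiles: list,
    dn_profiles: list,
    bin_centers: np.ndarray,
    window: tuple = (-5.0, 0.0),
):
    """OLS of connection strength on the Spearman rho of the pair's profiles.

    Profiles are baseline-Z PSTHs around reward; rho is computed over the
    ``window`` (default the 5 s before reward).  Returns a dict with slope,
    intercept, their 95% CI, the F-test p-value, and the per-pair rho.
    """
    import statsmodels.api as sm

    strengths = np.asarray(strengths, dtype=float)
    m = (bin_centers >= window[0]) & (bin_centers < window[1])
    rhos, keep = [], []
    for i, (p, d) in enumerate(zip(pc_profiles, dn_profiles)):
        pp, dd = np.asarray(p)[m], np.asarray(d)[m]
        if np.std(pp) == 0 or np.std(dd) == 0:
            continue  # constant profile: pair dropped
        rhos.append(spearmanr(pp, dd).statistic)
        keep.append(i)
    if len(keep) < 3:
        raise InsufficientDataError("need >= 3 pairs with non-constant profiles")
    rho = np.asarray(rhos)
    y = strengths[keep]
    Xd = sm.add_constant(rho)
    fit = sm.OLS(y, Xd).fit()
    ci = fit.conf_int()
    return {
        "slope": float(fit.params[1]),
        "intercept": float(fit.params[0]),
        "slope_ci": (float(ci[1][0]), float(ci[1][1])),
        "f_pvalue": float(fit.f_pvalue),
        "rho": rho,
        "pairs_used": keep,
    }


def brute_force_ccg(
    ref_spikes: np.ndarray,
    target_spikes: np.ndarray,
    bin_ms: float = 1.0,
    half_window_ms: float = 50.0,
) -> np.ndarray:
    """O(n^2) oracle for compute_ccg (test/validation use only)."""
    n_bins = int(round(2 * half_window_ms / bin_ms))
    counts = np.zeros(n_bins)
    for r in np.asarray(ref_spikes, dtype=float):
        for s in np.asarray(target_spikes, dtype=float):
            lag_ms = (s - r) * 1e3
            k = int(np.floor(lag_ms / bin_ms + 1e-6)) + n_bins // 2
            if 0 <= k < n_bins:
                counts[k] += 1
    return counts
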