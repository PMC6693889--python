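"""Firing-rate estimation, Z-scoring, event alignment and behavioral events.

The continuous firing rate of a unit is the Gaussian kernel density of its
spike times (each spike contributes unit mass) on a uniform 1 kHz grid, with
the kernel width set to the unit's median inter-spike interval.  Z-scoring is
done either against the whole recording or against a pre-event baseline
window (default [-10, -5) s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .errors import DegenerateUnitError, EmptyAlignmentError, InsufficientDataError, PrepcircError
from .session import BehaviorTrace

DEFAULT_RATE_FS = 1000.0


@dataclass
class RateTrace:
    """Continuous firing-rate estimate on a uniform grid starting at t0."""

    rate: np.ndarray         # Hz
    fs: float                # grid sampling rate, Hz
    t0: float = 0.0
    kernel_sigma: float = 0.0  # s
    unit_id: str | None = None

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.rate.size) / self.fs

    def sample(self, times: np.ndarray) -> np.ndarray:
        return np.interp(times, self.times, self.rate)


@dataclass
class ZScoreParams:
    mode: str = "whole_recording"            # or 'baseline_window'
    baseline_window: tuple = (-10.0, -5.0)   # s relative to the event, half-open
    mean: float = float("nan")
    sd: float = float("nan")


@dataclass
class Psth:
    """Per-trial event-aligned matrix (trials x bins) plus aggregates."""

    event_label: str
    window: tuple
    bin_s: float
    matrix: np.ndarray
    n_dropped: int = 0
    event_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def bin_edges(self) -> np.ndarray:
        a, b = self.window
        return a + np.arange(self.matrix.shape[1] + 1) * self.bin_s

    @property
    def bin_centers(self) -> np.ndarray:
        e = self.bin_edges
        return 0.5 * (e[:-1] + e[1:])

    def mean(self) -> np.ndarray:
        return self.matrix.mean(axis=0)

    def sd(self) -> np.ndarray:
        return self.matrix.std(axis=0, ddof=0)


def estimate_rate(
    spikes: np.ndarray,
    duration: float,
    fs: float = DEFAULT_RATE_FS,
    sigma: float | None = None,
    unit_id: str | None = None,
) -> RateTrace:
    """Gaussian-kernel firing-rate estimate; sigma defaults to the median ISI."""
    spikes = np.asarray(spikes, dtype=float)
    if spikes.size < 2:
        raise InsufficientDataError("estimate_rate needs at least 2 spikes")
    if sigma is None:
        sigma = float(np.median(np.diff(spikes)))
    if sigma <= 0:
        raise DegenerateUnitError("median inter-spike interval is not positive")
    n = int(round(duration * fs))
    counts = np.zeros(n)
    idx = np.clip((spikes * fs).astype(int), 0, n - 1)
    np.add.at(counts, idx, 1.0)
    rate = gaussian_filter1d(counts, sigma * fs, mode="constant", truncate=6.0) * fs
    return RateTrace(rate=rate, fs=fs, t0=0.0, kernel_sigma=sigma, unit_id=unit_id)


def zscore(values: np.ndarray, params: ZScoreParams | None = None) -> tuple[np.ndarray, ZScoreParams]:
    """Z-score a rate trace (1-d) against the whole recording.

    Returns the Z trace and the params with the mean/SD actually used filled
    in so PSTHs can be put on the same scale.
    """
    params = params or ZScoreParams()
    x = np.asarray(values, dtype=float)
    m = float(np.mean(x))
    s = float(np.std(x, ddof=0))
    if s <= 0:
        raise DegenerateUnitError("zero firing-rate SD; unit is constant")
    out = ZScoreParams(mode=params.mode, baseline_window=params.baseline_window, mean=m, sd=s)
    return (x - m) / s, out


def zscore_psth(psth: Psth, params: ZScoreParams) -> Psth:
    """Convert a rate PSTH to Z units.

    ``whole_recording`` uses the stored mean/SD; ``baseline_window`` centers
    each aggregate on the mean over the baseline window (shared SD from the
    same window, pooled over trials).
    """
    if params.mode == "whole_recording":
        if not np.isfinite(params.sd) or params.sd <= 0:
            raise DegenerateUnitError("whole-recording SD unavailable or zero")
        z = (psth.matrix - params.mean) / params.sd
    elif params.mode == "baseline_window":
        a, b = params.baseline_window
        centers = psth.bin_centers
        m = (centers >= a) & (centers < b)
        if not m.any():
            raise PrepcircError("baseline window does not overlap the PSTH window")
        base = psth.matrix[:, m]
        sd = float(base.std(ddof=0))
        if sd <= 0:
            raise DegenerateUnitError("zero SD in baseline window")
        z = (psth.matrix - base.mean()) / sd
    else:
        raise PrepcircError(f"unknown zscore mode {params.mode!r}")
    return Psth(psth.event_label, psth.window, psth.bin_s, z, psth.n_dropped, psth.event_times)


def align_psth(
    trace: RateTrace,
    event_times: np.ndarray,
    window: tuple = (-4.0, 2.0),
    bin_s: float = 0.01,
    event_label: str = "event",
) -> Psth:
    """Event-aligned per-trial matrix of the trace, binned to ``bin_s``.

    Events whose window is truncated by the recording edges are dropped and
    counted in ``n_dropped``.
    """
    a, b = window
    event_times = np.asarray(event_times, dtype=float)
    n_bins = int(round((b - a) / bin_s))
    spb = int(round(bin_s * trace.fs))
    if spb < 1:
        raise PrepcircError("bin smaller than the trace resolution")
    n_samp = n_bins * spb
    t_end = trace.t0 + trace.rate.size / trace.fs
    rows, kept = [], []
    for ev in event_times:
        i0 = int(round((ev + a - trace.t0) * trace.fs))
        if i0 < 0 or i0 + n_samp > trace.rate.size:
            continue
        seg = trace.rate[i0 : i0 + n_samp]
        rows.append(seg.reshape(n_bins, spb).mean(axis=1))
        kept.append(ev)
    if not rows:
        raise EmptyAlignmentError(
            f"no event with a full [{a}, {b}) window inside [{trace.t0}, {t_end})"
        )
    return Psth(
        event_label,
        (a, b),
        bin_s,
        np.vstack(rows),
        n_dropped=event_times.size - len(rows),
        event_times=np.array(kept),
    )


# ---------------------------------------------------------------------------
# behavioral event detection


def reward_exclusion_windows(
    reward_times: np.ndarray, before: float = 4.0, after: float = 3.0
) -> list[tuple[float, float]]:
    """Default reward-zone exclusion [reward - 4 s, reward + 3 s)."""
    return [(r - before, r + after) for r in np.asarray(reward_times, dtype=float)]


def _excluded(times: np.ndarray, windows) -> np.ndarray:
    mask = np.zeros(times.size, dtype=bool)
    for a, b in windows or []:
        mask |= (times >= a) & (times < b)
    return mask


def detect_decelerations(
    behavior: BehaviorTrace,
    exclusion_windows=None,
    theta_low: float = 20.0,
    theta_high: float = 30.0,
    min_run: float = 1.0,
    max_gap: float = 1.5,
) -> np.ndarray:
    """Times where speed falls below ``theta_low`` after a sustained run.

    A downward crossing of ``theta_low`` counts if the speed spent at least
    ``min_run`` s continuously above ``theta_high`` ending no more than
    ``max_gap`` s before the crossing (the braking transit itself).  Events
    inside any exclusion window are dropped.
    """
    v = behavior.running_speed
    fs = behavior.sample_rate
    t = behavior.times
    below = v < theta_low
    cross = np.flatnonzero(below[1:] & ~below[:-1]) + 1
    above = v >= theta_high
    # run length of consecutive 'above' samples ending at each index
    runlen = np.zeros(v.size)
    acc = 0.0
    for i in range(v.size):  # simple scan; traces are ~1e5 samples
        acc = acc + 1.0 / fs if above[i] else 0.0
        runlen[i] = acc
    events = []
    for i in cross:
        j0 = max(int(i - max_gap * fs), 0)
        if np.max(runlen[j0:i], initial=0.0) >= min_run:
            events.append(t[i])
    events = np.array(events)
    return events[~_excluded(events, exclusion_windows)] if events.size else events


def detect_lick_bout_starts(
    lick_times: np.ndarray, exclusion_windows=None, min_gap: float = 1.0
) -> np.ndarray:
    """First lick of each train: preceded by >= ``min_gap`` s without licks."""
    licks = np.asarray(lick_times, dtype=float)
    if licks.size == 0:
        return licks
    starts = licks[np.insert(np.diff(licks) >= min_gap, 0, True)]
    return starts[~_excluded(starts, exclusion_windows)]


def crosscov_rate_behavior(
    rate: RateTrace,
    behavior_series: np.ndarray,
    behavior_fs: float = 100.0,
    max_lag: float = 2.0,
    bin_s: float = 0.01,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Mean-subtracted cross-covariance between a unit rate and a behavior trace.

    Both series are put on a common 100 Hz base and the covariance is
    evaluated at ``bin_s`` lag steps over +-``max_lag``.  A positive peak lag
    means the firing rate *leads* the behavior.  Returns (lags_s, cov,
    extremum_lag_s).
    """
    dec = int(round(rate.fs / behavior_fs))
    if dec < 1:
        raise PrepcircError("rate grid coarser than the covariance base rate")
    r = rate.rate[: (rate.rate.size // dec) * dec].reshape(-1, dec).mean(axis=1)
    b = np.asarray(behavior_series, dtype=float)
    m = min(r.size, b.size)
    r, b = r[:m] - r[:m].mean(), b[:m] - b[:m].mean()
    step = int(round(bin_s * behavior_fs))
    k_max = int(round(max_lag / bin_s))
    if m <= 2 * k_max * step:
        raise PrepcircError("series shorter than twice the maximum lag")
    lags = np.arange(-k_max, k_max + 1) * bin_s
    cov = np.empty(lags.size)
    for i, k in enumerate(range(-k_max, k_max + 1)):
        s = k * step
        if s >= 0:
            x, y = r[: m - s], b[s:]
        else:
            x, y = r[-s:], b[: m + s]
        cov[i] = np.mean(x * y)
    extremum = lags[int(np.argmax(np.abs(cov)))]
    return lags, cov, float(extremum)


def group_trials_by_dip(
    behavior: BehaviorTrace,
    reward_times: np.ndarray,
    threshold: float = 20.0,
    lookback: float = 4.0,
) -> tuple[list[np.ndarray], int]:
    """Split rewarded trials into 3 groups by when speed dipped under 20 cm/s.

    The dip time of a trial is the first time in [reward - lookback, reward)
    at which speed is below ``threshold``.  Trials are split at the 33rd and
    66th percentiles of the dip-time distribution (stable sort, so ties are
    broken by trial order and groups are as equal as possible).  Trials with
    no dip are excluded and counted.
    """
    rewards = np.asarray(reward_times, dtype=float)
    v, t, fs = behavior.running_speed, behavior.times, behavior.sample_rate
    dips, idx = [], []
    for i, r in enumerate(rewards):
        i0 = max(int((r - lookback) * fs), 0)
        i1 = min(int(r * fs), v.size)
        seg = v[i0:i1]
        hit = np.flatnonzero(seg < threshold)
        if hit.size:
            dips.append(t[i0 + hit[0]] - r)
            idx.append(i)
    if len(dips) < 3:
        raise InsufficientDataError("need >= 3 rewarded trials with a pre-reward dip")
    order = np.argsort(np.asarray(dips), kind="stable")
    n = order.size
    cut1, cut2 = int(np.ceil(n / 3)), int(np.ceil(2 * n / 3))
    groups = [
        np.asarray(idx)[order[:cut1]],
        np.asarray(idx)[order[cut1:cut2]],
        np.asarray(idx)[order[cut2:]],
    ]
    return groups, rewards.size - n


def lick_rate_trace(
    lick_times: np.ndarray, duration: float, fs: float = 100.0, sigma: float = 0.1
) -> np.ndarray:
    """Gaussian-smoothed lick rate (Hz) on the behavior grid; sigma 100 ms."""
    n = int(round(duration * fs))
    counts = np.zeros(n)
    licks = np.asarray(lick_times, dtype=float)
    idx = np.clip((licks * fs).astype(int), 0, n - 1)
    np.add.at(counts, idx, 1.0)
    return gaussian_filter1d(counts, sigma * fs, mode="constant") * fs
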