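"""Speed-tuning curves, spline rate models and the reward-residual test.

Each Purkinje cell's firing rate is binned against running speed (5 cm/s
bins from the rounded minimum to maximum speed), fit with an
occupancy-weighted cubic smoothing spline, and converted back into a
predicted rate trace from the speed trace.  Cells with a learned pre-reward
decrease are selected by mean(FR[-4,-3) s) > mean(FR[-2,0) s) +
2*SD(FR[-4,-3) s) around rewards.  The residual test asks whether the
speed-only model overestimates the measured rate before rewards more than
before matched deceleration events outside the reward zone, in at least 80%
of equal-sized reward blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_smoothing_spline
from scipy.signal import butter, filtfilt

from .errors import InsufficientDataError, PrepcircError
from .rates import Psth, RateTrace
from .session import BehaviorTrace


@dataclass
class TuningCurve:
    unit_id: str
    bin_edges: np.ndarray        # cm/s
    mean_rate: np.ndarray        # Hz, NaN for unoccupied bins
    occupancy: np.ndarray        # s
    spline: object | None = None
    lam: float | None = None     # smoothing parameter actually used

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def lowpass_speed(behavior: BehaviorTrace, cutoff_hz: float = 100.0) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass of the speed trace.

    A 100 Hz cutoff is a no-op unless the behavior is sampled above 200 Hz,
    in which case the filter is actually applied.
    """
    v = behavior.running_speed
    if behavior.sample_rate <= 2.0 * cutoff_hz:
        return v
    b, a = butter(4, cutoff_hz / (behavior.sample_rate / 2.0))
    return filtfilt(b, a, v)


def build_tuning(
    behavior: BehaviorTrace,
    rate: RateTrace,
    unit_id: str = "",
    bin_width: float = 5.0,
    min_bins: int = 10,
) -> TuningCurve:
    """Mean firing rate per 5 cm/s speed bin, with per-bin occupancy.

    Falls back to doubled bin width (with a warning) when fewer than
    ``min_bins`` bins are occupied.
    """
    import warnings

    speed = lowpass_speed(behavior)
    t = behavior.times
    r = rate.sample(t)

    def _curve(width: float):
        lo = np.floor(speed.min() / width) * width
        hi = np.ceil(speed.max() / width) * width
        if hi <= lo:
            hi = lo + width
        edges = np.arange(lo, hi + width / 2, width)
        idx = np.clip(np.digitize(speed, edges) - 1, 0, edges.size - 2)
        n = edges.size - 1
        occ = np.bincount(idx, minlength=n) / behavior.sample_rate
        sums = np.bincount(idx, weights=r, minlength=n)
        with np.errstate(invalid="ignore"):
            mean = np.where(occ > 0, sums / np.maximum(occ * behavior.sample_rate, 1e-12), np.nan)
        return edges, mean, occ

    edges, mean, occ = _curve(bin_width)
    if np.sum(occ > 0) == 0:
        raise InsufficientDataError("no occupied speed bin")
    if np.sum(occ > 0) < min_bins:
        warnings.warn("fewer than 10 occupied speed bins; widening bins", stacklevel=2)
        edges, mean, occ = _curve(2.0 * bin_width)
    return TuningCurve(unit_id, edges, mean, occ)


def fit_tuning_spline(curve: TuningCurve, lam: float | None = None) -> TuningCurve:
    """Occupancy-weighted cubic smoothing spline through the binned curve.

    The smoothing parameter defaults to generalized cross-validation
    (``lam=None``); pass a small value to approach interpolation.  The fitted
    curve is evaluated with clamped extrapolation beyond the data range.
    """
    occ_mask = curve.occupancy > 0
    x = curve.bin_centers[occ_mask]
    y = curve.mean_rate[occ_mask]
    w = curve.occupancy[occ_mask]
    if x.size < 4:
        raise InsufficientDataError("need >= 4 occupied speed bins for the spline")
    spl = make_smoothing_spline(x, y, w=w / w.mean(), lam=lam)
    curve.spline = spl
    curve.lam = lam
    curve._range = (float(x[0]), float(x[-1]))  # clamp bounds
    return curve


def model_rate(speed: np.ndarray, curve: TuningCurve) -> tuple[np.ndarray, int]:
    """Speed trace -> predicted rate through the tuning spline.

    Speeds outside the fitted range are clamped to the boundary value;
    predictions are rectified at 0.  Returns (rate, n_clamped_samples).
    """
    if curve.spline is None:
        raise PrepcircError("tuning curve has no fitted spline")
    lo, hi = curve._range
    s = np.asarray(speed, dtype=float)
    n_clamped = int(np.sum((s < lo) | (s > hi)))
    pred = curve.spline(np.clip(s, lo, hi))
    return np.maximum(pred, 0.0), n_clamped


def select_decreasing_pcs(
    psth: Psth,
    early: tuple = (-4.0, -3.0),
    late: tuple = (-2.0, 0.0),
    n_sd: float = 2.0,
    min_trials: int = 20,
) -> bool:
    """Pre-reward decrease criterion on a reward-aligned rate PSTH.

    True iff the mean rate in [-4, -3) s exceeds the mean in [-2, 0) s by
    more than ``n_sd`` times the SD over the time bins of the trial-averaged
    PSTH within [-4, -3) s.
    """
    if psth.matrix.shape[0] < min_trials:
        raise InsufficientDataError(f"need >= {min_trials} trials, got {psth.matrix.shape[0]}")
    c = psth.bin_centers
    m_e = (c >= early[0]) & (c < early[1])
    m_l = (c >= late[0]) & (c < late[1])
    if not (m_e.any() and m_l.any()):
        raise PrepcircError("selection windows outside the PSTH window")
    avg = psth.mean()
    return bool(avg[m_e].mean() > avg[m_l].mean() + n_sd * avg[m_e].std(ddof=0))


@dataclass
class ResidualResult:
    unit_id: str
    decel_diff: float            # Hz, mean(model - actual) before decelerations
    reward_diffs: np.ndarray     # Hz, one per reward block
    fraction: float              # blocks satisfying the overestimation inequality
    overestimates_at_reward: bool
    n_decel: int
    n_blocks: int


def residual_test(
    model: RateTrace | np.ndarray,
    actual: RateTrace,
    decel_events: np.ndarray,
    reward_events: np.ndarray,
    unit_id: str = "",
    window: tuple = (-2.0, 0.0),
    min_fraction: float = 0.8,
    printed_direction: bool = False,
) -> ResidualResult:
    """Deceleration-vs-reward residual (overestimation) test.

    ``decel_diff`` is the mean over deceleration events of the mean
    (model - actual) in the 2 s before the event; rewards are partitioned
    chronologically into blocks of the same number of trials (remainder
    dropped) and scored identically.  The unit is flagged when the reward
    blocks' differences exceed the deceleration difference in at least 80%
    of blocks, i.e. the speed-only model overestimates firing specifically
    before rewards.  ``printed_direction=True`` inverts the inequality.
    """
    decel = np.asarray(decel_events, dtype=float)
    rewards = np.sort(np.asarray(reward_events, dtype=float))
    rewards = rewards[np.isfinite(rewards)]
    if decel.size < 3:
        raise InsufficientDataError(f"need >= 3 deceleration events, got {decel.size}")
    n_blocks = rewards.size // decel.size
    if n_blocks < 1:
        raise InsufficientDataError(
            f"need at least one full block of rewards ({rewards.size} rewards, {decel.size} decels)"
        )
    if isinstance(model, np.ndarray):
        model = RateTrace(model, actual.fs, actual.t0)

    def _diff(events: np.ndarray) -> float:
        rel = np.arange(window[0], window[1], 1.0 / actual.fs)
        vals = [model.sample(e + rel) - actual.sample(e + rel) for e in events]
        return float(np.mean(vals))

    decel_diff = _diff(decel)
    blocks = [rewards[i * decel.size : (i + 1) * decel.size] for i in range(n_blocks)]
    reward_diffs = np.array([_diff(b) for b in blocks])
    if printed_direction:
        hits = decel_diff > reward_diffs
    else:
        hits = reward_diffs > decel_diff
    fraction = float(hits.mean())
    return ResidualResult(
        unit_id, decel_diff, reward_diffs, fraction, bool(fraction >= min_fraction),
        int(decel.size), n_blocks,
    )
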