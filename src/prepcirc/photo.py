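"""Optogenetic photoactivation effects on single units and populations.

A unit is modulated by Purkinje-cell photoactivation when its per-trial mean
firing rate in the second after light onset differs between photostimulation
and control trials (two-sided Wilcoxon rank-sum, alpha 0.05); it is
inhibited when the control rate is higher.  The onset latency of inhibition
is the left edge of the first 2-ms bin after onset where the onset-aligned
spike histogram leaves a +-2 SD band around the baseline of the preceding
50 ms, in the direction of the modulation.  Across units, the size of the
photoactivation effect is regressed on the pre-onset ramp size and the
control firing rate (effect = alpha*ramp + beta*control + gamma).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateUnitError, InsufficientDataError
from .rates import RateTrace


@dataclass
class PhotoEffect:
    unit_id: str
    control_rate: float          # Hz in the 1-s window
    photo_rate: float
    p_value: float
    modulation: str              # 'inhibited' | 'excited' | 'none'
    onset_latency_ms: float = float("nan")
    ramp_size: float = float("nan")    # Z units, mean in [-1, 0) s before onset (control)
    effect_size: float = float("nan")  # Z units, photo - control in the window


def _window_rates(spikes: np.ndarray, onsets: np.ndarray, window: float) -> np.ndarray:
    s = np.asarray(spikes, dtype=float)
    return np.array(
        [(np.searchsorted(s, o + window) - np.searchsorted(s, o)) / window for o in onsets]
    )


def test_photo_modulation(
    spikes: np.ndarray,
    photo_onsets: np.ndarray,
    control_onsets: np.ndarray,
    unit_id: str = "",
    window: float = 1.0,
    alpha: float = 0.05,
) -> PhotoEffect:
    """Rank-sum comparison of per-trial rates in [onset, onset + window).

    Control trials use the matched "virtual" onsets (the time the mouse
    crossed the light-trigger position).  Requires >= 5 trials per condition.
    """
    photo_onsets = np.asarray(photo_onsets, dtype=float)
    control_onsets = np.asarray(control_onsets, dtype=float)
    if photo_onsets.size < 5 or control_onsets.size < 5:
        raise InsufficientDataError("need >= 5 trials per condition")
    r_photo = _window_rates(spikes, photo_onsets, window)
    r_ctrl = _window_rates(spikes, control_onsets, window)
    if np.all(r_photo == r_photo[0]) and np.all(r_ctrl == r_ctrl[0]) and r_photo[0] == r_ctrl[0]:
        p = 1.0
    else:
        p = float(stats.mannwhitneyu(r_ctrl, r_photo, alternative="two-sided").pvalue)
    if p < alpha:
        modulation = "inhibited" if r_ctrl.mean() > r_photo.mean() else "excited"
    else:
        modulation = "none"
    return PhotoEffect(
        unit_id,
        control_rate=float(r_ctrl.mean()),
        photo_rate=float(r_photo.mean()),
        p_value=p,
        modulation=modulation,
    )


def onset_latency(
    spikes: np.ndarray,
    photo_onsets: np.ndarray,
    direction: str,
    bin_ms: float = 2.0,
    baseline_ms: float = 50.0,
    search_ms: float = 100.0,
    n_sd: float = 2.0,
) -> float:
    """Latency (ms) of the firing-rate change after light onset.

    Builds an onset-aligned histogram at ``bin_ms`` resolution (counts summed
    over trials); the latency is the left edge of the first post-onset bin
    whose count leaves the baseline mean +- ``n_sd`` SD band (baseline =
    the ``baseline_ms`` preceding onset) in the direction of the unit's
    modulation.  NaN when no bin crosses within ``search_ms``.
    """
    if direction not in ("inhibited", "excited"):
        raise InsufficientDataError("latency is defined only for modulated units")
    s = np.asarray(spikes, dtype=float)
    onsets = np.asarray(photo_onsets, dtype=float)
    nb_base = int(round(baseline_ms / bin_ms))
    nb_post = int(round(search_ms / bin_ms))
    edges = (np.arange(-nb_base, nb_post + 1) * bin_ms) * 1e-3
    counts = np.zeros(edges.size - 1)
    for o in onsets:
        rel = s[(s >= o + edges[0]) & (s < o + edges[-1])] - o
        counts += np.histogram(rel, bins=edges)[0]
    base = counts[:nb_base]
    m, sd = base.mean(), base.std(ddof=0)
    if sd <= 0:
        raise DegenerateUnitError("zero baseline SD for latency estimation")
    post = counts[nb_base:]
    if direction == "inhibited":
        hits = post < m - n_sd * sd
    else:
        hits = post > m + n_sd * sd
    idx = np.flatnonzero(hits)
    if idx.size == 0:
        return float("nan")
    return float(idx[0] * bin_ms)


def attach_z_metrics(
    effect: PhotoEffect,
    rate: RateTrace,
    photo_onsets: np.ndarray,
    control_onsets: np.ndarray,
    window: float = 1.0,
    ramp_window: tuple = (-1.0, 0.0),
) -> PhotoEffect:
    """Fill in ramp_size and effect_size on the whole-recording Z scale.

    ramp_size = mean Z in the second before (virtual) onset on control
    trials; effect_size = mean Z during the window on photo trials minus
    control trials.
    """
    m = float(rate.rate.mean())
    sd = float(rate.rate.std(ddof=0))
    if sd <= 0:
        raise DegenerateUnitError("zero rate SD")

    def _mean_z(onsets: np.ndarray, a: float, b: float) -> float:
        rel = np.arange(a, b, 1.0 / rate.fs)
        return float(np.mean([(rate.sample(o + rel) - m) / sd for o in onsets]))

    effect.ramp_size = _mean_z(control_onsets, *ramp_window)
    effect.effect_size = _mean_z(photo_onsets, 0.0, window) - _mean_z(control_onsets, 0.0, window)
    return effect


def ramp_regression(effects: list[PhotoEffect]):
    """OLS: effect_size ~ alpha*ramp_size + beta*control_rate + gamma.

    Returns a dict with the coefficients, their t-test p-values and 95% CIs;
    warns (in the result) when the predictors are near-collinear.
    """
    import statsmodels.api as sm

    ok = [e for e in effects if np.isfinite(e.ramp_size) and np.isfinite(e.effect_size)]
    if len(ok) < 10:
        raise InsufficientDataError(f"need >= 10 units with ramp and effect, got {len(ok)}")
    ramp = np.array([e.ramp_size for e in ok])
    ctrl = np.array([e.control_rate for e in ok])
    y = np.array([e.effect_size for e in ok])
    X = sm.add_constant(np.column_stack([ramp, ctrl]))
    fit = sm.OLS(y, X).fit()
    cond = float(np.linalg.cond(X))
    return {
        "alpha": float(fit.params[1]),
        "beta": float(fit.params[2]),
        "gamma": float(fit.params[0]),
        "p_alpha": float(fit.pvalues[1]),
        "p_beta": float(fit.pvalues[2]),
        "p_gamma": float(fit.pvalues[0]),
        "conf_int": fit.conf_int(),
        "condition_number": cond,
        "collinearity_warning": cond > 1e6,
        "n": len(ok),
    }


def population_profiles(
    rates: dict[str, RateTrace],
    groups: dict[str, list],
    photo_onsets: np.ndarray,
    control_onsets: np.ndarray,
    window: tuple = (-1.0, 2.0),
    fs: float = 100.0,
):
    """Mean +- SD whole-recording-Z traces aligned to light onset, per type.

    Returns {type: {"time": t, "photo": (mean, sd), "control": (mean, sd)}}.
    """
    rel = np.arange(window[0], window[1], 1.0 / fs)
    out = {}
    for gname, uids in groups.items():
        if not uids:
            continue
        traces = {"photo": [], "control": []}
        for uid in uids:
            r = rates[uid]
            m, sd = float(r.rate.mean()), float(r.rate.std(ddof=0))
            if sd <= 0:
                continue
            for key, onsets in (("photo", photo_onsets), ("control", control_onsets)):
                z = np.mean([(r.sample(o + rel) - m) / sd for o in onsets], axis=0)
                traces[key].append(z)
        out[gname] = {
            "time": rel,
            "photo": (np.mean(traces["photo"], axis=0), np.std(traces["photo"], axis=0)),
            "control": (np.mean(traces["control"], axis=0), np.std(traces["control"], axis=0)),
        }
    return out


def compare_types_ranksum(values_by_type: dict[str, np.ndarray], n_comparisons: int | None = None):
    """Pairwise rank-sum comparisons across unit types with Bonferroni correction.

    Returns {(a, b): (p, significant)} where significance uses
    alpha = 0.05 / n_comparisons (0.0083 for the 6 pairwise comparisons of 4
    types).
    """
    keys = sorted(values_by_type)
    pairs = [(a, b) for i, a in enumerate(keys) for b in keys[i + 1 :]]
    n_comparisons = n_comparisons or len(pairs)
    alpha = 0.05 / max(n_comparisons, 1)
    out = {}
    for a, b in pairs:
        p = float(stats.mannwhitneyu(values_by_type[a], values_by_type[b], alternative="two-sided").pvalue)
        out[(a, b)] = (p, p < alpha)
    return out
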