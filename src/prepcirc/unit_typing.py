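"""Cerebellar unit typing: Purkinje cells, complex spikes and fat spikes.

Putative Purkinje cells (PCs) are identified by fitting each unit's
inter-spike-interval distribution with a lognormal and k-means clustering
the (mu, sigma) plane into two groups; the group with larger ISI mean and SD
is labelled non-PC.  Complex spikes (CSs) are separated from simple spikes
(SSs) by the positive "late peak" within 3 ms of the spike peak
(seed set = late peaks above median + 3 MAD, then per-spike Spearman
correlation against the CS/SS mean templates), and confirmed by the pause
in SS firing that follows each CS.  Climbing-fiber "fat spike" units are
identified by a waveform FWHM above 0.5 ms and characterized by their
reward-locked firing probability, onset and jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

from .errors import DegenerateUnitError, InsufficientDataError, PrepcircError
from .session import Waveform


@dataclass
class IsiFit:
    unit_id: str
    mu: float                 # mean of log ISI
    sigma: float              # SD of log ISI
    quality: float            # -KS distance of log ISI to the fitted normal
    degenerate: bool = False


def fit_isi_lognormal(spikes: np.ndarray, unit_id: str = "", min_isis: int = 50) -> IsiFit:
    """Maximum-likelihood lognormal fit of the ISI distribution.

    Equivalent to the mean/SD of log ISIs; quality is the (negated)
    Kolmogorov-Smirnov distance between the log-ISI sample and the fitted
    normal, so better fits score higher.
    """
    isis = np.diff(np.asarray(spikes, dtype=float))
    isis = isis[isis > 0]
    if isis.size < min_isis:
        raise InsufficientDataError(f"need >= {min_isis} ISIs, got {isis.size}")
    log_isi = np.log(isis)
    mu = float(log_isi.mean())
    sigma = float(log_isi.std(ddof=0))
    if sigma < 1e-12:
        return IsiFit(unit_id, mu, sigma, quality=float("-inf"), degenerate=True)
    ks = stats.kstest(log_isi, "norm", args=(mu, sigma)).statistic
    return IsiFit(unit_id, mu, sigma, quality=-float(ks))


def cluster_putative_pcs(fits: list[IsiFit], seed: int = 0) -> dict[str, str]:
    """k-means (k=2, 10 restarts) on the standardized (mu, sigma) plane.

    The cluster whose standardized centroid coordinate sum is larger (higher
    ISI mean and SD, i.e. slower and more irregular) is labelled non-PC.
    Returns unit_id -> 'PC' | 'non-PC'.
    """
    if len(fits) < 4:
        raise InsufficientDataError("need >= 4 units to cluster")
    X = np.array([[f.mu, f.sigma] for f in fits], dtype=float)
    sd = X.std(axis=0, ddof=0)
    if np.any(sd <= 0) and np.all(sd <= 0):
        raise PrepcircError("all units have identical ISI statistics; cannot cluster")
    Xz = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    km = KMeans(n_clusters=2, n_init=10, random_state=int(seed)).fit(Xz)
    sums = [km.cluster_centers_[k].sum() for k in range(2)]
    non_pc = int(np.argmax(sums))
    return {f.unit_id: ("non-PC" if lbl == non_pc else "PC") for f, lbl in zip(fits, km.labels_)}


# ---------------------------------------------------------------------------
# complex spikes


@dataclass
class CsResult:
    unit_id: str
    cs_times: np.ndarray
    ss_times: np.ndarray
    cs_template: np.ndarray | None
    ss_template: np.ndarray | None
    late_peak_threshold: float
    confirmed: bool = False
    pause_ms: float = float("nan")
    reason: str = ""


def _rank_rows(a: np.ndarray) -> np.ndarray:
    """Row-wise midranks (ties averaged), vectorized for Spearman correlation."""
    order = np.argsort(a, axis=1, kind="stable")
    ranks = np.empty_like(order, dtype=float)
    rng = np.arange(a.shape[1], dtype=float)
    np.put_along_axis(ranks, order, np.broadcast_to(rng, a.shape), axis=1)
    return ranks


def _spearman_vs(stream_ranks: np.ndarray, template: np.ndarray) -> np.ndarray:
    tr = stats.rankdata(template)
    tz = (tr - tr.mean()) / max(tr.std(), 1e-12)
    sz = stream_ranks - stream_ranks.mean(axis=1, keepdims=True)
    denom = np.maximum(sz.std(axis=1), 1e-12)
    return (sz @ tz) / (denom * stream_ranks.shape[1])


def detect_complex_spikes(
    stream: np.ndarray,
    spike_times: np.ndarray,
    sample_rate_khz: float,
    peak_index: int,
    baseline_rate: float,
    unit_id: str = "",
    rate_threshold: float = 15.0,
    n_mad: float = 3.0,
) -> CsResult:
    """Split a per-spike waveform stream into complex and simple spikes.

    Requires a baseline firing rate above ``rate_threshold`` Hz (a PC-like
    rate) and >= 3 ms of waveform after the peak.  Per spike, the late peak
    is the maximum amplitude in (0, 3] ms after the peak; spikes whose late
    peak exceeds the median + 3 MAD form a seed set whose mean waveform is
    the CS template (the rest form the SS template).  Each spike is then a CS
    iff its Spearman correlation with the CS template is positive and larger
    than with the SS template.  The CS/SS sets partition the spikes exactly.
    """
    stream = np.asarray(stream, dtype=float)
    spike_times = np.asarray(spike_times, dtype=float)
    if stream.shape[0] != spike_times.size:
        raise PrepcircError("waveform stream and spike times disagree in length")
    if baseline_rate <= rate_threshold:
        raise InsufficientDataError(
            f"baseline rate {baseline_rate:.1f} Hz below the {rate_threshold} Hz PC gate"
        )
    post = stream.shape[1] - 1 - peak_index
    if post < 3.0 * sample_rate_khz:
        raise PrepcircError("waveform window shorter than 3 ms after the peak")

    i0 = peak_index + 1
    i1 = peak_index + int(round(3.0 * sample_rate_khz)) + 1
    late = stream[:, i0:i1].max(axis=1)
    med = float(np.median(late))
    mad = float(np.median(np.abs(late - med)))
    thr = med + n_mad * mad
    seed = late > thr
    if not seed.any() or seed.all():
        return CsResult(unit_id, np.empty(0), spike_times, None, None, thr,
                        reason="empty or exhaustive late-peak seed set; no CS")
    cs_tpl = stream[seed].mean(axis=0)
    ss_tpl = stream[~seed].mean(axis=0)
    ranks = _rank_rows(stream)
    rho_cs = _spearman_vs(ranks, cs_tpl)
    rho_ss = _spearman_vs(ranks, ss_tpl)
    is_cs = (rho_cs > 0) & (rho_cs - rho_ss > 0)
    res = CsResult(
        unit_id,
        cs_times=spike_times[is_cs],
        ss_times=spike_times[~is_cs],
        cs_template=cs_tpl,
        ss_template=ss_tpl,
        late_peak_threshold=thr,
    )
    if res.cs_times.size and res.cs_times.size >= res.ss_times.size:
        # a CS set larger than the SS set is not physiological; report no CS
        return CsResult(unit_id, np.empty(0), spike_times, cs_tpl, ss_tpl, thr,
                        reason="CS set not a minority; no CS")
    return res


def confirm_cs(
    ss_times: np.ndarray,
    cs_times: np.ndarray,
    min_cs: int = 20,
    pause_window_ms: tuple = (0.0, 20.0),
    baseline_window_ms: tuple = (-50.0, -10.0),
    max_ratio: float = 0.5,
) -> tuple[bool, float, str]:
    """Confirm CSs by the pause in SS firing that follows them.

    Confirmed iff the SS rate in (0, 20] ms after CSs is below ``max_ratio``
    of the SS rate in [-50, -10) ms before them.  Returns (confirmed,
    estimated pause length in ms, reason-if-not).
    """
    ss = np.asarray(ss_times, dtype=float)
    cs = np.asarray(cs_times, dtype=float)
    if cs.size < min_cs:
        return False, float("nan"), f"only {cs.size} CS events (< {min_cs})"
    if ss.size == 0:
        raise InsufficientDataError("no simple spikes to test the pause against")

    def _rate(win_ms: tuple) -> float:
        a, b = win_ms[0] * 1e-3, win_ms[1] * 1e-3
        n = 0
        for c in cs:
            n += int(np.searchsorted(ss, c + b) - np.searchsorted(ss, c + a))
        return n / (cs.size * (b - a))

    post = _rate((pause_window_ms[0] + 1e-9, pause_window_ms[1]))
    base = _rate(baseline_window_ms)
    if base <= 0:
        return False, float("nan"), "no baseline SS firing"
    confirmed = post < max_ratio * base
    # pause length: first 1-ms lag bin where SS rate recovers to half baseline
    edges = np.arange(0.0, 50.0, 1.0)
    rates = np.array([_rate((e, e + 1.0)) for e in edges])
    rec = np.flatnonzero(rates >= 0.5 * base)
    pause = float(edges[rec[0]]) if rec.size else 50.0
    return confirmed, pause, "" if confirmed else "no SS pause after CS"


# ---------------------------------------------------------------------------
# fat spikes


def classify_fat_spike(
    waveform: Waveform, threshold_ms: float = 0.5
) -> tuple[float, bool, bool]:
    """FWHM (ms) of the absolute waveform about its dominant peak.

    Returns (fwhm_ms, is_fat, ambiguous).  ``ambiguous`` flags multi-peaked
    waveforms where a secondary extremum rivals the main one outside the
    half-maximum support.
    """
    w = np.abs(np.asarray(waveform.samples, dtype=float))
    pk = int(np.argmax(w))
    half = w[pk] / 2.0
    # walk left/right to the half-max crossings, linear interpolation
    i = pk
    while i > 0 and w[i] > half:
        i -= 1
    if w[i] <= half and i < pk:
        left = i + (half - w[i]) / max(w[i + 1] - w[i], 1e-12)
    else:
        left = 0.0
    j = pk
    while j < w.size - 1 and w[j] > half:
        j += 1
    if w[j] <= half and j > pk:
        right = j - (half - w[j]) / max(w[j - 1] - w[j], 1e-12)
    else:
        right = float(w.size - 1)
    fwhm_ms = (right - left) / waveform.sample_rate_khz
    outside = np.concatenate([w[: max(int(np.floor(left)) - 2, 0)], w[int(np.ceil(right)) + 3 :]])
    ambiguous = bool(outside.size and outside.max() > 0.9 * w[pk])
    return float(fwhm_ms), bool(fwhm_ms > threshold_ms), ambiguous


@dataclass
class FatSpikeResult:
    unit_id: str
    fwhm_ms: float = float("nan")
    is_fat: bool = False
    significant: bool = False
    p_value: float = float("nan")
    probability: float = float("nan")   # P(>=1 spike in the first significant 100-ms bin)
    onset_s: float = float("nan")       # mean first-spike time in that bin
    jitter_s: float = float("nan")      # mean |pairwise difference| of those times
    sig_bin: tuple | None = None


def fat_spike_reward_modulation(
    spike_times: np.ndarray,
    reward_times: np.ndarray,
    unit_id: str = "",
    alpha: float = 0.05,
    bin_s: float = 0.1,
    window_s: float = 0.5,
    min_trials: int = 10,
) -> FatSpikeResult:
    """Reward-locked modulation of a fat-spike (climbing fiber) unit.

    Per-trial spike counts in [-0.5, 0) vs [0, 0.5) s around reward are
    compared with a two-sided Wilcoxon rank-sum test.  The first 100-ms bin
    in [0, 0.5) whose per-trial spike probability exceeds the pre-reward
    bin-wise mean + 3 SD defines the firing probability, onset (mean first
    spike time in that bin) and jitter (mean absolute pairwise difference of
    those first-spike times).
    """
    spikes = np.asarray(spike_times, dtype=float)
    rewards = np.asarray(reward_times, dtype=float)
    rewards = rewards[np.isfinite(rewards)]
    if rewards.size < min_trials:
        raise InsufficientDataError(f"need >= {min_trials} rewarded trials")

    def _counts(a: float, b: float) -> np.ndarray:
        return np.array(
            [np.searchsorted(spikes, r + b) - np.searchsorted(spikes, r + a) for r in rewards]
        )

    pre = _counts(-window_s, 0.0)
    post = _counts(0.0, window_s)
    if np.all(pre == post):
        p = 1.0
    else:
        p = float(stats.mannwhitneyu(pre, post, alternative="two-sided").pvalue)
    res = FatSpikeResult(unit_id, p_value=p)
    if not (p < alpha and post.mean() > pre.mean()):
        return res

    n_bins = int(round(window_s / bin_s))
    post_prob = np.array([( _counts(k * bin_s, (k + 1) * bin_s) > 0).mean() for k in range(n_bins)])
    pre_prob = np.array(
        [(_counts(-window_s + k * bin_s, -window_s + (k + 1) * bin_s) > 0).mean() for k in range(n_bins)]
    )
    thr = pre_prob.mean() + 3.0 * pre_prob.std(ddof=0)
    sig = np.flatnonzero(post_prob > thr)
    if sig.size == 0:
        return res  # modulated overall but no single significant bin
    k = int(sig[0])
    a, b = k * bin_s, (k + 1) * bin_s
    firsts = []
    for r in rewards:
        i0 = np.searchsorted(spikes, r + a)
        i1 = np.searchsorted(spikes, r + b)
        if i1 > i0:
            firsts.append(spikes[i0] - r)
    firsts = np.asarray(firsts)
    res.significant = True
    res.sig_bin = (a, b)
    res.probability = float((post_prob[k]))
    res.onset_s = float(firsts.mean())
    if firsts.size > 1:
        d = np.abs(firsts[:, None] - firsts[None, :])
        res.jitter_s = float(d[np.triu_indices(firsts.size, 1)].mean())
    else:
        res.jitter_s = 0.0
    return res
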