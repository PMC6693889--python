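"""Synthetic virtual-corridor sessions with ground truth.

The generator emulates the statistical structure the downstream analyses
assume: a head-fixed mouse runs through a 360-cm patterned corridor
(80/40/80/40/80 cm segments followed by a checkerboard whose 40-cm point
delivers a soy-milk reward, after which the checkerboard is held for 2.5 s),
decelerating and licking in anticipation of reward.  Units are inhomogeneous
point processes simulated by Bernoulli thinning on a 1 kHz grid (the same
resolution as the 1-ms analysis bins):

* ``type1`` units ramp from the appearance of the rewarded checkerboard to
  reward and collapse; ``type2`` ramp and persist ~1 s; ``type3`` rise only
  after reward;
* ``run`` units follow a speed tuning curve, ``lick`` units a kernel on lick
  times;
* ``pc`` (Purkinje simple-spike) units follow tuning(speed) times a
  reward-locked multiplicative suppression, optionally carrying complex
  spikes that pause simple spiking;
* ``dn`` units are inhibited multiplicatively (rectified at zero) by each
  presynaptic PC spike through an exponential kernel at a millisecond
  latency;
* ``cf`` (climbing-fiber / fat-spike) units fire at low baseline rates with
  a reward-locked event at a configurable latency and jitter;
* photostimulation trials clamp PC intensity high, silence DN after ~2 ms
  and suppress ALM type-1/2 units after ~10 ms.

Every operation takes an explicit integer seed and is deterministic given it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .errors import ConfigError, GenerationError
from .session import BehaviorTrace, EventSeries, Session, TrialTable, Unit, Waveform

SPIKE_DT = 1e-3  # thinning resolution, matches analysis bins

# corridor segment labels in order of appearance
SEGMENTS = ("dots", "checkerboard", "triangles", "grating", "squares", "checkerboard_rewarded")


def eval_tuning(spec: dict, speed: np.ndarray) -> np.ndarray:
    """Evaluate a serializable firing-rate-vs-speed tuning function (Hz)."""
    kind = spec.get("kind", "linear")
    if kind == "linear":
        return spec["a"] + spec["b"] * speed
    if kind == "sigmoid":
        return spec["low"] + (spec["high"] - spec["low"]) / (
            1.0 + np.exp(-(speed - spec["mid"]) / spec["slope"])
        )
    raise ConfigError(f"unknown tuning kind {kind!r}")


@dataclass
class UnitSpec:
    """Roster entry: what one synthetic unit does."""

    unit_id: str
    region: str
    kind: str              # type1|type2|type3|run|lick|pc|dn|cf|poisson
    baseline: float = 5.0  # Hz
    amp: float = 20.0      # modulation amplitude, Hz
    sign: int = 1          # +1 increasing, -1 decreasing (type units)
    tuning: dict | None = None          # run / pc / dn-base units
    suppression: float = 0.0            # pc: reward-locked fractional dip in (0,1]
    cs_rate: float = 0.0                # pc: complex-spike rate, Hz
    cf_latency: float = 0.175           # cf: post-reward latency mean, s
    cf_jitter: float = 0.030            # cf: per-trial latency SD, s
    cf_prob: float = 0.9                # cf: per-trial event probability
    fwhm_ms: float = 0.25               # mean-waveform width
    photo_suppression: float = 0.0      # fraction of rate removed during photostim
    photo_lag: float = 0.0              # s after light onset


@dataclass
class Connection:
    pc_id: str
    dn_id: str
    strength: float        # in (0, 1]
    latency_ms: float = 1.0
    decay_ms: float = 3.0


@dataclass
class GenConfig:
    """All knobs of the synthetic session, with task-matched defaults."""

    n_trials: int = 60
    sample_rate: float = 100.0          # behavior Hz
    segment_lengths: tuple = (80.0, 40.0, 80.0, 40.0, 80.0, 80.0)
    reward_offset: float = 40.0         # cm into the final checkerboard
    hold_after_reward: float = 2.5      # s the checkerboard stays before reset

    # running model
    peak_speed: float = 45.0            # cm/s
    speed_noise: float = 2.0            # cm/s OU noise SD during cruise
    accel: float = 60.0                 # cm/s^2
    decel: float = 40.0                 # cm/s^2
    slow_speed: float = 12.0            # cm/s approach speed below the 20 cm/s dip
    decel_distance_mean: float = 35.0   # cm before reward where braking starts
    decel_distance_sd: float = 8.0
    false_decel_prob: float = 0.25      # per-trial prob of a dip outside the reward zone
    false_decel_speed: float = 8.0
    false_decel_duration: float = 1.5   # s at the reduced target (braking included)

    # lick model
    lick_anticipation: float = 0.5      # s before reward the burst starts (mean)
    lick_anticipation_sd: float = 0.15
    lick_rate: float = 7.0              # Hz within a burst
    lick_consume: float = 1.5           # s of post-reward licking
    false_bout_prob: float = 0.2        # per-trial prob of a 3-lick bout early in the trial

    # photostimulation model
    photo_fraction: float = 0.0         # fraction of trials with light
    photo_mode: str = "unilateral"
    photo_advance_cm: float = 20.0      # light starts this far before the reward position
    photo_duration: float = 1.0
    photo_pc_rate: float = 120.0        # Hz PC clamp during light
    photo_dn_suppression: float = 0.92
    photo_dn_lag: float = 0.002
    photo_alm_suppression: float = 0.5
    photo_alm_lag: float = 0.010

    roster: list = field(default_factory=list)        # list[UnitSpec]
    connections: list = field(default_factory=list)   # list[Connection]

    # waveform model
    wf_sample_rate_khz: float = 30.0
    wf_n_samples: int = 150
    wf_peak_index: int = 30
    wf_noise_sd: float = 0.05           # relative to unit template peak of 1.0
    wf_noise_smooth: float = 1.5        # samples; correlated noise, as band-limited data
    wf_repol_range: tuple = (0.05, 0.25)  # per-spike repolarization-bump amplitude (uniform)
    cs_snr: float = 5.0                 # CS late-peak amplitude / noise SD
    cs_pause: float = 0.015             # s of simple-spike silence after a CS

    def __post_init__(self) -> None:
        if self.n_trials <= 0:
            raise ConfigError("n_trials must be positive")
        if not 0.0 <= self.photo_fraction <= 1.0:
            raise ConfigError("photo_fraction must be in [0, 1]")
        for c in self.connections:
            if not 0.0 < c.strength <= 1.0:
                raise ConfigError("connection strength must be in (0, 1]")
            if c.latency_ms < 0:
                raise ConfigError("connection latency must be >= 0")

    @property
    def reward_position(self) -> float:
        return float(sum(self.segment_lengths[:-1]) + self.reward_offset)

    @property
    def segment_starts(self) -> dict[str, float]:
        starts, acc = {}, 0.0
        for name, ln in zip(SEGMENTS, self.segment_lengths):
            starts[name] = acc
            acc += ln
        return starts


@dataclass
class GroundTruth:
    """Everything the generator knows that the analyses must recover."""

    units: dict = field(default_factory=dict)          # uid -> spec summary
    connections: list = field(default_factory=list)
    false_decel_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    false_bout_starts: np.ndarray = field(default_factory=lambda: np.empty(0))
    anticipatory_starts: np.ndarray = field(default_factory=lambda: np.empty(0))
    photo_virtual_onsets: np.ndarray = field(default_factory=lambda: np.empty(0))  # control trials
    cs_times: dict = field(default_factory=dict)       # uid -> array
    cs_flags: dict = field(default_factory=dict)       # uid -> bool array over merged spikes

    def to_json(self, path: str | Path) -> None:
        def _conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, dict):
                return {k: _conv(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [_conv(v) for v in x]
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            return x

        payload = {k: _conv(v) for k, v in self.__dict__.items()}
        Path(path).write_text(json.dumps(payload))


# ---------------------------------------------------------------------------
# behavior


def generate_behavior(
    config: GenConfig, seed: int
) -> tuple[BehaviorTrace, EventSeries, TrialTable, GroundTruth]:
    """Simulate running, licking, corridor events and the trial table.

    Position is the integral of speed and resets each trial; exactly one
    reward per completed trial, delivered the moment the mouse reaches the
    reward position; the corridor is then held for 2.5 s before reset.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xBEA]))
    dt = 1.0 / config.sample_rate
    reward_pos = config.reward_position
    seg_starts = config.segment_starts

    speed_chunks, pos_chunks = [], []
    rewards, trial_starts, trial_rewards = [], [], []
    cue_times: dict[str, list[float]] = {name: [] for name in SEGMENTS}
    photo_onsets, photo_durations, photo_modes = [], [], []
    trial_photo: list[str] = []
    virtual_onsets = []
    false_decels = []
    lick_times: list[float] = []
    false_bout_starts, anticipatory_starts = [], []

    t = 0.0
    v = 5.0
    for _ in range(config.n_trials):
        trial_starts.append(t)
        is_photo = rng.random() < config.photo_fraction

        decel_at = reward_pos - np.clip(
            rng.normal(config.decel_distance_mean, config.decel_distance_sd), 20.0, 60.0
        )
        do_fd = rng.random() < config.false_decel_prob
        fd_pos = rng.uniform(100.0, 200.0) if do_fd else np.inf
        fd_until = -1.0  # time the false dip ends

        pos = 0.0
        seen = set()
        photo_on = None
        speeds, poss = [], []
        reward_t = None
        while reward_t is None:
            for name in SEGMENTS:
                if pos >= seg_starts[name] and name not in seen:
                    seen.add(name)
                    cue_times[name].append(t)
            photo_trigger = pos >= reward_pos - config.photo_advance_cm
            if photo_trigger and photo_on is None:
                photo_on = t
                if is_photo:
                    photo_onsets.append(t)
                    photo_durations.append(config.photo_duration)
                    photo_modes.append(config.photo_mode)
                else:
                    virtual_onsets.append(t)
            if pos >= fd_pos and fd_until < 0:
                fd_until = t + config.false_decel_duration
                false_decels.append(t)
            if t < fd_until:
                target = config.false_decel_speed
            elif pos >= decel_at:
                target = config.slow_speed
            else:
                target = config.peak_speed
            dv = np.clip(target - v, -config.decel * dt, config.accel * dt)
            v = max(v + dv + rng.normal(0.0, config.speed_noise) * np.sqrt(dt), 0.5)
            pos += v * dt
            t += dt
            speeds.append(v)
            poss.append(min(pos, reward_pos))
            if pos >= reward_pos:
                reward_t = t
        rewards.append(reward_t)
        trial_rewards.append(reward_t)
        trial_photo.append(config.photo_mode if is_photo else "none")

        # anticipatory + consummatory lick burst
        burst = reward_t - max(abs(rng.normal(config.lick_anticipation, config.lick_anticipation_sd)), 0.05)
        anticipatory_starts.append(burst)
        lt = burst
        while lt < reward_t + config.lick_consume:
            lick_times.append(lt)
            lt += 1.0 / config.lick_rate * (1.0 + 0.1 * rng.standard_normal())
        if rng.random() < config.false_bout_prob:
            fb = trial_starts[-1] + rng.uniform(0.25, 0.5) * (reward_t - trial_starts[-1])
            false_bout_starts.append(fb)
            for k in range(3):
                lick_times.append(fb + k / config.lick_rate)

        # post-reward hold: corridor frozen, mouse slows to a consummatory crawl
        n_hold = int(round(config.hold_after_reward / dt))
        for _ in range(n_hold):
            dv = np.clip(2.0 - v, -config.decel * dt, config.accel * dt)
            v = max(v + dv, 0.5)
            t += dt
            speeds.append(v)
            poss.append(reward_pos)
        speed_chunks.append(np.array(speeds))
        pos_chunks.append(np.array(poss))

    behavior = BehaviorTrace(
        sample_rate=config.sample_rate,
        running_speed=np.concatenate(speed_chunks),
        corridor_position=np.concatenate(pos_chunks),
    )
    duration = behavior.duration
    licks = np.sort(np.array([x for x in lick_times if 0 <= x <= duration]))
    licks = licks[np.insert(np.diff(licks) > 1e-4, 0, True)]
    events = EventSeries(
        reward_times=np.array(rewards),
        lick_times=licks,
        cue_times={k: np.array(v) for k, v in cue_times.items() if len(v)},
        photo_onsets=np.array(photo_onsets),
        photo_durations=np.array(photo_durations),
        photo_modes=photo_modes,
    )
    trials = TrialTable(
        index=np.arange(config.n_trials),
        start_time=np.array(trial_starts),
        reward_time=np.array(trial_rewards),
        photo_mode=trial_photo,
    )
    truth = GroundTruth(
        false_decel_times=np.array(false_decels),
        false_bout_starts=np.array(false_bout_starts),
        anticipatory_starts=np.array(anticipatory_starts),
        photo_virtual_onsets=np.array(virtual_onsets),
    )
    return behavior, events, trials, truth


# ---------------------------------------------------------------------------
# spikes


def _ramp_profile(t: np.ndarray, cues: np.ndarray, rewards: np.ndarray, kind: str) -> np.ndarray:
    """Unit-amplitude temporal profile of a type-1/2/3 unit on grid ``t``."""
    prof = np.zeros_like(t)
    for cue, rew in zip(cues, rewards):
        if not np.isfinite(rew):
            continue
        if kind in ("type1", "type2"):
            m = (t >= cue) & (t < rew)
            prof[m] = np.maximum(prof[m], (t[m] - cue) / max(rew - cue, 1e-6))
            if kind == "type1":
                m2 = (t >= rew) & (t < rew + 0.3)
                prof[m2] = np.maximum(prof[m2], np.exp(-(t[m2] - rew) / 0.05))
            else:
                m2 = (t >= rew) & (t < rew + 1.0)
                prof[m2] = np.maximum(prof[m2], 1.0)
                m3 = (t >= rew + 1.0) & (t < rew + 2.0)
                prof[m3] = np.maximum(prof[m3], np.exp(-(t[m3] - rew - 1.0) / 0.2))
        elif kind == "type3":
            rise0, rise1, hold_end, decay = rew + 0.05, rew + 0.3, rew + 1.0, 0.3
            m = (t >= rise0) & (t < rise1)
            prof[m] = np.maximum(prof[m], (t[m] - rise0) / (rise1 - rise0))
            m = (t >= rise1) & (t < hold_end)
            prof[m] = np.maximum(prof[m], 1.0)
            m = (t >= hold_end) & (t < hold_end + 1.5)
            prof[m] = np.maximum(prof[m], np.exp(-(t[m] - hold_end) / decay))
    return prof


def _match_cues_to_rewards(cues: np.ndarray, rewards: np.ndarray) -> np.ndarray:
    """For each reward, the latest rewarded-checkerboard appearance preceding it."""
    out = np.empty_like(rewards)
    for i, r in enumerate(rewards):
        prior = cues[cues < r]
        out[i] = prior[-1] if prior.size else max(r - 2.0, 0.0)
    return out


def _exp_kernel(latency_ms: float, decay_ms: float) -> np.ndarray:
    """Unit-peak causal kernel sampled at 1 kHz: 0 before the latency, then exp decay."""
    n = int(np.ceil((latency_ms + 6.0 * decay_ms) / 1.0)) + 1
    tau_ms = np.arange(n) * 1.0
    k = np.where(tau_ms >= latency_ms, np.exp(-np.maximum(tau_ms - latency_ms, 0.0) / decay_ms), 0.0)
    return k


def generate_spikes(
    behavior: BehaviorTrace,
    events: EventSeries,
    trials: TrialTable,
    config: GenConfig,
    seed: int,
    truth: GroundTruth | None = None,
) -> tuple[dict[str, np.ndarray], GroundTruth]:
    """Draw every roster unit as an inhomogeneous point process (1 kHz thinning)."""
    ss = np.random.SeedSequence([int(seed), 0x59C])
    child = {spec.unit_id: s for spec, s in zip(config.roster, ss.spawn(len(config.roster) + 1))}
    rng_global = np.random.default_rng(ss.spawn(1)[0])

    duration = behavior.duration
    n = int(round(duration / SPIKE_DT))
    t = (np.arange(n) + 0.5) * SPIKE_DT
    speed = np.interp(t, behavior.times, behavior.running_speed)
    rewards = events.reward_times
    cue_rew = events.cue_times.get("checkerboard_rewarded", np.empty(0))
    cue_match = _match_cues_to_rewards(cue_rew, rewards) if rewards.size else rewards

    # reward-locked PC suppression profile (shared shape; scaled per unit)
    supp = np.zeros(n)
    for r in rewards:
        m = (t >= r - 2.0) & (t < r)
        supp[m] = np.maximum(supp[m], (t[m] - (r - 2.0)) / 2.0)
        m2 = (t >= r) & (t < r + 0.5)
        supp[m2] = np.maximum(supp[m2], 1.0 - (t[m2] - r) / 0.5)

    # photostimulation masks
    def _photo_mask(lag: float) -> np.ndarray:
        m = np.zeros(n, dtype=bool)
        for on, dur in zip(events.photo_onsets, events.photo_durations):
            i0 = int(np.ceil((on + lag) / SPIKE_DT - 1e-9))
            i1 = int(np.floor((on + dur) / SPIKE_DT))
            m[max(i0, 0) : max(i1, 0)] = True
        return m

    mask_pc = _photo_mask(0.0)
    mask_dn = _photo_mask(config.photo_dn_lag)
    mask_alm = _photo_mask(config.photo_alm_lag)

    truth = truth or GroundTruth()
    truth.connections = [asdict(c) for c in config.connections]
    conn_by_dn: dict[str, list[Connection]] = {}
    for c in config.connections:
        conn_by_dn.setdefault(c.dn_id, []).append(c)

    def _thin(lam: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        p = lam * SPIKE_DT
        if np.any(p > 1.0):
            raise GenerationError(
                "intensity*dt exceeds 1 at 1 kHz resolution; lower the configured rates"
            )
        hit = rng.random(n) < p
        times = t[hit] - 0.5 * SPIKE_DT + rng.random(int(hit.sum())) * SPIKE_DT
        return times

    def _base_intensity(spec: UnitSpec) -> np.ndarray:
        if spec.kind in ("type1", "type2", "type3"):
            prof = _ramp_profile(t, cue_match, rewards, spec.kind)
            lam = spec.baseline + spec.sign * spec.amp * prof
        elif spec.kind == "run":
            lam = eval_tuning(spec.tuning, speed)
        elif spec.kind == "lick":
            lam = np.full(n, spec.baseline)
            for lk in events.lick_times:
                i0, i1 = int((lk - 0.15) / SPIKE_DT), int((lk + 0.15) / SPIKE_DT)
                i0, i1 = max(i0, 0), min(i1, n)
                lam[i0:i1] += spec.amp * np.exp(-0.5 * ((t[i0:i1] - lk) / 0.05) ** 2)
        elif spec.kind == "pc":
            lam = eval_tuning(spec.tuning, speed) * (1.0 - spec.suppression * supp)
        elif spec.kind == "dn":
            if spec.tuning is not None:
                lam = eval_tuning(spec.tuning, speed)
            else:
                prof = _ramp_profile(t, cue_match, rewards, "type2")
                lam = spec.baseline + spec.sign * spec.amp * prof
        elif spec.kind == "cf":
            lam = np.full(n, spec.baseline)
        elif spec.kind == "poisson":
            lam = np.full(n, spec.baseline)
        else:
            raise ConfigError(f"unknown unit kind {spec.kind!r}")
        return np.maximum(lam, 0.0)

    spikes: dict[str, np.ndarray] = {}
    pc_train_bins: dict[str, np.ndarray] = {}

    # pass 1: all non-DN units (PCs first so DN inhibition can see their spikes)
    for spec in config.roster:
        if spec.kind == "dn":
            continue
        rng = np.random.default_rng(child[spec.unit_id])
        lam = _base_intensity(spec)
        if spec.kind == "pc" and mask_pc.any():
            lam[mask_pc] = config.photo_pc_rate
        if spec.region == "ALM" and spec.kind in ("type1", "type2") and mask_alm.any():
            lam[mask_alm] *= 1.0 - config.photo_alm_suppression
        if spec.photo_suppression > 0.0:
            m = _photo_mask(spec.photo_lag)
            lam[m] *= 1.0 - spec.photo_suppression
        times = _thin(lam, rng)

        if spec.kind == "cf":
            inj = []
            for r in rewards:
                if rng.random() < spec.cf_prob:
                    inj.append(r + rng.normal(spec.cf_latency, spec.cf_jitter))
            times = np.unique(np.concatenate([times, np.array(inj)]))
            times = times[(times >= 0) & (times <= duration)]

        if spec.kind == "pc" and spec.cs_rate > 0.0:
            cs = _thin(np.full(n, spec.cs_rate), rng)
            keep = np.ones(times.size, dtype=bool)
            for c in cs:  # complex spikes silence simple spiking for a short pause
                keep &= ~((times > c) & (times <= c + config.cs_pause))
            merged = np.concatenate([times[keep], cs])
            order = np.argsort(merged)
            merged = merged[order]
            flags = np.concatenate([np.zeros(int(keep.sum()), bool), np.ones(cs.size, bool)])[order]
            times = merged
            truth.cs_times[spec.unit_id] = cs
            truth.cs_flags[spec.unit_id] = flags

        times = np.unique(times)
        spikes[spec.unit_id] = times
        if spec.kind == "pc":
            bins = np.zeros(n)
            np.add.at(bins, np.minimum((times / SPIKE_DT).astype(int), n - 1), 1.0)
            pc_train_bins[spec.unit_id] = bins

        truth.units[spec.unit_id] = {
            "kind": spec.kind,
            "true_type": {"type1": 1, "type2": 2, "type3": 3}.get(spec.kind, 0),
            "sign": spec.sign,
            "baseline": spec.baseline,
            "amp": spec.amp,
            "suppression": spec.suppression,
            "tuning": spec.tuning,
            "photo_suppression": spec.photo_suppression,
        }

    # pass 2: DN units, multiplicatively inhibited by their presynaptic PCs
    for spec in config.roster:
        if spec.kind != "dn":
            continue
        rng = np.random.default_rng(child[spec.unit_id])
        lam = _base_intensity(spec)
        for c in conn_by_dn.get(spec.unit_id, []):
            k = _exp_kernel(c.latency_ms, c.decay_ms)
            g = np.convolve(pc_train_bins[c.pc_id], k)[:n]
            lam *= np.maximum(1.0 - c.strength * g, 0.0)
        if mask_dn.any():
            lam[mask_dn] *= 1.0 - config.photo_dn_suppression
        spikes[spec.unit_id] = _thin(lam, rng)
        truth.units[spec.unit_id] = {
            "kind": "dn",
            "true_type": 0,
            "sign": spec.sign,
            "baseline": spec.baseline,
            "amp": spec.amp,
            "suppression": 0.0,
            "tuning": spec.tuning,
            "photo_suppression": config.photo_dn_suppression if mask_dn.any() else 0.0,
        }

    del rng_global
    return spikes, truth


# ---------------------------------------------------------------------------
# waveforms


def _template(config: GenConfig, fwhm_ms: float) -> np.ndarray:
    """Negative spike with a small fixed repolarization bump; peak amplitude 1."""
    i = np.arange(config.wf_n_samples, dtype=float)
    t_ms = (i - config.wf_peak_index) / config.wf_sample_rate_khz
    sigma = fwhm_ms / 2.3548200450309493
    w = -np.exp(-0.5 * (t_ms / sigma) ** 2)
    w += _ahp(config)                                      # slow afterhyperpolarization
    return w


def _ahp(config: GenConfig) -> np.ndarray:
    i = np.arange(config.wf_n_samples, dtype=float)
    t_ms = (i - config.wf_peak_index) / config.wf_sample_rate_khz
    return -0.25 * np.exp(-0.5 * ((t_ms - 1.8) / 0.7) ** 2) * (t_ms > 0.3)


def _repol_bump(config: GenConfig) -> np.ndarray:
    """Unit-amplitude repolarization overshoot just after the spike peak.

    Its amplitude varies spike to spike (afterpotentials fluctuate with the
    preceding firing history), which spreads the bulk of the late-peak
    distribution without fattening its upper tail.
    """
    i = np.arange(config.wf_n_samples, dtype=float)
    t_ms = (i - config.wf_peak_index) / config.wf_sample_rate_khz
    return np.exp(-0.5 * ((t_ms - 0.8) / 0.3) ** 2)


def _cs_extra(config: GenConfig, fwhm_ms: float) -> np.ndarray:
    """Difference between a complex-spike and a simple-spike waveform.

    A complex spike has a broader initial deflection (dendritic currents
    widen the somatic spike) followed by a slow positive depolarization with
    a spikelet riding on it.  The added late positive envelope peaks at
    ``cs_snr`` times the waveform noise SD within 3 ms of the spike peak.
    """
    i = np.arange(config.wf_n_samples, dtype=float)
    t_ms = (i - config.wf_peak_index) / config.wf_sample_rate_khz
    broadened = _template(config, 2.2 * fwhm_ms) - _template(config, fwhm_ms)
    env = np.exp(-0.5 * ((t_ms - 1.8) / 0.6) ** 2)
    env += 0.5 * np.exp(-0.5 * ((t_ms - 1.1) / 0.15) ** 2)  # spikelet
    env[t_ms <= 0.2] = 0.0
    late = config.cs_snr * config.wf_noise_sd * env / env.max()
    # the dendritic depolarization replaces the simple-spike afterhyperpolarization
    return broadened - _ahp(config) + late


def generate_waveforms(
    config: GenConfig,
    spikes: dict[str, np.ndarray],
    truth: GroundTruth,
    seed: int,
) -> tuple[dict[str, Waveform], dict[str, np.ndarray]]:
    """Mean waveforms for every roster unit and per-spike streams for PC units.

    Noise is additive, Gaussian and band-limited (smoothed over a few samples)
    with SD ``wf_noise_sd`` relative to a unit template peak of 1.  Spikes the
    generator labelled as complex carry a positive late peak within 3 ms of
    the spike peak whose amplitude is ``cs_snr`` times the noise SD.
    """
    from scipy.ndimage import gaussian_filter1d

    ss = np.random.SeedSequence([int(seed), 0x3AF])
    rngs = {spec.unit_id: np.random.default_rng(s) for spec, s in zip(config.roster, ss.spawn(len(config.roster)))}

    mean_waveforms: dict[str, Waveform] = {}
    streams: dict[str, np.ndarray] = {}
    repol = _repol_bump(config)
    u_mean = 0.5 * (config.wf_repol_range[0] + config.wf_repol_range[1])
    for spec in config.roster:
        tpl = _template(config, spec.fwhm_ms)
        mean_waveforms[spec.unit_id] = Waveform(
            tpl + u_mean * repol, config.wf_sample_rate_khz, config.wf_peak_index
        )
        if spec.kind != "pc":
            continue
        times = spikes[spec.unit_id]
        rng = rngs[spec.unit_id]
        noise = rng.standard_normal((times.size, config.wf_n_samples))
        noise = gaussian_filter1d(noise, config.wf_noise_smooth, axis=1, mode="nearest")
        noise *= config.wf_noise_sd / max(noise.std(), 1e-12)
        u = rng.uniform(*config.wf_repol_range, times.size)
        stream = tpl[None, :] + u[:, None] * repol[None, :] + noise
        flags = truth.cs_flags.get(spec.unit_id)
        if flags is not None and flags.any():
            stream[flags] += _cs_extra(config, spec.fwhm_ms)[None, :]
        streams[spec.unit_id] = stream
        mean_waveforms[spec.unit_id] = Waveform(
            stream.mean(axis=0), config.wf_sample_rate_khz, config.wf_peak_index
        )
    return mean_waveforms, streams


# ---------------------------------------------------------------------------
# one-call convenience


def generate_session(
    config: GenConfig, seed: int, session_id: str = "synthetic", with_waveforms: bool = False
) -> tuple[Session, GroundTruth, dict[str, np.ndarray]]:
    """Behavior + spikes (+ optional waveforms) bundled into a Session."""
    behavior, events, trials, truth = generate_behavior(config, seed)
    spikes, truth = generate_spikes(behavior, events, trials, config, seed, truth)
    streams: dict[str, np.ndarray] = {}
    units = []
    if with_waveforms:
        waveforms, streams = generate_waveforms(config, spikes, truth, seed)
        for spec in config.roster:
            units.append(Unit(spec.unit_id, spec.region, None, waveforms[spec.unit_id]))
    else:
        units = [Unit(spec.unit_id, spec.region) for spec in config.roster]
    session = Session(
        session_id=session_id,
        units=units,
        spikes=spikes,
        behavior=behavior,
        events=events,
        trials=trials,
        meta={"reward_position_cm": config.reward_position},
    )
    return session, truth, streams
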