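"""End-to-end recovery experiments on synthetic ground truth.

Each function simulates the study conditions with the session generator (or
a direct small-scale simulation where that is the cleaner oracle), runs the
corresponding analysis stage, and returns a dict of plain scalars: recovery
rates, false-positive counts, parameter errors, regression coefficients.
The acceptance test suite asserts on these numbers and
``scripts/acceptance.py`` reports them.

Problem sizes follow the generator's study conditions: 30-minute sessions
for connectivity, 200 trials for GLM type recovery, 100 trials for the
tuning-residual and photostimulation experiments.
"""

from __future__ import annotations

import numpy as np

from . import connectivity as conn
from . import glm, photo, rates, speed_tuning, unit_typing
from .synth import Connection, GenConfig, UnitSpec, generate_session

PC_TUNING = {"kind": "linear", "a": 40.0, "b": 0.2}


def _seed(seed: int, tag: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(seed) % (2**31), tag])


# ---------------------------------------------------------------------------
# cross-correlogram oracle


def ccg_oracle_check(seed: int = 0, n_pairs: int = 10, n_spikes: int = 1000) -> dict:
    """Bin-exact agreement of the fast CCG with the O(n^2) double loop."""
    rng = np.random.default_rng(_seed(seed, 1))
    max_diff = 0.0
    for _ in range(n_pairs):
        a = np.sort(rng.uniform(0.0, 60.0, n_spikes))
        b = np.sort(rng.uniform(0.0, 60.0, n_spikes))
        fast = conn.compute_ccg(a, b).counts
        slow = conn.brute_force_ccg(a, b)
        max_diff = max(max_diff, float(np.max(np.abs(fast - slow))))
    return {"max_abs_diff": max_diff, "n_pairs": n_pairs, "n_spikes": n_spikes}


# ---------------------------------------------------------------------------
# connectivity recovery


def connectivity_recovery(
    seed: int = 0,
    n_connected: int = 20,
    n_unconnected: int = 80,
    strength: float = 0.5,
    latency_ms: float = 1.0,
    n_trials: int = 170,
) -> dict:
    """Monosynaptic-call sensitivity/false positives on a 30-min paired session."""
    roster, connections = [], []
    for i in range(n_connected + n_unconnected):
        roster.append(UnitSpec(f"pc{i}", "CRUS1", "pc", tuning=dict(PC_TUNING), suppression=0.3))
        roster.append(UnitSpec(f"dn{i}", "DN", "dn", baseline=25.0, amp=10.0))
        if i < n_connected:
            connections.append(Connection(f"pc{i}", f"dn{i}", strength, latency_ms))
    cfg = GenConfig(n_trials=n_trials, roster=roster, connections=connections)
    session, truth, _ = generate_session(cfg, seed)

    hits = fp = 0
    strengths = []
    for i in range(n_connected + n_unconnected):
        ccg = conn.compute_ccg(session.spikes[f"pc{i}"], session.spikes[f"dn{i}"])
        call = conn.detect_modulation(ccg)
        if i < n_connected:
            if call.modulated and call.sign == "inhibited":
                hits += 1
                strengths.append(call.strength)
        elif call.modulated:
            fp += 1
    return {
        "sensitivity": hits / n_connected,
        "false_positives": fp,
        "n_unconnected": n_unconnected,
        "detected_strength_max": float(np.max(strengths)) if strengths else float("nan"),
        "duration_min": session.duration / 60.0,
    }


def shuffle_null(seed: int = 0, n_pairs: int = 50, n_trials: int = 120) -> dict:
    """Shuffle-corrected CCG on rate-comodulated but unconnected pairs.

    Every pair shares the trial-locked slow structure (PC suppression ramp,
    DN ramp) but has no synaptic coupling; the corrected correlogram in the
    10 ms after the PC spike should be statistically indistinguishable from
    zero.  Returns the across-pair mean and SE of the post-spike corrected
    bins.
    """
    roster = []
    for i in range(n_pairs):
        roster.append(UnitSpec(f"pc{i}", "CRUS1", "pc", tuning=dict(PC_TUNING), suppression=0.3))
        roster.append(UnitSpec(f"dn{i}", "DN", "dn", baseline=25.0, amp=10.0))
    cfg = GenConfig(n_trials=n_trials, roster=roster)
    session, _, _ = generate_session(cfg, seed)
    means = []
    for i in range(n_pairs):
        sc = conn.shuffle_corrected_ccg(
            session.spikes[f"pc{i}"], session.spikes[f"dn{i}"], session.events.reward_times
        )
        post = (sc.lags_ms >= 0.0) & (sc.lags_ms < 10.0)
        means.append(np.nanmean(sc.corrected[post]))
    means = np.asarray(means)
    return {
        "mean_corrected": float(means.mean()),
        "se": float(means.std(ddof=1) / np.sqrt(n_pairs)),
        "n_pairs": n_pairs,
    }


# ---------------------------------------------------------------------------
# GLM type recovery


def _typed_roster(n_per_type: int) -> list:
    roster = []
    for k, kind in enumerate(("type1", "type2", "type3")):
        for i in range(n_per_type):
            roster.append(UnitSpec(f"{kind}_{i}", "ALM", kind, baseline=5.0, amp=20.0))
    return roster


def glm_type_recovery(seed: int = 0, n_per_type: int = 10, n_trials: int = 200) -> dict:
    """Fraction of synthetic type-1/2/3 units recovered by the 0.17 R^2 rule."""
    cfg = GenConfig(n_trials=n_trials, roster=_typed_roster(n_per_type))
    session, truth, _ = generate_session(cfg, seed)
    cls = glm.classify_session_units(session, covariates=("reward", "run"))
    n_correct = sum(
        int(cls[uid].unit_type == truth.units[uid]["true_type"]) for uid in truth.units
    )
    return {"n_correct": n_correct, "n_units": 3 * n_per_type}


def glm_false_positive(seed: int = 0, n_units: int = 100, n_trials: int = 60) -> dict:
    """Unmodulated Poisson units falsely classified as reward-modulated."""
    roster = [UnitSpec(f"null{i}", "ALM", "poisson", baseline=10.0) for i in range(n_units)]
    cfg = GenConfig(n_trials=n_trials, roster=roster)
    session, _, _ = generate_session(cfg, seed)
    cls = glm.classify_session_units(session, covariates=("reward", "run"))
    n_false = sum(int(c.unit_type != 0) for c in cls.values())
    return {"n_false_reward": n_false, "n_units": n_units}


# ---------------------------------------------------------------------------
# complex-spike detection


def cs_detection(seed: int = 0, n_trials: int = 40, cs_rate: float = 0.5) -> dict:
    """Precision/recall of complex-spike detection at ~1% CS and SNR 5."""
    roster = [
        UnitSpec("pc0", "CRUS1", "pc", tuning=dict(PC_TUNING), suppression=0.3, cs_rate=cs_rate)
    ]
    cfg = GenConfig(n_trials=n_trials, roster=roster)
    session, truth, streams = generate_session(cfg, seed, with_waveforms=True)
    spikes = session.spikes["pc0"]
    stream = streams["pc0"]
    flags = truth.cs_flags["pc0"]
    res = unit_typing.detect_complex_spikes(
        stream,
        spikes,
        cfg.wf_sample_rate_khz,
        cfg.wf_peak_index,
        baseline_rate=spikes.size / session.duration,
    )
    detected = np.isin(spikes, res.cs_times)
    tp = int(np.sum(detected & flags))
    precision = tp / max(int(detected.sum()), 1)
    recall = tp / max(int(flags.sum()), 1)
    partition = res.cs_times.size + res.ss_times.size == spikes.size
    return {
        "precision": float(precision),
        "recall": float(recall),
        "partition_exact": bool(partition),
        "cs_fraction": float(flags.mean()),
        "n_spikes": int(spikes.size),
    }


# ---------------------------------------------------------------------------
# ISI lognormal fit + PC clustering


def isi_recovery(seed: int = 0, n_isis: int = 5000, mu: float = -3.0, sigma: float = 0.5) -> dict:
    """Parameter error of the lognormal ISI fit on a known sample."""
    rng = np.random.default_rng(_seed(seed, 6))
    isis = rng.lognormal(mu, sigma, n_isis)
    spikes = np.cumsum(isis)
    fit = unit_typing.fit_isi_lognormal(spikes)
    return {"mu_error": abs(fit.mu - mu), "sigma_error": abs(fit.sigma - sigma), "n": n_isis}


def pc_cluster_recovery(seed: int = 0, n_units: int = 40, pc_frac: float = 0.6) -> dict:
    """k-means PC/non-PC label agreement on a two-cluster ISI generator.

    PC-like units: fast, regular (log-ISI mean -4.0, SD 0.5); interneuron-like
    units: slow, irregular (mean -2.3, SD 1.0) -- the separation seen between
    Purkinje cells and molecular/granule-layer interneurons.
    """
    rng = np.random.default_rng(_seed(seed, 7))
    n_pc = int(round(n_units * pc_frac))
    fits, labels = [], []
    for i in range(n_units):
        is_pc = i < n_pc
        mu = rng.normal(-4.0 if is_pc else -2.3, 0.15)
        sg = rng.normal(0.5 if is_pc else 1.0, 0.05)
        isis = rng.lognormal(mu, max(sg, 0.05), 2000)
        fits.append(unit_typing.fit_isi_lognormal(np.cumsum(isis), unit_id=f"u{i}"))
        labels.append("PC" if is_pc else "non-PC")
    got = unit_typing.cluster_putative_pcs(fits, seed=int(np.asarray(_seed(seed, 8).generate_state(1))[0] % 2**31))
    acc = np.mean([got[f.unit_id] == lbl for f, lbl in zip(fits, labels)])
    return {"accuracy": float(acc), "n_units": n_units}


# ---------------------------------------------------------------------------
# speed-tuning residual test


def _residual_flag(session, uid: str, decel, rewards) -> bool:
    spikes = session.spikes[uid]
    trace = rates.estimate_rate(spikes, session.duration, unit_id=uid)
    curve = speed_tuning.build_tuning(session.behavior, trace, unit_id=uid)
    curve = speed_tuning.fit_tuning_spline(curve)
    pred, _ = speed_tuning.model_rate(
        speed_tuning.lowpass_speed(session.behavior), curve
    )
    model = rates.RateTrace(pred, session.behavior.sample_rate, 0.0)
    res = speed_tuning.residual_test(model, trace, decel, rewards, unit_id=uid)
    return res.overestimates_at_reward


def tuning_residual_experiment(
    seed: int = 0, n_per_group: int = 20, n_trials: int = 100, suppression: float = 0.3
) -> dict:
    """Residual-test flag rates for pure-speed vs reward-suppressed PCs."""
    roster = []
    for i in range(n_per_group):
        roster.append(UnitSpec(f"pure{i}", "CRUS1", "pc", tuning=dict(PC_TUNING), suppression=0.0))
        roster.append(
            UnitSpec(f"supp{i}", "CRUS1", "pc", tuning=dict(PC_TUNING), suppression=suppression)
        )
    cfg = GenConfig(n_trials=n_trials, roster=roster, false_decel_prob=0.10)
    session, truth, _ = generate_session(cfg, seed)
    rewards = session.events.reward_times
    excl = rates.reward_exclusion_windows(rewards)
    decel = rates.detect_decelerations(session.behavior, excl)
    flags_pure = [_residual_flag(session, f"pure{i}", decel, rewards) for i in range(n_per_group)]
    flags_supp = [_residual_flag(session, f"supp{i}", decel, rewards) for i in range(n_per_group)]
    return {
        "null_flag_rate": float(np.mean(flags_pure)),
        "suppressed_flag_rate": float(np.mean(flags_supp)),
        "n_decel": int(decel.size),
        "n_rewards": int(rewards.size),
        "n_per_group": n_per_group,
    }


def decreasing_pc_selection(seed: int = 0, n_per_group: int = 20, n_trials: int = 40) -> dict:
    """Pre-reward-decrease selection of suppressed vs non-suppressed PCs."""
    roster = []
    for i in range(n_per_group):
        roster.append(UnitSpec(f"pure{i}", "CRUS1", "pc", tuning=dict(PC_TUNING), suppression=0.0))
        roster.append(UnitSpec(f"supp{i}", "CRUS1", "pc", tuning=dict(PC_TUNING), suppression=0.4))
    cfg = GenConfig(n_trials=n_trials, roster=roster)
    session, _, _ = generate_session(cfg, seed)
    rewards = session.events.reward_times
    correct = 0
    for i in range(n_per_group):
        for name, expect in ((f"pure{i}", False), (f"supp{i}", True)):
            trace = rates.estimate_rate(session.spikes[name], session.duration)
            psth = rates.align_psth(trace, rewards, (-4.0, 2.0), 0.05)
            if speed_tuning.select_decreasing_pcs(psth) == expect:
                correct += 1
    return {"agreement": correct / (2 * n_per_group), "n_units": 2 * n_per_group}


# ---------------------------------------------------------------------------
# photostimulation


def photo_detection(seed: int = 0, n_dn: int = 40, n_null: int = 60, n_trials: int = 100) -> dict:
    """Detection of injected DN silencing and the false-positive rate."""
    roster = [UnitSpec(f"dn{i}", "DN", "dn", baseline=30.0, amp=15.0) for i in range(n_dn)]
    roster += [UnitSpec(f"null{i}", "ALM", "poisson", baseline=12.0) for i in range(n_null)]
    cfg = GenConfig(n_trials=n_trials, roster=roster, photo_fraction=0.4)
    session, truth, _ = generate_session(cfg, seed)
    on = session.events.photo_onsets
    virt = truth.photo_virtual_onsets
    detected = fp = 0
    for i in range(n_dn):
        eff = photo.test_photo_modulation(session.spikes[f"dn{i}"], on, virt, f"dn{i}")
        if eff.modulation == "inhibited":
            detected += 1
    for i in range(n_null):
        eff = photo.test_photo_modulation(session.spikes[f"null{i}"], on, virt, f"null{i}")
        if eff.modulation != "none":
            fp += 1
    return {
        "detection_rate": detected / n_dn,
        "false_positive_rate": fp / n_null,
        "n_photo_trials": int(on.size),
        "n_control_trials": int(virt.size),
    }


def photo_latency_recovery(
    seed: int = 0, lags_ms=(2.0, 8.0, 10.0, 14.0), n_trials: int = 150, n_units: int = 9
) -> dict:
    """Onset-latency recovery for step suppressions at known lags.

    The single-unit first-crossing rule grazes the 2-SD band by chance in a
    small percentage of baseline bins, so the latency of a cohort is
    summarized as the median over ``n_units`` identical units (the usual
    population estimate); the reported error per lag is that of the median.
    """
    errors = {}
    for j, lag in enumerate(lags_ms):
        roster = [
            UnitSpec(f"u{i}", "ALM", "poisson", baseline=60.0,
                     photo_suppression=0.98, photo_lag=lag * 1e-3)
            for i in range(n_units)
        ]
        cfg = GenConfig(n_trials=n_trials, roster=roster, photo_fraction=0.5)
        session, _, _ = generate_session(cfg, int(seed) + 1000 * (j + 1))
        lats = [
            photo.onset_latency(session.spikes[f"u{i}"], session.events.photo_onsets, "inhibited")
            for i in range(n_units)
        ]
        errors[lag] = abs(float(np.nanmedian(lats)) - lag)
    return {"max_error_ms": max(errors.values()), "errors": {k: float(v) for k, v in errors.items()}}


def ramp_regression_recovery(
    seed: int = 0, n_sims: int = 100, n_units: int = 60, alpha_true: float = -0.8, noise: float = 0.3
) -> dict:
    """Monte-Carlo recovery of the photoactivation-effect regression.

    Effects are simulated as alpha*ramp + noise with a zero true control-rate
    coefficient; reports the mean recovered alpha, the fraction of runs with
    alpha in [-1.0, -0.6], and the fraction with beta non-significant.
    """
    rng = np.random.default_rng(_seed(seed, 9))
    alphas, alpha_ok, beta_ns = [], 0, 0
    for _ in range(n_sims):
        ramp = rng.normal(0.0, 1.0, n_units)
        ctrl = rng.gamma(4.0, 5.0, n_units)
        eff = alpha_true * ramp + rng.normal(0.0, noise, n_units)
        effects = [
            photo.PhotoEffect(f"u{i}", control_rate=ctrl[i], photo_rate=0.0, p_value=0.0,
                              modulation="inhibited", ramp_size=ramp[i], effect_size=eff[i])
            for i in range(n_units)
        ]
        res = photo.ramp_regression(effects)
        alphas.append(res["alpha"])
        alpha_ok += int(-1.0 <= res["alpha"] <= -0.6)
        beta_ns += int(res["p_beta"] > 0.05)
    return {
        "alpha_mean": float(np.mean(alphas)),
        "alpha_in_range_frac": alpha_ok / n_sims,
        "beta_nonsig_frac": beta_ns / n_sims,
        "n_sims": n_sims,
    }


# ---------------------------------------------------------------------------
# fat spikes


def fat_spike_null(seed: int = 0, n_sims: int = 200, rate: float = 1.5, n_trials: int = 40) -> dict:
    """Type-I error of the fat-spike reward-modulation test on Poisson units."""
    rng = np.random.default_rng(_seed(seed, 10))
    rewards = 12.0 * (np.arange(n_trials) + 1.0)
    duration = rewards[-1] + 5.0
    n_sig = 0
    for _ in range(n_sims):
        n = rng.poisson(rate * duration)
        spikes = np.sort(rng.uniform(0.0, duration, n))
        res = unit_typing.fat_spike_reward_modulation(spikes, rewards)
        n_sig += int(res.significant)
    return {"null_sig_rate": n_sig / n_sims, "n_sims": n_sims}


def fat_spike_cf_recovery(seed: int = 0, n_units: int = 8, n_trials: int = 60) -> dict:
    """Onset/jitter recovery for generator climbing-fiber units (175 +- 30 ms)."""
    roster = [
        UnitSpec(f"cf{i}", "CRUS1", "cf", baseline=1.0, cf_latency=0.175, cf_jitter=0.030,
                 fwhm_ms=0.8)
        for i in range(n_units)
    ]
    cfg = GenConfig(n_trials=n_trials, roster=roster)
    session, _, _ = generate_session(cfg, seed)
    onsets, jitters, n_sig = [], [], 0
    for i in range(n_units):
        res = unit_typing.fat_spike_reward_modulation(
            session.spikes[f"cf{i}"], session.events.reward_times
        )
        if res.significant:
            n_sig += 1
            onsets.append(res.onset_s)
            jitters.append(res.jitter_s)
    return {
        "n_significant": n_sig,
        "n_units": n_units,
        "onset_mean_s": float(np.mean(onsets)) if onsets else float("nan"),
        "jitter_mean_s": float(np.mean(jitters)) if jitters else float("nan"),
    }
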