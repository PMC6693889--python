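"""Session data model and plain-text on-disk format.

A *session* is one recording: per-unit sorted spike times, continuous behavior
traces (running speed and corridor position), typed event lists (rewards,
licks, visual-cue appearances, photostimulation pulses) and a trial table.

Conventions used throughout the package:

* times are seconds as floats, 0 = recording start;
* all windows are half-open ``[a, b)``; event-aligned lag 0 is the event time;
* positions are cm from the corridor start (reward at 360 cm by default);
* a session on disk is a directory of diffable CSV tables plus one JSON meta
  file (``meta.json``, ``units.csv``, ``spikes.csv``, ``behavior.csv``,
  ``events.csv``, ``trials.csv`` and optionally ``waveforms.csv``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SessionFormatError, SessionValidationError

_FLOAT_FMT = "%.12g"  # >= 9 significant digits so read(write(s)) == s numerically

REGIONS = ("ALM", "DN", "IPN", "CRUS1", "CRUS2")


@dataclass
class Waveform:
    """Mean extracellular waveform of one unit."""

    samples: np.ndarray          # amplitude vs time, arbitrary units
    sample_rate_khz: float
    peak_index: int              # index of the main (absolute) peak

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate_khz <= 0:
            raise SessionValidationError("waveform sample rate must be > 0")
        if not (0 <= self.peak_index < self.samples.size):
            raise SessionValidationError("waveform peak index outside array")

    @property
    def times_ms(self) -> np.ndarray:
        """Time axis in ms, 0 at the peak sample."""
        return (np.arange(self.samples.size) - self.peak_index) / self.sample_rate_khz


@dataclass
class Unit:
    unit_id: str
    region: str = "ALM"
    putative_class: str | None = None   # pyramidal / fast-spiking / unknown
    mean_waveform: Waveform | None = None


@dataclass
class BehaviorTrace:
    """Uniformly sampled running speed (cm/s) and corridor position (cm)."""

    sample_rate: float
    running_speed: np.ndarray
    corridor_position: np.ndarray

    def __post_init__(self) -> None:
        self.running_speed = np.asarray(self.running_speed, dtype=float)
        self.corridor_position = np.asarray(self.corridor_position, dtype=float)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.running_speed.size) / self.sample_rate

    @property
    def duration(self) -> float:
        return self.running_speed.size / self.sample_rate


@dataclass
class EventSeries:
    reward_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    lick_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    cue_times: dict[str, np.ndarray] = field(default_factory=dict)
    photo_onsets: np.ndarray = field(default_factory=lambda: np.empty(0))
    photo_durations: np.ndarray = field(default_factory=lambda: np.empty(0))
    photo_modes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.reward_times = np.asarray(self.reward_times, dtype=float)
        self.lick_times = np.asarray(self.lick_times, dtype=float)
        self.cue_times = {k: np.asarray(v, dtype=float) for k, v in self.cue_times.items()}
        self.photo_onsets = np.asarray(self.photo_onsets, dtype=float)
        self.photo_durations = np.asarray(self.photo_durations, dtype=float)


@dataclass
class TrialTable:
    index: np.ndarray
    start_time: np.ndarray
    reward_time: np.ndarray      # NaN where the trial was not rewarded
    photo_mode: list[str]        # 'none', 'unilateral' or 'bilateral'

    def __post_init__(self) -> None:
        self.index = np.asarray(self.index, dtype=int)
        self.start_time = np.asarray(self.start_time, dtype=float)
        self.reward_time = np.asarray(self.reward_time, dtype=float)

    def __len__(self) -> int:
        return self.index.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": self.index,
                "start_s": self.start_time,
                "reward_s": self.reward_time,
                "photo_mode": self.photo_mode,
            }
        )


@dataclass
class Session:
    session_id: str
    units: list[Unit]
    spikes: dict[str, np.ndarray]
    behavior: BehaviorTrace
    events: EventSeries
    trials: TrialTable
    meta: dict = field(default_factory=dict)

    def unit(self, unit_id: str) -> Unit:
        for u in self.units:
            if u.unit_id == unit_id:
                return u
        raise KeyError(unit_id)

    @property
    def duration(self) -> float:
        return self.behavior.duration


# ---------------------------------------------------------------------------
# validation

def validate_session(session: Session) -> None:
    """Check every structural invariant; raise SessionValidationError on the first hit."""
    ids = [u.unit_id for u in session.units]
    if len(set(ids)) != len(ids):
        raise SessionValidationError("duplicate unit ids")
    if session.behavior.sample_rate <= 0:
        raise SessionValidationError("behavior sample rate must be > 0")
    if session.behavior.running_speed.size != session.behavior.corridor_position.size:
        raise SessionValidationError("behavior series have unequal lengths")
    if not np.all(np.isfinite(session.behavior.running_speed)):
        raise SessionValidationError("running speed contains non-finite values")
    duration = session.behavior.duration
    for uid, times in session.spikes.items():
        if uid not in ids:
            raise SessionValidationError(f"spikes for unknown unit {uid!r}")
        if times.size and np.any(np.diff(times) <= 0):
            raise SessionValidationError(f"spike times not strictly increasing for unit {uid!r}")
        if times.size and (times[0] < 0 or times[-1] > duration):
            raise SessionValidationError(f"spike times outside recording for unit {uid!r}")
    for name, arr in [
        ("reward", session.events.reward_times),
        ("lick", session.events.lick_times),
        ("photo", session.events.photo_onsets),
        *[(f"cue:{k}", v) for k, v in session.events.cue_times.items()],
    ]:
        if arr.size and np.any(np.diff(arr) < 0):
            raise SessionValidationError(f"{name} event times not sorted")
        if arr.size and (arr[0] < 0 or arr[-1] > duration):
            raise SessionValidationError(f"{name} event outside [0, duration]")
    if session.events.photo_durations.size and np.any(session.events.photo_durations <= 0):
        raise SessionValidationError("photo durations must be > 0")
    tr = session.trials
    if len(tr) > 1 and np.any(np.diff(tr.start_time) <= 0):
        raise SessionValidationError("trials must be ordered and non-overlapping")
    starts = tr.start_time
    for r in tr.reward_time[np.isfinite(tr.reward_time)]:
        i = np.searchsorted(starts, r, side="right") - 1
        if i < 0:
            raise SessionValidationError(f"reward at {r} s precedes the first trial")
    for u in session.units:
        if u.mean_waveform is not None:
            # Waveform __post_init__ already enforced rate/peak invariants
            pass


# ---------------------------------------------------------------------------
# on-disk format

_REQUIRED = ["meta.json", "units.csv", "spikes.csv", "behavior.csv", "events.csv", "trials.csv"]


def write_session(session: Session, path: str | Path) -> None:
    """Write ``session`` as the CSV+JSON directory dialect read by :func:`read_session`."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    wf_meta: dict = {}
    wf_rows = []
    for u in session.units:
        if u.mean_waveform is not None:
            wf_meta[u.unit_id] = {
                "sample_rate_khz": u.mean_waveform.sample_rate_khz,
                "peak_index": int(u.mean_waveform.peak_index),
            }
            wf_rows.append([u.unit_id, *u.mean_waveform.samples.tolist()])

    meta = {
        "session_id": session.session_id,
        "behavior_sample_rate_hz": session.behavior.sample_rate,
        "meta": session.meta,
        "waveforms": wf_meta,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))

    pd.DataFrame(
        {
            "unit_id": [u.unit_id for u in session.units],
            "region": [u.region for u in session.units],
            "putative_class": [u.putative_class or "" for u in session.units],
        }
    ).to_csv(path / "units.csv", index=False)

    uid_col: list[str] = []
    t_col: list[float] = []
    for u in session.units:
        times = session.spikes.get(u.unit_id, np.empty(0))
        uid_col.extend([u.unit_id] * len(times))
        t_col.extend(np.asarray(times).tolist())
    pd.DataFrame({"unit_id": uid_col, "time_s": t_col}).to_csv(
        path / "spikes.csv", index=False, float_format=_FLOAT_FMT
    )

    beh = session.behavior
    pd.DataFrame(
        {"time_s": beh.times, "speed_cms": beh.running_speed, "position_cm": beh.corridor_position}
    ).to_csv(path / "behavior.csv", index=False, float_format=_FLOAT_FMT)

    ev = session.events
    rows = []
    for t in ev.reward_times:
        rows.append(("reward", t, math.nan, ""))
    for t in ev.lick_times:
        rows.append(("lick", t, math.nan, ""))
    for label, times in sorted(ev.cue_times.items()):
        for t in times:
            rows.append((f"cue:{label}", t, math.nan, ""))
    for t, d, m in zip(ev.photo_onsets, ev.photo_durations, ev.photo_modes):
        rows.append(("photo", t, d, m))
    pd.DataFrame(rows, columns=["event_type", "time_s", "duration_s", "mode"]).to_csv(
        path / "events.csv", index=False, float_format=_FLOAT_FMT
    )

    session.trials.to_frame().to_csv(path / "trials.csv", index=False, float_format=_FLOAT_FMT)

    if wf_rows:
        n = max(len(r) - 1 for r in wf_rows)
        cols = ["unit_id"] + [f"s{i}" for i in range(n)]
        pd.DataFrame(wf_rows, columns=cols).to_csv(
            path / "waveforms.csv", index=False, float_format=_FLOAT_FMT
        )


def read_session(path: str | Path) -> Session:
    """Read and validate a session directory; inverse of :func:`write_session`."""
    path = Path(path)
    for name in _REQUIRED:
        if not (path / name).exists():
            raise SessionFormatError(f"missing session file: {name}")

    meta = json.loads((path / "meta.json").read_text())
    units_df = pd.read_csv(path / "units.csv", keep_default_na=False)
    spikes_df = pd.read_csv(path / "spikes.csv")
    beh_df = pd.read_csv(path / "behavior.csv")
    ev_df = pd.read_csv(path / "events.csv", keep_default_na=False)
    tr_df = pd.read_csv(path / "trials.csv", keep_default_na=False)

    waveforms: dict[str, Waveform] = {}
    wf_path = path / "waveforms.csv"
    if wf_path.exists():
        wf_df = pd.read_csv(wf_path)
        for _, row in wf_df.iterrows():
            uid = str(row["unit_id"])
            info = meta.get("waveforms", {}).get(uid)
            if info is None:
                raise SessionFormatError(f"waveforms.csv has unit {uid!r} absent from meta.json")
            samples = row.drop("unit_id").to_numpy(dtype=float)
            waveforms[uid] = Waveform(samples, info["sample_rate_khz"], info["peak_index"])

    units = [
        Unit(
            unit_id=str(r["unit_id"]),
            region=str(r["region"]),
            putative_class=(str(r["putative_class"]) or None),
            mean_waveform=waveforms.get(str(r["unit_id"])),
        )
        for _, r in units_df.iterrows()
    ]

    spikes: dict[str, np.ndarray] = {u.unit_id: np.empty(0) for u in units}
    if len(spikes_df):
        for uid, grp in spikes_df.groupby("unit_id", sort=False):
            spikes[str(uid)] = grp["time_s"].to_numpy(dtype=float)

    behavior = BehaviorTrace(
        sample_rate=float(meta["behavior_sample_rate_hz"]),
        running_speed=beh_df["speed_cms"].to_numpy(dtype=float),
        corridor_position=beh_df["position_cm"].to_numpy(dtype=float),
    )

    def _sel(kind: str) -> pd.DataFrame:
        return ev_df[ev_df["event_type"] == kind]

    cue: dict[str, np.ndarray] = {}
    for et in ev_df["event_type"].unique():
        if str(et).startswith("cue:"):
            cue[str(et)[4:]] = np.sort(_sel(et)["time_s"].to_numpy(dtype=float))
    photo = _sel("photo")
    events = EventSeries(
        reward_times=np.sort(_sel("reward")["time_s"].to_numpy(dtype=float)),
        lick_times=np.sort(_sel("lick")["time_s"].to_numpy(dtype=float)),
        cue_times=cue,
        photo_onsets=photo["time_s"].to_numpy(dtype=float),
        photo_durations=pd.to_numeric(photo["duration_s"]).to_numpy(dtype=float),
        photo_modes=[str(m) for m in photo["mode"]],
    )

    reward_col = pd.to_numeric(tr_df["reward_s"], errors="coerce").to_numpy(dtype=float)
    trials = TrialTable(
        index=tr_df["index"].to_numpy(dtype=int),
        start_time=tr_df["start_s"].to_numpy(dtype=float),
        reward_time=reward_col,
        photo_mode=[str(m) if str(m) else "none" for m in tr_df["photo_mode"]],
    )

    session = Session(
        session_id=str(meta["session_id"]),
        units=units,
        spikes=spikes,
        behavior=behavior,
        events=events,
        trials=trials,
        meta=meta.get("meta", {}),
    )
    validate_session(session)
    return session


def sessions_equal(a: Session, b: Session, rtol: float = 1e-9) -> bool:
    """Field-by-field equality up to numeric text precision; used by round-trip tests."""
    if a.session_id != b.session_id or a.meta != b.meta:
        return False
    if [u.unit_id for u in a.units] != [u.unit_id for u in b.units]:
        return False
    for ua, ub in zip(a.units, b.units):
        if (ua.region, ua.putative_class) != (ub.region, ub.putative_class):
            return False
        wa, wb = ua.mean_waveform, ub.mean_waveform
        if (wa is None) != (wb is None):
            return False
        if wa is not None and wb is not None:
            if wa.peak_index != wb.peak_index or not np.isclose(
                wa.sample_rate_khz, wb.sample_rate_khz, rtol=rtol
            ):
                return False
            if not np.allclose(wa.samples, wb.samples, rtol=rtol, atol=1e-12):
                return False
    for uid in a.spikes:
        if not np.allclose(a.spikes[uid], b.spikes.get(uid, np.empty(0)), rtol=rtol, atol=1e-9):
            return False
    if not np.isclose(a.behavior.sample_rate, b.behavior.sample_rate, rtol=rtol):
        return False
    for xa, xb in [
        (a.behavior.running_speed, b.behavior.running_speed),
        (a.behavior.corridor_position, b.behavior.corridor_position),
        (a.events.reward_times, b.events.reward_times),
        (a.events.lick_times, b.events.lick_times),
        (a.events.photo_onsets, b.events.photo_onsets),
        (a.trials.start_time, b.trials.start_time),
    ]:
        if xa.shape != xb.shape or not np.allclose(xa, xb, rtol=rtol, atol=1e-9):
            return False
    if sorted(a.events.cue_times) != sorted(b.events.cue_times):
        return False
    for k in a.events.cue_times:
        if not np.allclose(a.events.cue_times[k], b.events.cue_times[k], rtol=rtol, atol=1e-9):
            return False
    if a.events.photo_modes != b.events.photo_modes or a.trials.photo_mode != b.trials.photo_mode:
        return False
    ra, rb = a.trials.reward_time, b.trials.reward_time
    if ra.shape != rb.shape or not np.allclose(np.isnan(ra), np.isnan(rb)):
        return False
    if not np.allclose(ra[~np.isnan(ra)], rb[~np.isnan(rb)], rtol=rtol, atol=1e-9):
        return False
    return True
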