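"""Device-synchronization utilities and the on-disk session store.

Pulse schedules model the continuous TTL trains (e.g. 30 Hz camera
triggers) the rig emits; pulse logs are the timestamps an external device
actually recorded, checked for dropped frames and used to align behavioral
events post hoc. Sessions are stored as HDF5 (groups /config, /trials,
/events, /wheel) with a mirrored flat CSV trial table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd

from .task_engine import SessionRecord, TaskConfig, TrialRecord
from .wheel import WheelTrace

__all__ = [
    "FORMAT_VERSION",
    "PulseSchedule",
    "PulseLog",
    "generate_schedule",
    "read_pulse_log",
    "detect_dropped",
    "align_events",
    "write_session",
    "read_session",
    "trials_dataframe",
    "write_trial_csv",
]

FORMAT_VERSION = "1.0"

_DROP_THRESHOLD = 1.5  # gaps beyond 1.5x the nominal interval imply drops


@dataclass(frozen=True)
class PulseSchedule:
    """Ideal pulse train: strictly increasing timestamps at a fixed rate."""

    rate: float
    timestamps: np.ndarray


@dataclass(frozen=True)
class PulseLog:
    """Timestamps received from an external device, non-decreasing."""

    timestamps: np.ndarray
    nominal_rate: float

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps, dtype=float)
        if np.any(np.diff(ts) < 0):
            raise ValueError("pulse log timestamps must be non-decreasing")
        object.__setattr__(self, "timestamps", ts)


def generate_schedule(rate: float, duration: float) -> PulseSchedule:
    """Pulse timestamps 0, 1/rate, ... strictly below ``duration``."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    if duration < 0:
        raise ValueError("duration must be >= 0")
    n = int(np.ceil(duration * rate - 1e-9))
    return PulseSchedule(rate=rate, timestamps=np.arange(n) / rate)


def read_pulse_log(path, nominal_rate: float) -> PulseLog:
    """Read a single-column text/CSV file of pulse times in seconds."""
    ts = np.loadtxt(path, ndmin=1, delimiter=None if str(path).endswith(".txt") else ",")
    return PulseLog(timestamps=np.atleast_1d(ts.ravel()), nominal_rate=nominal_rate)


def detect_dropped(log: PulseLog) -> list[tuple[int, int]]:
    """Gaps implying missing frames: list of (gap index, n missing).

    A gap g between pulses i and i+1 larger than 1.5/nominal_rate implies
    round(g * nominal_rate) - 1 missing frames at index i.
    """
    ts = log.timestamps
    if len(ts) < 2:
        return []
    gaps = np.diff(ts)
    out: list[tuple[int, int]] = []
    thresh = _DROP_THRESHOLD / log.nominal_rate
    for i in np.flatnonzero(gaps > thresh):
        missing = int(round(gaps[i] * log.nominal_rate)) - 1
        if missing > 0:
            out.append((int(i), missing))
    return out


def align_events(
    event_times: Sequence[float], log: PulseLog
) -> tuple[np.ndarray, np.ndarray]:
    """Map event times to nearest-pulse frame indices.

    Returns (indices, in_span) where ties between two pulses resolve to the
    earlier index and ``in_span`` flags events within the log's time span.
    """
    ts = log.timestamps
    if len(ts) == 0:
        raise ValueError("pulse log is empty")
    events = np.asarray(event_times, dtype=float)
    right = np.searchsorted(ts, events, side="left")
    right = np.clip(right, 0, len(ts) - 1)
    left = np.clip(right - 1, 0, len(ts) - 1)
    d_left = np.abs(events - ts[left])
    d_right = np.abs(ts[right] - events)
    idx = np.where(d_left <= d_right, left, right)  # tie -> earlier index
    in_span = (events >= ts[0]) & (events <= ts[-1])
    return idx.astype(int), in_span


# ---------------------------------------------------------------------------
# Session store


_TRIAL_COLUMNS = [
    ("index", int, -1),
    ("strength", float, np.nan),
    ("dominant_octave", "S8", b""),
    ("signed_strength", float, np.nan),
    ("is_go", int, -1),  # -1 = n/a
    ("correct_side", "S8", b""),
    ("quiescence_duration", float, np.nan),
    ("t_start", float, np.nan),
    ("stim_onset", float, np.nan),
    ("response_time", float, np.nan),
    ("rt", float, np.nan),
    ("outcome", "S20", b""),
    ("turn_direction", "S8", b""),
    ("prestim_turning", float, np.nan),
    ("reward_delivered", float, np.nan),
    ("n_stim_repeats", int, 0),
    ("t_end", float, np.nan),
]


def trials_dataframe(record: SessionRecord) -> pd.DataFrame:
    """Flat per-trial table of a session."""
    rows = []
    for t in record.trials:
        rows.append(
            {
                "index": t.index,
                "strength": t.strength,
                "dominant_octave": t.dominant_octave,
                "signed_strength": t.signed_strength,
                "is_go": t.is_go,
                "correct_side": t.correct_side,
                "quiescence_duration": t.quiescence_duration,
                "t_start": t.t_start,
                "stim_onset": t.stim_onset,
                "response_time": t.response_time,
                "rt": t.rt,
                "outcome": t.outcome,
                "turn_direction": t.turn_direction,
                "prestim_turning": t.prestim_turning,
                "reward_delivered": t.reward_delivered,
                "n_stim_repeats": t.n_stim_repeats,
                "t_end": t.t_end,
            }
        )
    return pd.DataFrame(rows)


def write_trial_csv(record: SessionRecord, path) -> None:
    trials_dataframe(record).to_csv(path, index=False)


def write_session(record: SessionRecord, path, csv_mirror: bool = True) -> None:
    """Write a session to HDF5 (and a sibling .csv trial table)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        f.attrs["task"] = record.task
        f.attrs["stage"] = record.stage
        f.attrs["t_start"] = record.t_start
        f.attrs["t_end"] = record.t_end
        f.attrs["termination_reason"] = record.termination_reason
        f.attrs["total_reward"] = record.total_reward
        f.attrs["seed"] = -1 if record.seed is None else record.seed

        g = f.create_group("config")
        g.attrs["json"] = json.dumps(record.config.to_dict())

        gt = f.create_group("trials")
        n = len(record.trials)
        for name, dtype, default in _TRIAL_COLUMNS:
            vals = []
            for t in record.trials:
                v = getattr(t, name)
                if v is None:
                    v = default
                elif name == "is_go":
                    v = int(v)
                elif dtype in ("S8", "S20"):
                    v = str(v).encode()
                vals.append(v)
            gt.create_dataset(name, data=np.asarray(vals, dtype=dtype) if n else np.empty(0, dtype=dtype))

        # events flattened across trials: (trial_index, tick, code)
        trial_idx, ticks, names = [], [], []
        for t in record.trials:
            for tick, name in t.events:
                trial_idx.append(t.index)
                ticks.append(tick)
                names.append(name.encode())
        ge = f.create_group("events")
        ge.create_dataset("trial", data=np.asarray(trial_idx, dtype=np.int64))
        ge.create_dataset("tick", data=np.asarray(ticks, dtype=np.int64))
        ge.create_dataset("name", data=np.asarray(names, dtype="S24"))

        gw = f.create_group("wheel")
        gw.create_dataset("angle", data=record.wheel.angle)
        gw.attrs["t0"] = record.wheel.t0
        gw.attrs["dt"] = record.wheel.dt

    if csv_mirror:
        write_trial_csv(record, path.with_suffix(".csv"))


def read_session(path) -> SessionRecord:
    """Read a session written by :func:`write_session` (lossless round trip)."""
    with h5py.File(path, "r") as f:
        version = f.attrs.get("format_version")
        if version != FORMAT_VERSION:
            raise ValueError(
                f"unsupported session file version {version!r} "
                f"(expected {FORMAT_VERSION!r})"
            )
        config = TaskConfig.from_dict(json.loads(f["config"].attrs["json"]))
        gt = f["trials"]
        n = len(gt["index"])
        cols = {name: gt[name][()] for name, _, _ in _TRIAL_COLUMNS}

        ge = f["events"]
        ev_trial = ge["trial"][()]
        ev_tick = ge["tick"][()]
        ev_name = ge["name"][()]
        events_by_trial: dict[int, list] = {}
        for ti, tk, nm in zip(ev_trial, ev_tick, ev_name):
            events_by_trial.setdefault(int(ti), []).append((int(tk), nm.decode()))

        trials = []
        for i in range(n):
            def _s(name):
                v = cols[name][i].decode()
                return v or None

            def _f(name):
                v = float(cols[name][i])
                return None if np.isnan(v) else v

            ig = int(cols["is_go"][i])
            trials.append(
                TrialRecord(
                    index=int(cols["index"][i]),
                    strength=float(cols["strength"][i]),
                    dominant_octave=cols["dominant_octave"][i].decode(),
                    signed_strength=float(cols["signed_strength"][i]),
                    is_go=None if ig < 0 else bool(ig),
                    correct_side=_s("correct_side"),
                    quiescence_duration=float(cols["quiescence_duration"][i]),
                    t_start=float(cols["t_start"][i]),
                    stim_onset=float(cols["stim_onset"][i]),
                    response_time=_f("response_time"),
                    rt=_f("rt"),
                    outcome=_s("outcome"),
                    turn_direction=cols["turn_direction"][i].decode(),
                    prestim_turning=float(cols["prestim_turning"][i]),
                    reward_delivered=float(cols["reward_delivered"][i]),
                    n_stim_repeats=int(cols["n_stim_repeats"][i]),
                    t_end=float(cols["t_end"][i]),
                    events=events_by_trial.get(int(cols["index"][i]), []),
                )
            )
        seed = int(f.attrs["seed"])
        record = SessionRecord(
            task=str(f.attrs["task"]),
            stage=int(f.attrs["stage"]),
            config=config,
            trials=trials,
            t_start=float(f.attrs["t_start"]),
            t_end=float(f.attrs["t_end"]),
            termination_reason=str(f.attrs["termination_reason"]),
            total_reward=float(f.attrs["total_reward"]),
            wheel=WheelTrace(
                f["wheel"]["angle"][()],
                t0=float(f["wheel"].attrs["t0"]),
                dt=float(f["wheel"].attrs["dt"]),
            ),
            seed=None if seed < 0 else seed,
        )
    return record
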