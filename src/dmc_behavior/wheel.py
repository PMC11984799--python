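"""Quadrature decoding and wheel-trace signal processing.

The steering wheel position comes from a two-channel (A/B) rotary encoder
with 1,024 pulses per revolution. Decoding uses x1 counting: one full
quadrature pulse period (four edge transitions) advances the angle by
360/PPR degrees, signed by the A/B phase order. Traces live on a uniform
100 Hz grid with cumulative (unwrapped) angle in degrees; positive is a
rightward turn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EncoderStream",
    "WheelTrace",
    "decode_quadrature",
    "encode_angle_profile",
    "angular_velocity",
    "detect_quiescence",
    "detect_goal_crossing",
    "accumulated_turning",
    "write_encoder_csv",
    "read_encoder_csv",
    "SAMPLE_RATE",
    "DT",
]

SAMPLE_RATE = 100.0  # Hz
DT = 1.0 / SAMPLE_RATE

# Gray-code sequence of (A, B) states for forward rotation.
_FORWARD_CYCLE = [(0, 0), (1, 0), (1, 1), (0, 1)]
_STATE_INDEX = {s: i for i, s in enumerate(_FORWARD_CYCLE)}


@dataclass
class EncoderStream:
    """Edge events (timestamp s, channel 'A'|'B', level 0|1) from an encoder."""

    edges: list[tuple[float, str, int]]
    pulses_per_revolution: int = 1024

    def __post_init__(self) -> None:
        times = [e[0] for e in self.edges]
        if any(t1 < t0 for t0, t1 in zip(times, times[1:])):
            raise ValueError("encoder edge timestamps must be non-decreasing")


@dataclass
class WheelTrace:
    """Cumulative wheel angle (degrees) on a uniform 100 Hz grid."""

    angle: np.ndarray
    t0: float = 0.0
    dt: float = DT

    def __post_init__(self) -> None:
        self.angle = np.asarray(self.angle, dtype=np.float64)

    @property
    def timestamps(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.angle)) * self.dt

    @property
    def t_end(self) -> float:
        return self.t0 + (len(self.angle) - 1) * self.dt

    def index_at(self, t: float) -> int:
        """Grid index of time ``t`` (nearest sample, clipped to the trace)."""
        i = int(round((t - self.t0) / self.dt))
        return min(max(i, 0), len(self.angle) - 1)

    def angle_at(self, t: float) -> float:
        return float(self.angle[self.index_at(t)])

    def __len__(self) -> int:
        return len(self.angle)


def decode_quadrature(stream: EncoderStream, duration: float | None = None) -> WheelTrace:
    """Decode A/B edges into a signed cumulative angle trace at 100 Hz.

    Position between edges is a step function, so resampling onto the grid
    uses last-observation-carried-forward.
    """
    ppr = stream.pulses_per_revolution
    quantum = 360.0 / ppr  # x1 counting: one count per full pulse period
    a, b = 0, 0
    qc = 0  # quarter-period (edge transition) counter, internal only
    step_times: list[float] = [0.0]
    step_angles: list[float] = [0.0]
    for t, channel, level in stream.edges:
        prev = _STATE_INDEX[(a, b)]
        if channel == "A":
            a = int(level)
        elif channel == "B":
            b = int(level)
        else:
            raise ValueError(f"unknown channel {channel!r}")
        cur = _STATE_INDEX[(a, b)]
        delta = (cur - prev) % 4
        if delta == 1:
            qc += 1
        elif delta == 3:
            qc -= 1
        elif delta == 2:
            raise ValueError(f"illegal quadrature transition (missed edge) at t={t}")
        count = int(qc / 4)  # truncate toward zero: full periods only
        step_times.append(t)
        step_angles.append(count * quantum)

    t_last = step_times[-1] if duration is None else duration
    n = int(np.ceil(t_last / DT)) + 1
    grid = np.arange(n) * DT
    idx = np.searchsorted(step_times, grid, side="right") - 1
    angle = np.asarray(step_angles)[idx]
    return WheelTrace(angle=angle, t0=0.0)


def encode_angle_profile(
    times: np.ndarray, angles: np.ndarray, pulses_per_revolution: int = 1024
) -> EncoderStream:
    """Synthesize a quadrature edge stream from an angle-vs-time profile.

    Inverse of :func:`decode_quadrature` up to one quantum (360/PPR/4 deg);
    intended for tests and simulation.
    """
    times = np.asarray(times, dtype=float)
    angles = np.asarray(angles, dtype=float)
    quantum = 360.0 / pulses_per_revolution  # one full pulse period
    edges: list[tuple[float, str, int]] = []
    state = 0  # index into _FORWARD_CYCLE, starts at (0, 0)
    count = 0
    t_prev = times[0] if len(times) else 0.0
    for i in range(1, len(times)):
        a0, a1 = angles[i - 1], angles[i]
        t0, t1 = times[i - 1], times[i]
        while True:
            if a1 > count * quantum + quantum / 2:
                target = count + 1
            elif a1 < count * quantum - quantum / 2:
                target = count - 1
            else:
                break
            # linear time interpolation of the crossing
            frac = 0.5 if a1 == a0 else (target * quantum - a0) / (a1 - a0)
            frac = min(max(frac, 0.0), 1.0)
            t_cross = max(t0 + frac * (t1 - t0), t_prev)
            step = 1 if target > count else -1
            # one full pulse period = four edge transitions
            for k in range(4):
                new_state = (state + step) % 4
                pa, pb = _FORWARD_CYCLE[state]
                na, nb = _FORWARD_CYCLE[new_state]
                t_edge = max(t_cross + k * 1e-6, t_prev)
                if na != pa:
                    edges.append((t_edge, "A", na))
                if nb != pb:
                    edges.append((t_edge, "B", nb))
                state = new_state
                t_prev = t_edge
            count = target
    return EncoderStream(edges=edges, pulses_per_revolution=pulses_per_revolution)


def write_encoder_csv(stream: EncoderStream, path) -> None:
    """Store an edge stream as CSV with columns timestamp, channel, level."""
    with open(path, "w") as fh:
        fh.write("timestamp,channel,level\n")
        for t, channel, level in stream.edges:
            fh.write(f"{float(t)!r},{channel},{int(level)}\n")


def read_encoder_csv(path, pulses_per_revolution: int = 1024) -> EncoderStream:
    edges: list[tuple[float, str, int]] = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            t, channel, level = line.strip().split(",")
            edges.append((float(t), channel, int(level)))
    return EncoderStream(edges=edges, pulses_per_revolution=pulses_per_revolution)


def angular_velocity(trace: WheelTrace) -> np.ndarray:
    """Velocity in deg/s on the trace's grid (central differences)."""
    if len(trace) < 2:
        raise ValueError("need at least 2 samples for velocity")
    return np.gradient(trace.angle, trace.dt)


def detect_quiescence(
    trace: WheelTrace,
    start_time: float,
    required_duration: float,
    jitter_tolerance: float = 2.0,
) -> float | None:
    """Earliest time the wheel has been still for ``required_duration``.

    The wheel counts as still while its angle stays within
    ``jitter_tolerance`` degrees of the window-anchor angle; an excursion
    beyond tolerance restarts the window at that sample. Returns ``None``
    ("pending") if the trace ends before the requirement is met.
    """
    i_start = trace.index_at(start_time)
    window = int(round(required_duration / trace.dt))
    anchor = i_start
    for i in range(i_start, len(trace)):
        if abs(trace.angle[i] - trace.angle[anchor]) > jitter_tolerance:
            anchor = i
        elif i - anchor >= window:
            return trace.t0 + i * trace.dt
    return None


def detect_goal_crossing(
    trace: WheelTrace,
    origin_time: float,
    goal: float,
    deadline: float,
) -> tuple[float, str] | None:
    """First time in [origin_time, deadline] the displacement reaches ``goal``.

    Returns (crossing_time, 'right'|'left') or None. Displacement is measured
    from the angle at ``origin_time``.
    """
    if goal <= 0:
        raise ValueError("goal must be positive")
    i0 = trace.index_at(origin_time)
    i1 = min(trace.index_at(deadline), len(trace) - 1)
    ref = trace.angle[i0]
    disp = trace.angle[i0 : i1 + 1] - ref
    hits = np.flatnonzero(np.abs(disp) >= goal)
    if hits.size == 0:
        return None
    i = i0 + int(hits[0])
    direction = "right" if trace.angle[i] - ref > 0 else "left"
    return trace.t0 + i * trace.dt, direction


def accumulated_turning(trace: WheelTrace, t0: float, t1: float) -> float:
    """Total wheel path length (deg, both directions) over [t0, t1]."""
    if t1 < t0:
        raise ValueError("t1 must be >= t0")
    i0, i1 = trace.index_at(t0), trace.index_at(t1)
    return float(np.sum(np.abs(np.diff(trace.angle[i0 : i1 + 1]))))
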