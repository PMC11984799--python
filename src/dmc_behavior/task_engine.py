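"""Event-driven trial and session state machines.

Four task variants run on a simulated clock: pretraining (passive stimulus +
reward), detection (turn either way to report a stimulus), Go/NoGo (turn vs
withhold), and 2AFC (turn toward the side mapped to the dominant octave).

The clock is virtual and discretized to the 100 Hz wheel grid: all times are
integer *ticks* of 10 ms, so configured interval durations (ITI, timeout,
noise) are exact in the event logs. A trial runs: draw quiescence duration
uniform [1.0, 1.5] s -> await wheel stillness (2 deg jitter tolerance) ->
stimulus onset, repeating the cloud until a turning-goal crossing or the end
of the response window -> classify -> reward or timeout (plus white noise
where due) -> ITI.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .stimuli import ToneCloudSpec
from .wheel import (
    DT,
    WheelTrace,
    accumulated_turning,
    detect_goal_crossing,
    detect_quiescence,
)
from .agents import Agent, Decision

__all__ = [
    "TaskConfig",
    "StimulusAssignment",
    "TrialRecord",
    "SessionRecord",
    "TrialScheduler",
    "classify_outcome",
    "check_disengagement",
    "run_trial",
    "run_session",
    "TICKS_PER_SECOND",
]

TICKS_PER_SECOND = 100  # engine clock = wheel grid

TASKS = ("pretraining", "detection", "gonogo", "2afc")

# stage -> stimulus strengths available in 2AFC training
STAGE_STRENGTHS_2AFC = {
    0: (100.0,),
    1: (100.0,),
    2: (100.0, 85.0),
    3: (100.0, 85.0, 70.0),
    4: (100.0, 85.0, 70.0, 60.0),
}


def _ticks(seconds: float) -> int:
    return int(round(seconds * TICKS_PER_SECOND))


def _sec(tick: int) -> float:
    return tick / TICKS_PER_SECOND


@dataclass
class TaskConfig:
    """Complete parameterization of one session."""

    task: str
    stage: int = 0
    turning_goal: float = 30.0         # deg
    reward_size: float = 5.0           # ul
    strengths: tuple = (100.0,)        # percent
    stimulus_duration: float = 0.51    # s
    response_window: float = 1.02      # s from stimulus onset
    iti: float = 0.5                   # s
    timeout: float = 1.5               # s
    noise_punish_duration: float = 0.5  # s
    quiescence_range: tuple = (1.0, 1.5)  # s, drawn uniformly per trial
    jitter_tolerance: float = 2.0      # deg
    session_min: float = 45 * 60.0     # s, earliest disengagement
    session_cap: float = 60 * 60.0     # s, hard limit
    go_octave: str = "high"            # gonogo: octave of the Go stimulus
    high_side: str = "right"           # 2afc: side rewarded for the high octave
    reward_multipliers: dict = field(
        default_factory=lambda: {"left": 1.0, "right": 1.0}
    )
    pretraining_session_index: int = 1

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.response_window < self.stimulus_duration:
            raise ValueError("response_window must cover the stimulus duration")
        if self.session_cap <= self.session_min and self.task != "pretraining":
            raise ValueError("session_cap must exceed session_min")

    @classmethod
    def for_task(cls, task: str, stage: int = 0, **overrides) -> "TaskConfig":
        """Stage-appropriate defaults for each task."""
        kw: dict = {"task": task, "stage": stage}
        if task == "pretraining":
            idx = overrides.get("pretraining_session_index", 1)
            kw.update(
                stimulus_duration=2.04,
                response_window=2.04,
                reward_size=5.0,
                session_min=0.0,
                session_cap={1: 15, 2: 30, 3: 45}.get(idx, 45) * 60.0,
            )
        elif task == "detection":
            kw.update(
                turning_goal=15.0 if stage == 0 else 30.0,
                reward_size=5.0,
                session_cap=60 * 60.0,
            )
        elif task == "gonogo":
            kw.update(
                turning_goal=15.0 if stage == 0 else 30.0,
                reward_size=5.0,
                session_cap=60 * 60.0,
            )
        elif task == "2afc":
            kw.update(
                turning_goal=15.0 if stage == 0 else 30.0,
                strengths=STAGE_STRENGTHS_2AFC[min(stage, 4)],
                reward_size=3.0,
                response_window=15.0,
                session_cap=90 * 60.0,
            )
        kw.update(overrides)
        return cls(**kw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["strengths"] = list(self.strengths)
        d["quiescence_range"] = list(self.quiescence_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        d = dict(d)
        d["strengths"] = tuple(d["strengths"])
        d["quiescence_range"] = tuple(d["quiescence_range"])
        return cls(**d)


@dataclass(frozen=True)
class StimulusAssignment:
    """One trial's stimulus: strength, dominant octave, and task semantics."""

    strength: float
    dominant_octave: str
    is_go: Optional[bool] = None        # gonogo only
    correct_side: Optional[str] = None  # 2afc only

    @property
    def signed_strength(self) -> float:
        """Signed evidence: + = right-rewarded (2afc) or respond (Go/target)."""
        if self.correct_side is not None:
            return self.strength if self.correct_side == "right" else -self.strength
        if self.is_go is not None:
            return self.strength if self.is_go else -self.strength
        return self.strength

    def cloud_spec(self, seed: Optional[int] = None, duration: float = 0.51) -> ToneCloudSpec:
        return ToneCloudSpec(
            strength=self.strength,
            dominant_octave=self.dominant_octave,
            duration=duration,
            seed=seed,
        )


@dataclass
class TrialRecord:
    """Full log of one trial; times are seconds on the session clock."""

    index: int
    strength: float
    dominant_octave: str
    signed_strength: float
    is_go: Optional[bool]
    correct_side: Optional[str]
    quiescence_duration: float
    t_start: float
    stim_onset: float
    response_time: Optional[float]  # absolute crossing time, None if no crossing
    rt: Optional[float]             # response_time - stim_onset
    outcome: Optional[str]
    turn_direction: str             # 'left' | 'right' | 'none'
    prestim_turning: float          # accumulated deg before stimulus onset
    reward_delivered: float         # ul
    n_stim_repeats: int
    t_end: float
    events: list = field(default_factory=list)  # (tick:int, name:str)


@dataclass
class SessionRecord:
    """One session: config snapshot, trials, events, wheel trace."""

    task: str
    stage: int
    config: TaskConfig
    trials: list
    t_start: float
    t_end: float
    termination_reason: str  # 'disengaged' | 'time_cap'
    total_reward: float      # ul
    wheel: WheelTrace
    seed: Optional[int] = None

    @property
    def duration_min(self) -> float:
        return (self.t_end - self.t_start) / 60.0

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def classify_outcome(
    task: str,
    assignment: StimulusAssignment,
    crossing: Optional[tuple],
) -> str:
    """Map a (possibly absent) goal crossing to the task's outcome label."""
    if task == "detection":
        return "correct" if crossing is not None else "incorrect"
    if task == "gonogo":
        if assignment.is_go:
            return "hit" if crossing is not None else "miss"
        return "false_alarm" if crossing is not None else "correct_rejection"
    if task == "2afc":
        if crossing is None:
            return "omission"
        return "correct" if crossing[1] == assignment.correct_side else "incorrect"
    raise ValueError(f"unknown task {task!r}")


class TrialScheduler:
    """Chooses each trial's stimulus, honoring ordering/debiasing rules.

    Go/NoGo: uniform pseudorandom with at most 3 identical consecutive trial
    types. 2AFC stage 0: alternating high/low blocks, switching after three
    consecutive correct trials. 2AFC stages 1-3: pseudorandom side and
    strength with repeat-after-error debiasing (an incorrect trial repeats
    the same stimulus). Stage 4: fully pseudorandom.
    """

    def __init__(self, config: TaskConfig, rng: np.random.Generator):
        self.config = config
        self.rng = rng
        self._recent_go: list[bool] = []
        self._block_side: Optional[str] = None
        self._block_correct = 0
        self._last: Optional[StimulusAssignment] = None
        self._last_outcome: Optional[str] = None

    def _octave_for_side(self, side: str) -> str:
        high_side = self.config.high_side
        return "high" if side == high_side else "low"

    def next(self) -> StimulusAssignment:
        cfg = self.config
        if cfg.task in ("pretraining", "detection"):
            return StimulusAssignment(strength=100.0, dominant_octave="middle")
        if cfg.task == "gonogo":
            if len(self._recent_go) >= 3 and len(set(self._recent_go[-3:])) == 1:
                is_go = not self._recent_go[-1]  # forced switch after 3 repeats
            else:
                is_go = bool(self.rng.random() < 0.5)
            octave = cfg.go_octave if is_go else ("low" if cfg.go_octave == "high" else "high")
            return StimulusAssignment(strength=100.0, dominant_octave=octave, is_go=is_go)
        # 2afc
        if cfg.stage == 0:
            if self._block_side is None:
                self._block_side = "right" if self.rng.random() < 0.5 else "left"
            side = self._block_side
            strength = 100.0
        elif cfg.stage in (1, 2, 3) and self._last_outcome == "incorrect":
            return self._last  # repeat-after-error debiasing
        else:
            side = "right" if self.rng.random() < 0.5 else "left"
            strength = float(self.rng.choice(cfg.strengths))
        return StimulusAssignment(
            strength=strength,
            dominant_octave=self._octave_for_side(side),
            correct_side=side,
        )

    def record(self, assignment: StimulusAssignment, outcome: str) -> None:
        self._last = assignment
        self._last_outcome = outcome
        if self.config.task == "gonogo":
            self._recent_go.append(bool(assignment.is_go))
        elif self.config.task == "2afc" and self.config.stage == 0:
            if outcome == "correct":
                self._block_correct += 1
                if self._block_correct >= 3:
                    self._block_side = "left" if self._block_side == "right" else "right"
                    self._block_correct = 0
            else:
                self._block_correct = 0


def check_disengagement(
    task: str,
    trials: list,
    now: float,
    session_min: float,
    response_window: float = 15.0,
    window: int = 20,
) -> bool:
    """Online rule that ends a session when the subject stops working.

    Detection/Go-NoGo: fewer than 4 goal crossings in the last 20 trials.
    2AFC: rolling median RT over the last 20 trials (omissions count as
    infinite) exceeds 4x the session median RT over responded trials
    (fallback: the response window if nothing was ever answered). Always
    false before ``session_min`` or with fewer than 20 trials.
    """
    if now < session_min or len(trials) < window:
        return False
    recent = trials[-window:]
    if task in ("detection", "gonogo"):
        n_crossings = sum(1 for t in recent if t.rt is not None)
        return n_crossings < 4
    if task == "2afc":
        rolling = np.median([t.rt if t.rt is not None else np.inf for t in recent])
        responded = [t.rt for t in trials if t.rt is not None]
        baseline = np.median(responded) if responded else response_window
        return bool(rolling > 4.0 * baseline)
    return False


@dataclass
class _EngineState:
    now_tick: int = 0
    last_angle: float = 0.0
    segments: list = field(default_factory=list)
    trials: list = field(default_factory=list)
    total_reward: float = 0.0


def _punishment(task: str, outcome: str) -> tuple[bool, bool]:
    """(timeout?, white_noise?) for an outcome."""
    if task == "detection":
        return outcome == "incorrect", False
    if task == "gonogo":
        if outcome == "false_alarm":
            return True, True
        return outcome == "miss", False
    if task == "2afc":
        if outcome == "incorrect":
            return True, True
        return outcome == "omission", False
    return False, False


def run_trial(
    config: TaskConfig,
    agent: Agent,
    state: _EngineState,
    scheduler: TrialScheduler,
    rng: np.random.Generator,
) -> Optional[TrialRecord]:
    """Run one trial FSM; returns None if the session cap truncates it."""
    cfg = config
    t0_tick = state.now_tick
    cap_tick = _ticks(cfg.session_cap)

    q = rng.uniform(*cfg.quiescence_range)
    q_ticks = _ticks(q)
    assignment = scheduler.next()

    # --- pre-stimulus epoch: wait for wheel quiescence
    pre = agent.prestim_trace(_sec(q_ticks), rng)
    pre_abs = state.last_angle + pre
    trace_pre = WheelTrace(pre_abs, t0=_sec(t0_tick))
    t_quiet = detect_quiescence(
        trace_pre, _sec(t0_tick), _sec(q_ticks), cfg.jitter_tolerance
    )
    while t_quiet is None:  # agent contract: eventually still; extend if needed
        pre_abs = np.concatenate([pre_abs, np.full(q_ticks + 20, pre_abs[-1])])
        trace_pre = WheelTrace(pre_abs, t0=_sec(t0_tick))
        t_quiet = detect_quiescence(
            trace_pre, _sec(t0_tick), _sec(q_ticks), cfg.jitter_tolerance
        )
    onset_tick = int(round(t_quiet * TICKS_PER_SECOND))
    n_pre = onset_tick - t0_tick
    prestim_turning = accumulated_turning(trace_pre, _sec(t0_tick), _sec(onset_tick))

    # --- decision and response epoch
    decision = agent.decide(
        cfg.task,
        assignment.signed_strength,
        prestim_turning,
        _sec(t0_tick),
        rng,
    )
    post = agent.response_trace(decision, cfg.turning_goal, cfg.response_window, rng)
    onset_angle = pre_abs[n_pre] if n_pre < len(pre_abs) else pre_abs[-1]
    full = np.concatenate([pre_abs[:n_pre], onset_angle + post])
    trace = WheelTrace(full, t0=_sec(t0_tick))

    window_ticks = _ticks(cfg.response_window)
    crossing = detect_goal_crossing(
        trace, _sec(onset_tick), cfg.turning_goal, _sec(onset_tick + window_ticks)
    )
    outcome = classify_outcome(cfg.task, assignment, crossing)
    scheduler.record(assignment, outcome)

    if crossing is not None:
        cross_tick = int(round(crossing[0] * TICKS_PER_SECOND))
        turn_direction = crossing[1]
        resp_end_tick = cross_tick
    else:
        cross_tick = None
        turn_direction = "none"
        resp_end_tick = onset_tick + window_ticks

    timeout_p, noise_p = _punishment(cfg.task, outcome)
    reward = 0.0
    rewarded = outcome in ("correct", "hit") and cfg.task != "pretraining"
    if rewarded:
        reward = cfg.reward_size * cfg.reward_multipliers.get(turn_direction, 1.0)

    timeout_ticks = _ticks(cfg.timeout) if timeout_p else 0
    iti_ticks = _ticks(cfg.iti)
    end_tick = resp_end_tick + timeout_ticks + iti_ticks
    if end_tick > cap_tick:
        return None  # session timer fires mid-trial; trial is discarded

    # --- event log (ticks are exact; seconds = tick / 100)
    n_repeats = int(np.ceil((resp_end_tick - onset_tick) / _ticks(cfg.stimulus_duration)))
    n_repeats = max(n_repeats, 1)
    events: list[tuple[int, str]] = [(t0_tick, "trial_start"), (onset_tick, "stimulus_on")]
    for k in range(1, n_repeats):
        events.append((onset_tick + k * _ticks(cfg.stimulus_duration), "stimulus_repeat"))
    if cross_tick is not None:
        events.append((cross_tick, "response"))
    events.append((resp_end_tick, "stimulus_off"))
    if rewarded:
        events.append((resp_end_tick, "reward"))
    if timeout_p:
        events.append((resp_end_tick, "timeout_start"))
        if noise_p:
            events.append((resp_end_tick, "noise_on"))
            events.append((resp_end_tick + _ticks(cfg.noise_punish_duration), "noise_off"))
        events.append((resp_end_tick + timeout_ticks, "timeout_end"))
    events.append((resp_end_tick + timeout_ticks, "iti_start"))
    events.append((end_tick, "trial_end"))
    events.sort(key=lambda e: e[0])

    # --- fix the wheel segment to exactly cover [t0, end)
    n_needed = end_tick - t0_tick
    if len(full) < n_needed:
        full = np.concatenate([full, np.full(n_needed - len(full), full[-1])])
    else:
        full = full[:n_needed]

    record = TrialRecord(
        index=len(state.trials),
        strength=assignment.strength,
        dominant_octave=assignment.dominant_octave,
        signed_strength=assignment.signed_strength,
        is_go=assignment.is_go,
        correct_side=assignment.correct_side,
        quiescence_duration=_sec(q_ticks),
        t_start=_sec(t0_tick),
        stim_onset=_sec(onset_tick),
        response_time=None if cross_tick is None else _sec(cross_tick),
        rt=None if cross_tick is None else _sec(cross_tick - onset_tick),
        outcome=outcome,
        turn_direction=turn_direction,
        prestim_turning=float(prestim_turning),
        reward_delivered=reward,
        n_stim_repeats=n_repeats,
        t_end=_sec(end_tick),
        events=events,
    )
    state.segments.append(full)
    state.last_angle = float(full[-1])
    state.now_tick = end_tick
    state.total_reward += reward
    state.trials.append(record)
    return record


def _run_pretraining(config: TaskConfig, rng: np.random.Generator) -> _EngineState:
    """Passive stimulus + reward loop; the wheel is immobilized."""
    state = _EngineState()
    cap_tick = _ticks(config.session_cap)
    stim_ticks = _ticks(config.stimulus_duration)
    iti_ticks = _ticks(config.iti)
    while state.now_tick + stim_ticks + iti_ticks <= cap_tick:
        t0 = state.now_tick
        end = t0 + stim_ticks + iti_ticks
        events = [
            (t0, "trial_start"),
            (t0, "stimulus_on"),
            (t0 + stim_ticks, "stimulus_off"),
            (t0 + stim_ticks, "reward"),
            (t0 + stim_ticks, "iti_start"),
            (end, "trial_end"),
        ]
        state.trials.append(
            TrialRecord(
                index=len(state.trials),
                strength=100.0,
                dominant_octave="middle",
                signed_strength=100.0,
                is_go=None,
                correct_side=None,
                quiescence_duration=0.0,
                t_start=_sec(t0),
                stim_onset=_sec(t0),
                response_time=None,
                rt=None,
                outcome=None,
                turn_direction="none",
                prestim_turning=0.0,
                reward_delivered=config.reward_size,
                n_stim_repeats=1,
                t_end=_sec(end),
                events=events,
            )
        )
        state.segments.append(np.zeros(end - t0))
        state.total_reward += config.reward_size
        state.now_tick = end
    return state


def run_session(
    config: TaskConfig,
    agent: Agent,
    rng: np.random.Generator,
    seed: Optional[int] = None,
) -> SessionRecord:
    """Loop trials until disengagement (after session_min) or the time cap."""
    if config.task == "pretraining":
        state = _run_pretraining(config, rng)
        reason = "time_cap"
    else:
        state = _EngineState()
        scheduler = TrialScheduler(config, rng)
        cap_tick = _ticks(config.session_cap)
        reason = "time_cap"
        while state.now_tick < cap_tick:
            record = run_trial(config, agent, state, scheduler, rng)
            if record is None:
                state.now_tick = cap_tick
                break
            if check_disengagement(
                config.task,
                state.trials,
                _sec(state.now_tick),
                config.session_min,
                config.response_window,
            ):
                reason = "disengaged"
                break

    if state.segments:
        angle = np.concatenate(state.segments + [np.array([state.last_angle])])
    else:
        angle = np.zeros(1)
    return SessionRecord(
        task=config.task,
        stage=config.stage,
        config=config,
        trials=state.trials,
        t_start=0.0,
        t_end=_sec(state.now_tick),
        termination_reason=reason,
        total_reward=state.total_reward,
        wheel=WheelTrace(angle, t0=0.0),
        seed=seed,
    )
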