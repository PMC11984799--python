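"""Automated multi-session training: stage advancement, intersession
reward-size adjustment and debiasing, and task-proficiency evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import yaml

from . import analysis
from .agents import Agent
from .task_engine import SessionRecord, TaskConfig, run_session

__all__ = [
    "REWARD_BOUNDS",
    "SessionSummary",
    "StageState",
    "summarize_session",
    "adjust_reward",
    "evaluate_stage_advance",
    "intersession_debias",
    "evaluate_proficiency",
    "run_training",
]

# task -> (min, max) reward size in ul
REWARD_BOUNDS = {
    "detection": (3.0, 5.0),
    "gonogo": (3.0, 5.0),
    "2afc": (1.5, 3.0),
    "pretraining": (5.0, 5.0),
}

FINAL_STAGE = {"detection": 1, "gonogo": 1, "2afc": 4}
N_PRETRAINING_SESSIONS = 3


@dataclass
class SessionSummary:
    """Per-session aggregates consumed by the training rules."""

    task: str
    stage: int
    n_trials: int
    n_correct: int
    consumed_ml: float
    duration_min: float
    termination_reason: str
    dprime: Optional[float] = None
    n_hit: Optional[int] = None
    accuracy_high: Optional[float] = None  # correct fraction, high-octave trials
    accuracy_low: Optional[float] = None
    accuracy_high_100: Optional[float] = None  # 100% clouds only
    accuracy_low_100: Optional[float] = None
    right_fraction: Optional[float] = None  # of responded trials


def _accuracy(trials) -> Optional[float]:
    if not trials:
        return None
    n_ok = sum(1 for t in trials if t.outcome in ("correct", "hit", "correct_rejection"))
    return n_ok / len(trials)


def summarize_session(record: SessionRecord) -> SessionSummary:
    trials = record.trials
    correct = [t for t in trials if t.outcome in ("correct", "hit", "correct_rejection")]
    summary = SessionSummary(
        task=record.task,
        stage=record.stage,
        n_trials=len(trials),
        n_correct=len(correct),
        consumed_ml=record.total_reward / 1000.0,
        duration_min=record.duration_min,
        termination_reason=record.termination_reason,
    )
    if record.task == "gonogo":
        counts = analysis.OutcomeCounts.from_trials(trials)
        summary.n_hit = counts.n_hit
        if counts.n_hit + counts.n_miss > 0 and counts.n_fa + counts.n_cr > 0:
            summary.dprime = analysis.dprime(counts)
    if record.task == "2afc":
        high = [t for t in trials if t.dominant_octave == "high"]
        low = [t for t in trials if t.dominant_octave == "low"]
        summary.accuracy_high = _accuracy(high)
        summary.accuracy_low = _accuracy(low)
        summary.accuracy_high_100 = _accuracy([t for t in high if t.strength == 100.0])
        summary.accuracy_low_100 = _accuracy([t for t in low if t.strength == 100.0])
        responded = [t for t in trials if t.turn_direction != "none"]
        if responded:
            summary.right_fraction = sum(
                1 for t in responded if t.turn_direction == "right"
            ) / len(responded)
    return summary


def adjust_reward(prev: float, consumed_ml: float, task: str) -> float:
    """Intersession reward-size rule: -0.1 ul if >1 ml consumed, +0.1 if <1 ml,
    clamped to the task's [min, max] bounds."""
    if prev < 0 or consumed_ml < 0:
        raise ValueError("reward size and consumption must be non-negative")
    lo, hi = REWARD_BOUNDS[task]
    if consumed_ml > 1.0:
        new = prev - 0.1
    elif consumed_ml < 1.0:
        new = prev + 0.1
    else:
        new = prev
    return float(min(max(new, lo), hi))


def evaluate_stage_advance(task: str, stage: int, summary: SessionSummary) -> bool:
    """Strict-inequality advancement thresholds per task and stage."""
    if task == "detection":
        if stage == 0:
            return summary.n_correct > 150
        if stage == 1:
            return False  # terminal stage
    elif task == "gonogo":
        if stage == 0:
            # hits, not hits+CRs: an immobile animal accumulates correct
            # rejections without ever responding and must not advance
            return (summary.n_hit or 0) > 150
        if stage == 1:
            return False
    elif task == "2afc":
        if stage == 0:
            return summary.n_correct > 300
        if stage == 1:
            return (
                summary.accuracy_high is not None
                and summary.accuracy_low is not None
                and summary.accuracy_high > 0.80
                and summary.accuracy_low > 0.80
            )
        if stage == 2:
            return (
                summary.accuracy_high is not None
                and summary.accuracy_low is not None
                and summary.accuracy_high > 0.75
                and summary.accuracy_low > 0.75
            )
        if stage == 3:
            return summary.n_correct > 350
        if stage == 4:
            return False
    raise ValueError(f"unknown task/stage {task!r}/{stage}")


def intersession_debias(summary: SessionSummary) -> dict:
    """Reward multipliers for the next session: a >85% turn-direction bias
    doubles the reward for the neglected direction."""
    mult = {"left": 1.0, "right": 1.0}
    rf = summary.right_fraction
    if rf is None:
        return mult
    if rf > 0.85:
        mult["left"] = 2.0
    elif (1.0 - rf) > 0.85:
        mult["right"] = 2.0
    return mult


def evaluate_proficiency(
    task: str,
    recent_summaries: list,
    recent_records: Optional[list] = None,
) -> bool:
    """Task-proficiency check over the last three stage-final sessions.

    Go/NoGo: d' > 1.8 on three consecutive sessions. 2AFC: >300 trials and
    >80% correct on 100% clouds for both sides in each of three consecutive
    stage-4 sessions, and the psychometric fit of their cumulative data has
    |bias| < 16, threshold (slope) < 19, and both lapses < 0.2.
    """
    if len(recent_summaries) < 3:
        return False
    last3 = recent_summaries[-3:]
    if task == "gonogo":
        return all(s.dprime is not None and s.dprime > 1.8 for s in last3)
    if task == "2afc":
        for s in last3:
            if s.n_trials <= 300:
                return False
            if s.accuracy_high_100 is None or s.accuracy_high_100 <= 0.80:
                return False
            if s.accuracy_low_100 is None or s.accuracy_low_100 <= 0.80:
                return False
        if recent_records is None or len(recent_records) < 3:
            return False
        trials = [t for r in recent_records[-3:] for t in r.trials]
        x, n, k = analysis.per_level_choices(trials)
        if len(x) < 2:
            return False
        fit = analysis.fit_psychometric(x, n, k)
        return (
            abs(fit.bias) < 16.0
            and fit.slope < 19.0
            and fit.lapse1 < 0.2
            and fit.lapse2 < 0.2
        )
    raise ValueError(f"proficiency is defined for gonogo and 2afc, not {task!r}")


@dataclass
class StageState:
    """Per-animal training state persisted between sessions."""

    task: str
    stage: int = 0
    reward_size: float = 5.0
    reward_multipliers: dict = field(
        default_factory=lambda: {"left": 1.0, "right": 1.0}
    )
    n_pretraining_done: int = 0
    sessions_completed: int = 0
    proficient: bool = False
    history: list = field(default_factory=list)  # SessionSummary dicts

    def __post_init__(self) -> None:
        lo, hi = REWARD_BOUNDS[self.task]
        if not (lo <= self.reward_size <= hi):
            raise ValueError(
                f"reward_size {self.reward_size} outside [{lo}, {hi}] for {self.task}"
            )

    @classmethod
    def initial(cls, task: str) -> "StageState":
        return cls(task=task, reward_size=REWARD_BOUNDS[task][1])

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StageState":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def run_training(
    task: str,
    agent: Agent,
    n_sessions: int,
    seed: int = 0,
    include_pretraining: bool = True,
    stop_when_proficient: bool = True,
    config_overrides: Optional[dict] = None,
):
    """Simulate up to ``n_sessions`` sessions of staged training.

    Returns (StageState, list[SessionSummary], list[SessionRecord]).
    Pretraining runs for the first three sessions, then the task starts at
    stage 0; stage advancement, reward adjustment and (2AFC, stages 0-3)
    intersession debiasing apply between sessions.
    """
    rng = np.random.default_rng(seed)
    state = StageState.initial(task)
    summaries: list[SessionSummary] = []
    records: list[SessionRecord] = []
    stage_final_summaries: list[SessionSummary] = []
    stage_final_records: list[SessionRecord] = []

    for i in range(n_sessions):
        if include_pretraining and state.n_pretraining_done < N_PRETRAINING_SESSIONS:
            cfg = TaskConfig.for_task(
                "pretraining",
                pretraining_session_index=state.n_pretraining_done + 1,
            )
            record = run_session(cfg, agent, rng, seed=seed)
            state.n_pretraining_done += 1
        else:
            overrides = dict(config_overrides or {})
            overrides.setdefault("reward_size", state.reward_size)
            overrides.setdefault("reward_multipliers", dict(state.reward_multipliers))
            cfg = TaskConfig.for_task(task, stage=state.stage, **overrides)
            record = run_session(cfg, agent, rng, seed=seed)
        summary = summarize_session(record)
        summaries.append(summary)
        records.append(record)
        state.sessions_completed += 1
        state.history.append(asdict(summary))

        if record.task == "pretraining":
            continue

        # intersession reward-size adjustment (stage >= 1 for detection/gonogo,
        # applied throughout for 2afc bounds symmetry)
        if not (record.task in ("detection", "gonogo") and record.stage == 0):
            state.reward_size = adjust_reward(
                state.reward_size, summary.consumed_ml, task
            )
        # intersession debiasing: 2afc stages 0-3 only
        if record.task == "2afc" and record.stage <= 3:
            state.reward_multipliers = intersession_debias(summary)
        else:
            state.reward_multipliers = {"left": 1.0, "right": 1.0}

        final = FINAL_STAGE[task]
        if state.stage == final:
            stage_final_summaries.append(summary)
            stage_final_records.append(record)
            if task in ("gonogo", "2afc"):
                state.proficient = evaluate_proficiency(
                    task, stage_final_summaries, stage_final_records
                )
            else:  # detection has no printed proficiency rule; final stage = done
                state.proficient = True
        elif evaluate_stage_advance(task, state.stage, summary):
            state.stage += 1

        if stop_when_proficient and state.proficient:
            break

    return state, summaries, records
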