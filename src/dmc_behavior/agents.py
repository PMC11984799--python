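"""Simulated mouse agents with parameterized psychometric ground truth.

An :class:`AgentPolicy` holds the true psychometric parameters (lapses,
bias, slope), a log-normal reaction-time distribution, response
probability, turn-amplitude distribution, impulsive pre-stimulus turning,
and quiescence compliance. Agents close the loop with the task engine by
emitting causal 100 Hz wheel-trace segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .wheel import DT

__all__ = [
    "AgentPolicy",
    "Decision",
    "Agent",
    "choose_response",
    "render_prestim_trace",
    "render_response_trace",
    "make_agent",
    "AGENT_PROFILES",
]


@dataclass(frozen=True)
class AgentPolicy:
    """Ground-truth behavioral parameters of a simulated mouse.

    ``true_lapse_left`` is the lower asymptote of P(right turn | x) (errors on
    strong-left stimuli); ``true_lapse_right`` is 1 minus the upper asymptote.
    """

    true_bias: float = 0.0        # stimulus-strength %
    true_slope: float = 10.0      # stimulus-strength %
    true_lapse_left: float = 0.0
    true_lapse_right: float = 0.0
    rt_median: float = 0.40       # s
    rt_sigma: float = 0.25        # log-normal shape
    response_probability: float = 1.0
    turn_amplitude_mean: float = 55.0  # deg
    turn_amplitude_sd: float = 8.0
    impulsivity: float = 0.0      # mean impulsive bursts per non-compliant trial
    quiescence_compliance: float = 1.0
    disengage_after_min: Optional[float] = None
    disengage_rt_factor: float = 5.0

    def __post_init__(self) -> None:
        for name in ("true_lapse_left", "true_lapse_right"):
            v = getattr(self, name)
            if not (0.0 <= v <= 0.5):
                raise ValueError(f"{name} must be in [0, 0.5]")
        if not (0.0 <= self.response_probability <= 1.0):
            raise ValueError("response_probability must be in [0, 1]")
        if not (0.0 <= self.quiescence_compliance <= 1.0):
            raise ValueError("quiescence_compliance must be in [0, 1]")
        if self.true_slope <= 0:
            raise ValueError("true_slope must be positive")

    def p_right(self, x: float) -> float:
        """True psychometric P(right | signed strength x)."""
        from scipy.special import erf

        l1, l2 = self.true_lapse_left, self.true_lapse_right
        return l1 + (1 - l1 - l2) * (erf((x - self.true_bias) / self.true_slope) + 1) / 2


@dataclass(frozen=True)
class Decision:
    direction: Optional[str]  # 'left' | 'right' | None
    rt: Optional[float]       # s from stimulus onset, None iff no response


def choose_response(
    policy: AgentPolicy,
    signed_strength: float,
    rng: np.random.Generator,
    session_time: float = 0.0,
) -> Decision:
    """Draw a (direction, reaction time) decision for one stimulus.

    Responds at all with ``response_probability``; given a response, turns
    right with the true psychometric probability P(x); RT is log-normal with
    the policy's median and sigma (inflated after ``disengage_after_min``).
    """
    if rng.random() >= policy.response_probability:
        return Decision(None, None)
    direction = "right" if rng.random() < policy.p_right(signed_strength) else "left"
    rt = float(policy.rt_median * np.exp(policy.rt_sigma * rng.standard_normal()))
    if (
        policy.disengage_after_min is not None
        and session_time >= policy.disengage_after_min * 60.0
    ):
        rt *= policy.disengage_rt_factor
    return Decision(direction, max(rt, 0.05))


def render_prestim_trace(
    policy: AgentPolicy,
    quiescence_duration: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Pre-stimulus wheel-angle segment (deg, 100 Hz) starting at trial start.

    With probability ``quiescence_compliance`` the agent is immediately
    still; otherwise it emits impulsive bursts (brief drifting excursions)
    before settling. The segment always ends with at least
    ``quiescence_duration`` + margin of stillness so quiescence is
    eventually satisfiable.
    """
    n_quiet = int(round(quiescence_duration / DT)) + 20
    if policy.impulsivity <= 0 or rng.random() < policy.quiescence_compliance:
        return np.zeros(n_quiet)
    n_bursts = 1 + rng.poisson(policy.impulsivity)
    pieces = [np.zeros(int(round(rng.uniform(0.05, 0.2) / DT)))]
    level = 0.0
    for _ in range(n_bursts):
        amp = rng.uniform(4.0, 25.0) * rng.choice([-1.0, 1.0])
        n_b = int(round(rng.uniform(0.15, 0.35) / DT))
        burst = level + amp * np.sin(np.pi * np.arange(n_b) / n_b) ** 2
        # drift: the wheel does not return all the way
        settle = rng.uniform(0.0, 0.6) * amp
        k = max(n_b // 3, 1)
        burst[-k:] = np.linspace(burst[-k], level + settle, k)
        level += settle
        pieces.append(burst)
        pieces.append(level + np.zeros(int(round(rng.uniform(0.1, 0.4) / DT))))
    pieces.append(level + np.zeros(n_quiet))
    return np.concatenate(pieces)


def render_response_trace(
    policy: AgentPolicy,
    decision: Decision,
    goal: float,
    response_window: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Post-onset wheel-angle segment (deg, 100 Hz, relative to onset angle).

    For a response, a constant-velocity turn timed so the displacement
    crosses ``goal`` within one sample of the decision's RT, continuing to a
    sampled amplitude beyond the goal and then holding. For no response, a
    flat segment spanning the response window.
    """
    post_hold = 0.6  # s of trace kept after the movement completes
    if decision.direction is None:
        return np.zeros(int(round((response_window + post_hold) / DT)) + 1)
    sign = 1.0 if decision.direction == "right" else -1.0
    amp = max(
        goal * 1.2,
        rng.normal(policy.turn_amplitude_mean, policy.turn_amplitude_sd),
    )
    rt = decision.rt
    move_lead = min(0.25, max(rt - DT, 0.01))  # movement starts before the crossing
    v = goal / move_lead  # deg/s so that goal is crossed exactly at rt
    t_start = rt - move_lead
    t_total = t_start + amp / v + post_hold
    n = int(round(t_total / DT)) + 1
    t = np.arange(n) * DT
    seg = np.clip((t - t_start) * v, 0.0, amp)
    return sign * seg


class Agent:
    """Closed-loop wrapper: per-trial decisions plus wheel-trace rendering.

    Go/NoGo and detection reuse the psychometric machinery with the signed
    strength replaced by a respond/withhold evidence variable (+strength for
    Go/target, -strength for NoGo): the probability of responding is then
    P(x), and the turn direction itself is drawn uniformly.
    """

    def __init__(self, policy: AgentPolicy):
        self.policy = policy

    def prestim_trace(self, quiescence_duration: float, rng: np.random.Generator) -> np.ndarray:
        return render_prestim_trace(self.policy, quiescence_duration, rng)

    def decide(
        self,
        task: str,
        signed_strength: float,
        prestim_turning: float,
        session_time: float,
        rng: np.random.Generator,
    ) -> Decision:
        pol = self.policy
        if task == "2afc":
            return choose_response(pol, signed_strength, rng, session_time)
        # detection / gonogo: P(x) is the probability of responding at all
        p_respond = pol.response_probability * float(pol.p_right(signed_strength))
        responded = rng.random() < p_respond
        extra_rt_scale = 1.0
        if not responded and signed_strength < 0 and pol.impulsivity > 0:
            # impulsive overshoot: carried-over pre-stimulus turning can tip a
            # NoGo trial into a false alarm, faster the more the wheel moved
            p_extra = min(0.8, prestim_turning / 60.0)
            if rng.random() < p_extra:
                responded = True
                extra_rt_scale = 1.0 / (1.0 + prestim_turning / 25.0)
        if not responded:
            return Decision(None, None)
        base = choose_response(
            replace(pol, response_probability=1.0), signed_strength, rng, session_time
        )
        direction = "right" if rng.random() < 0.5 else "left"
        return Decision(direction, max(base.rt * extra_rt_scale, 0.05))

    def response_trace(
        self,
        decision: Decision,
        goal: float,
        response_window: float,
        rng: np.random.Generator,
    ) -> np.ndarray:
        return render_response_trace(self.policy, decision, goal, response_window, rng)


#: Documented default parameter sets per profile.
AGENT_PROFILES: dict[str, dict] = {
    "ideal": {},
    "lapsing": {"true_lapse_left": 0.1, "true_lapse_right": 0.1},
    "biased": {"true_bias": 20.0, "true_lapse_left": 0.05, "true_lapse_right": 0.05},
    "impulsive": {
        "impulsivity": 1.5,
        "quiescence_compliance": 0.35,
        "true_lapse_left": 0.05,
        "true_lapse_right": 0.05,
    },
    "disengaging": {"disengage_after_min": 46.0},
    "never_responding": {"response_probability": 0.0},
}


def make_agent(profile: str, **overrides) -> Agent:
    """Build an agent from a named profile with optional field overrides."""
    if profile not in AGENT_PROFILES:
        raise ValueError(
            f"unknown profile {profile!r}; known: {sorted(AGENT_PROFILES)}"
        )
    params = {**AGENT_PROFILES[profile], **overrides}
    return Agent(AgentPolicy(**params))
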