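import numpy as np
import pytest

from dmc_behavior.agents import Agent, AgentPolicy, Decision, make_agent
from dmc_behavior.task_engine import TaskConfig, run_session


class ForcedAgent(Agent):
    """Test double: always responds with a fixed direction and RT."""

    def __init__(self, direction="right", rt=0.3, policy=None):
        super().__init__(policy or AgentPolicy())
        self._direction = direction
        self._rt = rt

    def decide(self, task, signed_strength, prestim_turning, session_time, rng):
        if self._direction is None:
            return Decision(None, None)
        return Decision(self._direction, self._rt)


@pytest.fixture(scope="session")
def ideal_agent():
    return make_agent("ideal")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def short_session(task, agent, seed=0, stage=1, session_min=60.0, session_cap=120.0, **kw):
    """Run a session with shortened virtual durations (unit-test scale)."""
    cfg = TaskConfig.for_task(
        task, stage=stage, session_min=session_min, session_cap=session_cap, **kw
    )
    return run_session(cfg, agent, np.random.default_rng(seed), seed=seed)


@pytest.fixture(scope="session")
def afc_session():
    """A ~5-min simulated 2AFC stage-4 session from a lapsing agent."""
    agent = make_agent("lapsing")
    cfg = TaskConfig.for_task("2afc", stage=4, session_min=240.0, session_cap=300.0)
    return run_session(cfg, agent, np.random.default_rng(7), seed=7)
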