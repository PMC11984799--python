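import numpy as np
import pytest

from dmc_behavior.agents import make_agent
from dmc_behavior.task_engine import (
    StimulusAssignment,
    TaskConfig,
    TrialScheduler,
    check_disengagement,
    classify_outcome,
    run_session,
)

from conftest import ForcedAgent, short_session


def events_dict(trial):
    out = {}
    for tick, name in trial.events:
        out.setdefault(name, []).append(tick)
    return out


def make_fake_trial(rt, index=0):
    """Minimal stand-in record for disengagement-rule unit tests."""

    class T:
        pass

    t = T()
    t.rt = rt
    t.index = index
    return t


class TestClassifyOutcome:
    def test_detection(self):
        a = StimulusAssignment(100.0, "middle")
        assert classify_outcome("detection", a, (1.0, "right")) == "correct"
        assert classify_outcome("detection", a, None) == "incorrect"

    @pytest.mark.parametrize(
        "is_go,crossing,expected",
        [
            (True, (1.0, "left"), "hit"),
            (True, None, "miss"),
            (False, (1.0, "right"), "false_alarm"),
            (False, None, "correct_rejection"),
        ],
    )
    def test_gonogo(self, is_go, crossing, expected):
        a = StimulusAssignment(100.0, "high", is_go=is_go)
        assert classify_outcome("gonogo", a, crossing) == expected

    @pytest.mark.parametrize(
        "side,crossing,expected",
        [
            ("left", (1.0, "left"), "correct"),
            ("left", (1.0, "right"), "incorrect"),
            ("right", (1.0, "right"), "correct"),
            ("left", None, "omission"),
        ],
    )
    def test_2afc(self, side, crossing, expected):
        a = StimulusAssignment(100.0, "low", correct_side=side)
        assert classify_outcome("2afc", a, crossing) == expected

    def test_unknown_task(self):
        with pytest.raises(ValueError):
            classify_outcome("lever", StimulusAssignment(100.0, "low"), None)


class TestTaskConfig:
    def test_window_covers_stimulus(self):
        with pytest.raises(ValueError):
            TaskConfig(task="detection", stimulus_duration=2.0, response_window=1.0)

    def test_detection_defaults(self):
        cfg = TaskConfig.for_task("detection", stage=0)
        assert cfg.turning_goal == 15.0
        assert cfg.response_window == 1.02
        assert cfg.session_cap == 3600.0

    def test_2afc_stage_strengths(self):
        assert TaskConfig.for_task("2afc", stage=3).strengths == (100.0, 85.0, 70.0)
        assert TaskConfig.for_task("2afc", stage=4).strengths == (100.0, 85.0, 70.0, 60.0)
        assert TaskConfig.for_task("2afc", stage=4).response_window == 15.0

    def test_round_trip(self):
        cfg = TaskConfig.for_task("gonogo", stage=1)
        assert TaskConfig.from_dict(cfg.to_dict()) == cfg


class TestScheduler:
    def test_gonogo_repeat_limit(self, rng):
        cfg = TaskConfig.for_task("gonogo", stage=1)
        sched = TrialScheduler(cfg, rng)
        kinds = []
        for _ in range(500):
            a = sched.next()
            sched.record(a, "hit")
            kinds.append(a.is_go)
        for i in range(len(kinds) - 3):
            assert len(set(kinds[i : i + 4])) > 1  # never 4 identical in a row

    def test_2afc_stage0_blocks_switch_after_3_correct(self, rng):
        cfg = TaskConfig.for_task("2afc", stage=0)
        sched = TrialScheduler(cfg, rng)
        sides = []
        for _ in range(12):
            a = sched.next()
            sched.record(a, "correct")
            sides.append(a.correct_side)
        assert sides[0:3] == [sides[0]] * 3
        assert sides[3] != sides[0]  # block switch
        assert sides[3:6] == [sides[3]] * 3

    def test_2afc_stage0_error_resets_block_count(self, rng):
        cfg = TaskConfig.for_task("2afc", stage=0)
        sched = TrialScheduler(cfg, rng)
        for outcome in ("correct", "correct", "incorrect", "correct", "correct"):
            a = sched.next()
            sched.record(a, outcome)
        assert sched.next().correct_side == a.correct_side  # still same block

    def test_repeat_after_error_stages_1_to_3(self, rng):
        cfg = TaskConfig.for_task("2afc", stage=2)
        sched = TrialScheduler(cfg, rng)
        a = sched.next()
        sched.record(a, "incorrect")
        b = sched.next()
        assert (b.strength, b.correct_side) == (a.strength, a.correct_side)

    def test_no_repeat_after_error_stage_4(self):
        cfg = TaskConfig.for_task("2afc", stage=4)
        rng = np.random.default_rng(0)
        sched = TrialScheduler(cfg, rng)
        repeats = 0
        prev = None
        for _ in range(400):
            a = sched.next()
            sched.record(a, "incorrect")
            if prev is not None and (a.strength, a.correct_side) == (prev.strength, prev.correct_side):
                repeats += 1
            prev = a
        assert repeats < 400 * 0.4  # would be ~100% under repeat-on-error

    def test_omission_does_not_trigger_repeat(self):
        cfg = TaskConfig.for_task("2afc", stage=2)
        rng = np.random.default_rng(3)
        sched = TrialScheduler(cfg, rng)
        seen = set()
        for _ in range(50):
            a = sched.next()
            sched.record(a, "omission")
            seen.add(a.correct_side)
        assert seen == {"left", "right"}


class TestRunTrial:
    def test_detection_correct_truncates_stimulus(self):
        record = short_session("detection", ForcedAgent("right", rt=0.3), seed=1)
        t = record.trials[0]
        assert t.outcome == "correct"
        assert t.reward_delivered > 0
        assert t.rt == pytest.approx(0.3, abs=0.011)
        ev = events_dict(t)
        assert ev["stimulus_off"][0] == ev["response"][0]  # immediate termination
        assert t.n_stim_repeats == 1

    def test_stimulus_repeats_until_window_end(self):
        record = short_session("detection", ForcedAgent(None), seed=1)
        t = record.trials[0]
        assert t.outcome == "incorrect"
        # 1.02 s window = two 0.51 s presentations
        assert t.n_stim_repeats == 2
        ev = events_dict(t)
        assert len(ev.get("stimulus_repeat", [])) == 1

    def test_gonogo_false_alarm_noise_and_timeout(self):
        record = short_session("gonogo", ForcedAgent("left", rt=0.2), seed=2)
        fa = next(t for t in record.trials if t.outcome == "false_alarm")
        ev = events_dict(fa)
        assert ev["noise_off"][0] - ev["noise_on"][0] == 50  # 0.5 s exactly
        assert ev["timeout_end"][0] - ev["timeout_start"][0] == 150  # 1.5 s
        hit = next(t for t in record.trials if t.outcome == "hit")
        assert "noise_on" not in events_dict(hit)
        assert hit.reward_delivered > 0

    def test_gonogo_miss_timeout_no_noise(self):
        record = short_session("gonogo", ForcedAgent(None), seed=3)
        miss = next(t for t in record.trials if t.outcome == "miss")
        ev = events_dict(miss)
        assert "timeout_start" in ev and "noise_on" not in ev
        cr = next(t for t in record.trials if t.outcome == "correct_rejection")
        assert "timeout_start" not in events_dict(cr)

    def test_2afc_omission_timeout_without_noise(self):
        record = short_session("2afc", ForcedAgent(None), stage=4, seed=4)
        t = record.trials[0]
        assert t.outcome == "omission"
        ev = events_dict(t)
        assert ev["timeout_end"][0] - ev["timeout_start"][0] == 150
        assert "noise_on" not in ev

    def test_2afc_incorrect_gets_noise(self):
        record = short_session("2afc", ForcedAgent("right", rt=0.3), stage=4, seed=5)
        inc = next(t for t in record.trials if t.outcome == "incorrect")
        assert "noise_on" in events_dict(inc)

    def test_iti_duration_exact(self):
        record = short_session("detection", ForcedAgent("right", rt=0.3), seed=6)
        for t in record.trials:
            ev = events_dict(t)
            assert ev["trial_end"][0] - ev["iti_start"][0] == 50  # 0.5 s

    def test_event_ticks_non_decreasing(self):
        record = short_session("2afc", make_agent("lapsing"), stage=4, seed=7)
        for t in record.trials:
            ticks = [tick for tick, _ in t.events]
            assert ticks == sorted(ticks)

    def test_quiescence_duration_in_range(self):
        record = short_session("detection", ForcedAgent("right", rt=0.3), seed=8)
        for t in record.trials:
            assert 1.0 - 0.005 <= t.quiescence_duration <= 1.5 + 0.005
            assert t.stim_onset >= t.t_start + t.quiescence_duration - 0.011


class TestDisengagement:
    def test_inactive_before_session_min(self):
        trials = [make_fake_trial(None, i) for i in range(30)]
        assert not check_disengagement("detection", trials, 40 * 60.0, 45 * 60.0)

    def test_detection_rule(self):
        trials = [make_fake_trial(0.3 if i % 7 == 0 else None, i) for i in range(40)]
        # last 20 trials contain ceil(20/7)=3 crossings -> disengaged
        assert check_disengagement("detection", trials, 50 * 60.0, 45 * 60.0)
        trials = [make_fake_trial(0.3 if i % 4 == 0 else None, i) for i in range(40)]
        assert not check_disengagement("detection", trials, 50 * 60.0, 45 * 60.0)

    def test_needs_twenty_trials(self):
        trials = [make_fake_trial(None, i) for i in range(19)]
        assert not check_disengagement("detection", trials, 50 * 60.0, 45 * 60.0)

    def test_2afc_rolling_median_rule(self):
        fast = [make_fake_trial(0.4, i) for i in range(100)]
        slow = [make_fake_trial(2.0, 100 + i) for i in range(20)]
        assert check_disengagement("2afc", fast + slow, 50 * 60.0, 45 * 60.0)
        assert not check_disengagement("2afc", fast, 50 * 60.0, 45 * 60.0)

    def test_2afc_omissions_count_as_infinite_rt(self):
        fast = [make_fake_trial(0.4, i) for i in range(100)]
        omitted = [make_fake_trial(None, 100 + i) for i in range(20)]
        assert check_disengagement("2afc", fast + omitted, 50 * 60.0, 45 * 60.0)


class TestRunSession:
    def test_never_responder_disengages_after_45_min(self):
        cfg = TaskConfig.for_task("detection", stage=1)
        record = run_session(cfg, make_agent("never_responding"), np.random.default_rng(0))
        assert record.termination_reason == "disengaged"
        assert record.t_end >= 45 * 60.0
        assert record.t_end <= 45 * 60.0 + 30 * 60  # well before cap

    def test_time_cap_respected(self):
        record = short_session("detection", ForcedAgent("right", rt=0.3), seed=9)
        assert record.termination_reason == "time_cap"
        assert record.t_end <= 120.0

    def test_session_replay_determinism(self):
        a = short_session("2afc", make_agent("lapsing"), stage=4, seed=11)
        b = short_session("2afc", make_agent("lapsing"), stage=4, seed=11)
        assert len(a.trials) == len(b.trials)
        for ta, tb in zip(a.trials, b.trials):
            assert ta == tb
        np.testing.assert_array_equal(a.wheel.angle, b.wheel.angle)

    def test_wheel_trace_continuous_across_trials(self):
        record = short_session("2afc", make_agent("impulsive"), stage=4, seed=12)
        jumps = np.abs(np.diff(record.wheel.angle))
        assert np.max(jumps) < 25.0  # no teleporting between trials

    def test_pretraining_session(self):
        cfg = TaskConfig.for_task("pretraining", pretraining_session_index=1)
        record = run_session(cfg, make_agent("ideal"), np.random.default_rng(0))
        assert record.t_end == pytest.approx(15 * 60.0, abs=3.0)
        assert record.n_trials > 200
        assert all(t.outcome is None for t in record.trials)
        assert record.total_reward == pytest.approx(record.n_trials * 5.0)
        assert np.all(record.wheel.angle == 0.0)  # wheel immobilized

    @pytest.mark.parametrize("idx,minutes", [(1, 15), (2, 30), (3, 45)])
    def test_pretraining_durations(self, idx, minutes):
        cfg = TaskConfig.for_task("pretraining", pretraining_session_index=idx)
        assert cfg.session_cap == minutes * 60.0

    def test_reward_multiplier_applied(self):
        record = short_session(
            "2afc",
            ForcedAgent("left", rt=0.3),
            stage=4,
            seed=13,
            reward_multipliers={"left": 2.0, "right": 1.0},
        )
        correct = [t for t in record.trials if t.outcome == "correct"]
        assert correct and all(
            t.reward_delivered == pytest.approx(2.0 * record.config.reward_size)
            for t in correct
        )
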