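import numpy as np
import pytest

from mozznet.audio_io import Label
from mozznet.controller import (
    Action,
    ControllerConfig,
    FIELD_WEEK_RUN_PROFILES,
    PowerController,
    Trigger,
    build_run_stream,
    positive_runs,
    replay_field_week,
    run_session,
)
from mozznet.detector import SegmentDecision

from reference_controller import algorithm_on_times

L_SEG = 0.33


def _stream(flags, start_slot=0):
    """Decision stream from a positive/negative flag sequence."""
    scores = {True: np.array([0.0, 0.0, 256.0]), False: np.array([256.0, 0.0, 0.0])}
    return [
        SegmentDecision((start_slot + i) * L_SEG, scores[bool(f)], Label.MOSQUITO, bool(f))
        for i, f in enumerate(flags)
    ]


def _on_events(decisions, config=None):
    events, _ = run_session(decisions, config or ControllerConfig())
    return [e for e in events if e.action == Action.POWER_ON]


class TestTriggerRules:
    def test_three_consecutive_positives_trigger_on_the_third(self):
        ons = _on_events(_stream([1, 1, 1, 0, 0]))
        assert len(ons) == 1
        assert ons[0].time_s == pytest.approx(2 * L_SEG)
        assert ons[0].trigger == Trigger.CONSECUTIVE_RUN

    def test_isolated_positive_never_triggers_and_state_expires(self):
        ctrl = PowerController()
        for d in _stream([1] + [0] * 40):
            assert ctrl.step(d) == []
        assert not ctrl.state.i_mos  # watch window expired

    def test_two_consecutive_positives_do_not_trigger(self):
        assert _on_events(_stream([1, 1] + [0] * 40)) == []

    def test_non_consecutive_pair_triggers(self):
        ons = _on_events(_stream([1, 0, 1]))
        assert len(ons) == 1
        assert ons[0].trigger == Trigger.NON_CONSECUTIVE_PAIR

    def test_pair_separated_by_more_than_window_does_not_trigger(self):
        gap = int(12 / L_SEG)
        assert _on_events(_stream([1] + [0] * gap + [1])) == []

    def test_two_qualifying_runs_in_one_window_trigger_once(self):
        ons = _on_events(_stream([1, 1, 1, 1, 0, 0, 1, 1, 1]))
        assert len(ons) == 1

    def test_empty_stream_no_events(self):
        events, summary = run_session([])
        assert events == [] and summary["n_power_on"] == 0

    def test_out_of_order_decisions_rejected(self):
        ctrl = PowerController()
        ctrl.step(_stream([0], start_slot=10)[0])
        with pytest.raises(ValueError):
            ctrl.step(_stream([0], start_slot=0)[0])


class TestPowerTiming:
    def test_power_off_exactly_l_power_after_on(self):
        cfg = ControllerConfig()
        decisions = _stream([1, 1, 1]) + _stream([0], start_slot=11000)
        events, _ = run_session(decisions, cfg)
        on = [e for e in events if e.action == Action.POWER_ON][0]
        off = [e for e in events if e.action == Action.POWER_OFF][0]
        assert off.time_s == pytest.approx(on.time_s + cfg.l_power_s)

    def test_power_off_check_boundaries(self):
        ctrl = PowerController()
        ctrl.state.i_power = True
        ctrl.state.t_power = 0.0
        assert ctrl.power_off_check(3599.0) == []
        events = ctrl.power_off_check(3600.33)
        assert len(events) == 1 and events[0].action == Action.POWER_OFF
        assert events[0].time_s == pytest.approx(3600.0)

    def test_never_on_never_off(self):
        assert PowerController().power_off_check(1e6) == []

    def test_events_alternate_and_on_time_accounting(self):
        # two bursts far apart: ON, OFF, ON, OFF (the first decision after
        # the vaporization period is still skipped, hence four positives)
        decisions = _stream([1, 1, 1]) + _stream([1, 1, 1, 1], start_slot=12000)
        events, summary = run_session(decisions)
        actions = [e.action for e in events]
        assert actions == [Action.POWER_ON, Action.POWER_OFF] * 2
        assert summary["on_time_s"] == 2 * 3600.0

    def test_positives_during_vaporization_never_retrigger(self):
        decisions = _stream([1, 1, 1] + [1] * 200)
        assert len(_on_events(decisions)) == 1

    def test_all_positive_eight_hours_gives_one_on_per_power_period(self):
        n = int(8 * 3600 / L_SEG)
        ons = _on_events(_stream([1] * n))
        assert len(ons) == 8  # ceil(8 h / 1 h)


class TestFieldWeekReplay:
    def test_run_length_partition(self):
        stream = build_run_stream([1, 1, 3, (4, 3)])
        assert positive_runs(stream) == [1, 1, 3, 4, 3]

    def test_week_totals_match_field_observation(self):
        per_night, totals = replay_field_week()
        assert totals == {"n_positive_runs": 43, "n_power_on": 8}

    def test_per_night_decisions(self):
        per_night, _ = replay_field_week()
        expected = dict(
            night1=1, night2=0, night3=2, night4=1, night5=0, night6=2, night7=2
        )
        assert {k: v["n_power_on"] for k, v in per_night.items()} == expected

    def test_lone_runs_of_one_and_two_are_fully_suppressed(self):
        _, summary = run_session(build_run_stream([1, 2, 1, 2, 2]))
        assert summary["n_power_on"] == 0
        assert summary["n_suppressed_runs"] == 5


def _random_streams(n_streams, rng, max_len=60):
    for _ in range(n_streams):
        length = int(rng.integers(1, max_len))
        p = rng.uniform(0.05, 0.6)
        yield rng.random(length) < p


class TestAgainstReferenceTranscription:
    def test_matches_pseudocode_transcription_on_random_streams(self, rng):
        cfg = ControllerConfig()
        for flags in _random_streams(2000, rng):
            decisions = _stream(flags)
            ours = [e.time_s for e in _on_events(decisions, cfg)]
            ref = algorithm_on_times([(d.time_s, d.positive) for d in decisions])
            assert ours == ref

    def test_no_trigger_from_fewer_than_x_fp_positives_in_window(self, rng):
        cfg = ControllerConfig()
        for flags in _random_streams(300, rng):
            decisions = _stream(flags)
            times = {d.time_s for d in decisions if d.positive}
            for e in _on_events(decisions, cfg):
                in_window = [t for t in times if e.time_s - cfg.l_win_s < t <= e.time_s]
                assert len(in_window) >= cfg.x_fp

    def test_longer_window_triggers_a_superset_of_streams(self, rng):
        cfg10 = ControllerConfig(l_win_s=10.0)
        cfg20 = ControllerConfig(l_win_s=20.0)
        for flags in _random_streams(300, rng, max_len=120):
            decisions = _stream(flags)
            if _on_events(decisions, cfg10):
                assert _on_events(decisions, cfg20)
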