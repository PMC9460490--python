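"""Vaporizer power control with false-positive suppression.

A single positive 330 ms segment never actuates the vaporizer: spurious
positives from everyday noise would otherwise keep it on (at theta=210
the mean time to a false positive is minutes).  Instead, the first
positive opens a watch window of length L_win anchored at that positive
(T_mos).  Within the window, further positives falling inside the
coalescing interval of X_fp segments (i.e. the immediately following
segment slots, X_fp * L_seg) are absorbed; the first positive arriving
after the coalescing interval but still inside the window triggers
POWER_ON.  With X_fp = 2 this realises the deployed rule: at least
X_fp + 1 = 3 consecutive positive segments, or X_fp = 2 positives that
are not consecutive, within L_win = 10 s.

On POWER_ON the vaporizer runs for a fixed L_power (1 h), the watch state
resets, and positives during vaporization never re-trigger; by default
(sense_during_vape=False) sensing pauses entirely until POWER_OFF.  If no
trigger completes within L_win of T_mos the watch state expires at the
next evaluated segment (isolated positives and lone pairs of consecutive
positives are thereby suppressed).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field

import numpy as np

from .audio_io import Label
from .detector import SegmentDecision

_EPS = 1e-9


@dataclass
class ControllerConfig:
    x_fp: int = 2
    l_win_s: float = 10.0
    l_power_s: float = 3600.0
    l_seg_s: float = 0.33
    l_slice_s: float = 0.03
    sense_during_vape: bool = False

    def __post_init__(self) -> None:
        if self.x_fp < 1:
            raise ValueError("x_fp must be >= 1")
        if self.l_win_s <= self.x_fp * self.l_seg_s:
            raise ValueError("l_win_s must exceed the coalescing interval")
        if self.l_power_s <= 0:
            raise ValueError("l_power_s must be positive")


class Action(enum.Enum):
    POWER_ON = "POWER_ON"
    POWER_OFF = "POWER_OFF"


class Trigger(enum.Enum):
    CONSECUTIVE_RUN = "consecutive-run"
    NON_CONSECUTIVE_PAIR = "non-consecutive-pair"
    TIMEOUT = "timeout"


@dataclass(frozen=True)
class ActuationEvent:
    time_s: float
    action: Action
    trigger: Trigger


@dataclass
class ControllerState:
    t_now: float = 0.0
    t_mos: float = 0.0  # last first-positive registration
    t_power: float = 0.0  # last power-on
    i_mos: bool = False
    i_power: bool = False
    run_length: int = 0  # current consecutive-positive run (for event labelling)
    _last_positive_t: float | None = None


class PowerController:
    """Algorithm state machine folding segment decisions into actuation events."""

    def __init__(self, config: ControllerConfig | None = None):
        self.config = config or ControllerConfig()
        self.state = ControllerState()

    def step(self, decision: SegmentDecision) -> list[ActuationEvent]:
        """Advance by one segment decision; returns 0..1 events.

        Decisions must arrive in time order, one per segment.  The
        power-off check runs at the *end* of the iteration, as in the
        deployed control loop, so the first decision after the
        vaporization period elapses is still skipped.
        """
        cfg, st = self.config, self.state
        t = decision.time_s
        if t < st.t_now - _EPS:
            raise ValueError(f"out-of-order decision at t={t} (now {st.t_now})")
        st.t_now = t
        events: list[ActuationEvent] = []

        if not st.i_power or cfg.sense_during_vape:
            # consecutive-run bookkeeping (event labelling only)
            if decision.positive:
                adjacent = (
                    st._last_positive_t is not None
                    and t - st._last_positive_t <= cfg.l_seg_s * 1.5
                )
                st.run_length = st.run_length + 1 if adjacent else 1
                st._last_positive_t = t

            if not st.i_power:  # positives while ON never re-trigger
                # watch-window expiry: no qualifying pattern within L_win
                if st.i_mos and t - st.t_mos >= cfg.l_win_s - _EPS:
                    st.i_mos = False

                if decision.positive:
                    if not st.i_mos:
                        st.i_mos = True
                        st.t_mos = t - cfg.l_slice_s
                    elif t - st.t_mos <= cfg.x_fp * cfg.l_seg_s + _EPS:
                        pass  # coalesce the first x_fp positives
                    elif t - st.t_mos < cfg.l_win_s - _EPS:
                        st.i_mos = False
                        st.i_power = True
                        st.t_power = t
                        kind = (
                            Trigger.CONSECUTIVE_RUN
                            if st.run_length >= cfg.x_fp + 1
                            else Trigger.NON_CONSECUTIVE_PAIR
                        )
                        events.append(ActuationEvent(t, Action.POWER_ON, kind))

        events.extend(self.power_off_check(t))
        return events

    def power_off_check(self, t_now: float) -> list[ActuationEvent]:
        """POWER_OFF exactly when the vaporizer has run longer than L_power."""
        cfg, st = self.config, self.state
        if st.i_power and t_now - st.t_power > cfg.l_power_s + _EPS:
            st.i_power = False
            return [ActuationEvent(st.t_power + cfg.l_power_s, Action.POWER_OFF, Trigger.TIMEOUT)]
        return []


def positive_runs(decisions) -> list[int]:
    """Lengths of maximal consecutive-positive runs, in stream order.

    Two positives are consecutive when their timestamps differ by one
    segment (gaps in a sparse stream count as negatives).
    """
    runs, run, last_t = [], 0, None
    for d in decisions:
        if d.positive:
            if run and last_t is not None and d.time_s - last_t <= 0.33 * 1.5:
                run += 1
            else:
                if run:
                    runs.append(run)
                run = 1
            last_t = d.time_s
        else:
            if run:
                runs.append(run)
            run = 0
    if run:
        runs.append(run)
    return runs


def run_session(decisions, config: ControllerConfig | None = None):
    """Fold a decision stream; returns (events, summary).

    The summary partitions the positive segments into maximal consecutive
    runs by length and counts suppressed vs actuated detections.  A
    vaporization still running at stream end is closed with its scheduled
    POWER_OFF.
    """
    config = config or ControllerConfig()
    ctrl = PowerController(config)
    events = []
    for d in decisions:
        events.extend(ctrl.step(d))
    if ctrl.state.i_power:
        ctrl.state.i_power = False
        events.append(
            ActuationEvent(
                ctrl.state.t_power + config.l_power_s, Action.POWER_OFF, Trigger.TIMEOUT
            )
        )
    runs = positive_runs(decisions)
    hist: dict[int, int] = {}
    for r in runs:
        hist[r] = hist.get(r, 0) + 1
    n_on = sum(1 for e in events if e.action == Action.POWER_ON)
    summary = {
        "run_length_histogram": dict(sorted(hist.items())),
        "n_positive_segments": int(sum(runs)),
        "n_positive_runs": len(runs),
        "n_power_on": n_on,
        "n_suppressed_runs": len(runs) - n_on,
        "on_time_s": n_on * config.l_power_s,
    }
    return events, summary


# -------------------------------------------------- field-trial replay


#: Run-length profiles of positive segment decisions observed in a
#: week-long overnight bedroom deployment (8 h/night, no mosquito sound
#: played): for each night, the lengths of the maximal consecutive runs
#: of positives, in replay order.  On night 6 a run of 4 was followed by
#: a run of 3 within a single 10 s watch window (marked by a tuple), and
#: the ON-state lockout makes the pair actuate only once.
FIELD_WEEK_RUN_PROFILES: dict[str, list] = {
    "night1": [2, 3],
    "night2": [1, 1, 1, 2, 2, 2],
    "night3": [1, 1, 1, 1, 1, 1, 2, 2, 3, 5],
    "night4": [1, 1, 2, 2, 3],
    "night5": [1, 1, 1, 2, 2],
    "night6": [1, 1, 3, (4, 3)],
    "night7": [1, 1, 1, 1, 2, 2, 2, 2, 4, 4],
}


def build_run_stream(
    profile: list,
    l_seg_s: float = 0.33,
    gap_segments: int = 11213,
    pair_gap_segments: int = 2,
) -> list[SegmentDecision]:
    """Positive-only decision stream realizing a run-length profile.

    Runs are separated by ``gap_segments`` segment slots (the default,
    ~3700 s, exceeds both the watch window and the vaporization period so
    every run is judged independently); a tuple ``(a, b)`` places run b
    only ``pair_gap_segments`` slots after run a, inside one watch window.
    """
    decisions = []
    slot = 0

    def emit(length):
        nonlocal slot
        for _ in range(length):
            decisions.append(
                SegmentDecision(
                    slot * l_seg_s, np.array([0.0, 0.0, 256.0]), Label.MOSQUITO, True
                )
            )
            slot += 1

    for entry in profile:
        if isinstance(entry, tuple):
            first, *rest = entry
            emit(first)
            for r in rest:
                slot += pair_gap_segments
                emit(r)
        else:
            emit(entry)
        slot += gap_segments
    return decisions


def replay_field_week(
    profiles: dict[str, list] | None = None, config: ControllerConfig | None = None
):
    """Replay each night's profile independently; per-night and total counts."""
    profiles = profiles or FIELD_WEEK_RUN_PROFILES
    config = config or ControllerConfig()
    per_night = {}
    for night, profile in profiles.items():
        _, summary = run_session(build_run_stream(profile, config.l_seg_s), config)
        per_night[night] = summary
    totals = {
        "n_positive_runs": sum(s["n_positive_runs"] for s in per_night.values()),
        "n_power_on": sum(s["n_power_on"] for s in per_night.values()),
    }
    return per_night, totals


def events_to_csv(events, path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "action", "trigger"])
        for e in events:
            w.writerow([f"{e.time_s:.2f}", e.action.value, e.trigger.value])


def summary_to_json(summary, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2)
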