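"""Run the full pipeline: wingbeat at a distance -> decisions -> actuation.

Trains the classifier, synthesizes a 10 s female wingbeat received at
40 cm (1/r attenuation over a quiet-room floor), streams it through the
330 ms segment detector at theta=210, and feeds the decisions to the
power controller (>=3 consecutive or >=2 non-consecutive positives in
10 s).  Also replays the week-long field-trial run-length profiles to
show the false-positive suppression arithmetic.
"""

from mozznet import (
    ControllerConfig,
    DetectorConfig,
    DistanceModel,
    WingbeatSpec,
    attenuate,
    gen_mosquito,
    replay_field_week,
    run_session,
    stream_decisions,
)
from mozznet.pipeline import train_default_model


def main():
    model, info = train_default_model(seed=0)
    print(f"held-out validation accuracy: {info['validation_accuracy']:.3f}\n")

    source = gen_mosquito(WingbeatSpec(sex="female", duration_s=10.0, level_db=32.0, seed=4))
    received = attenuate(source, DistanceModel(), 40.0)
    decisions = stream_decisions(received, model, DetectorConfig())
    n_pos = sum(d.positive for d in decisions)
    print(f"10 s wingbeat at 40 cm: {len(decisions)} segments, {n_pos} positive")

    events, summary = run_session(decisions, ControllerConfig())
    ons = [e for e in events if e.action.value == "POWER_ON"]
    print(f"power-on events: {len(ons)}"
          + (f" (first at t={ons[0].time_s:.2f} s, {ons[0].trigger.value})" if ons else ""))

    print("\nfield-week replay (no mosquito sound played):")
    per_night, totals = replay_field_week()
    for night, s in per_night.items():
        print(f"  {night}: {s['n_positive_runs']:>2} positive runs -> "
              f"{s['n_power_on']} vaporizer decisions")
    print(f"  total: {totals['n_positive_runs']} runs -> {totals['n_power_on']} decisions "
          "(isolated positives and lone pairs are suppressed)")


if __name__ == "__main__":
    main()
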