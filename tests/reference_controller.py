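"""Line-by-line transcription of the deployed power-control loop.

Kept deliberately flat and pseudocode-shaped (one while-style pass,
explicit timestamp arithmetic) so it can serve as an independent oracle
for the PowerController state machine.  Two agreed gap-fixes of the
printed loop are included, matching the production semantics: the watch
flag expires once T_now - T_mos reaches L_win without a trigger, and
classification is skipped entirely while the vaporizer runs (sensing
pauses during vaporization).
"""

_EPS = 1e-9


def algorithm_on_times(
    decisions,
    x_fp: int = 2,
    l_win: float = 10.0,
    l_power: float = 3600.0,
    l_seg: float = 0.33,
    l_slice: float = 0.03,
):
    """Times of every power-on over a decision stream of (time, positive)."""
    t_mos = 0.0
    t_power = 0.0
    i_mos = False
    i_power = False
    on_times = []
    for t_now, positive in decisions:
        if not i_power:
            # watch-window expiry (gap fix): no trigger completed in L_win
            if i_mos and t_now - t_mos >= l_win - _EPS:
                i_mos = False
            # Power control check (ON)
            if positive:
                if i_mos is False:  # first positive since last vaporization
                    i_mos = True
                    t_mos = t_now - l_slice  # register the event
                else:
                    if t_now - t_mos <= x_fp * l_seg + _EPS:
                        pass  # coalesce the first x_fp positives
                    else:
                        if t_now - t_mos < l_win - _EPS:  # x_fp+ positives in L_win
                            i_mos = False
                            i_power = True
                            t_power = t_now
                            on_times.append(t_now)  # power_control(ON)
        # Power control check (OFF)
        if i_power and t_now - t_power > l_power + _EPS:
            i_power = False  # power_control(OFF)
    return on_times
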