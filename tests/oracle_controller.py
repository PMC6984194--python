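"""Independent tick-by-tick simulation of the six-state hand controller.

Written directly from the state-transition narrative, deliberately without
reusing any package code, so it can serve as the oracle for
``run_controller`` equivalence checks.
"""

OPEN, FLEXING, JUST_CLOSED, CLOSED, EXTENDING, JUST_OPENED = (
    "remaining_opened", "currently_flexing", "just_closed",
    "remaining_closed", "currently_extending", "just_opened",
)


def simulate(p_of, p_ce, p_ef, dt=0.05, theta_of=0.7, theta_ce=0.7, theta_ef=0.7,
             movement_duration=2.0, timeout=2.0, initial=OPEN):
    """Return (state per tick, movement events as (tick_index, label))."""
    state = initial
    entered = 0
    states, movements = [], []
    for i in range(len(p_of)):
        elapsed = (i - entered) * dt
        new = state
        move = None
        if state == OPEN:
            if p_of[i] >= theta_of:
                new, move = FLEXING, "movement_flexion"
        elif state == FLEXING:
            if elapsed >= movement_duration:
                new = JUST_CLOSED
        elif state == JUST_CLOSED:
            if p_ce[i] >= theta_ce and (1.0 - p_ef[i]) >= theta_ef:
                new, move = EXTENDING, "movement_extension"
            elif elapsed >= timeout:
                new = CLOSED
        elif state == CLOSED:
            if p_ce[i] >= theta_ce:
                new, move = EXTENDING, "movement_extension"
        elif state == EXTENDING:
            if elapsed >= movement_duration:
                new = JUST_OPENED
        elif state == JUST_OPENED:
            if p_of[i] >= theta_of and p_ef[i] >= theta_ef:
                new, move = FLEXING, "movement_flexion"
            elif elapsed >= timeout:
                new = OPEN
        if new != state:
            entered = i
        state = new
        states.append(state)
        if move is not None:
            movements.append((i, move))
    return states, movements
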