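"""Feedback-block performance evaluation and questionnaire scoring.

The self-paced feedback tasks have no fixed trial grid, so a trial
structure is reconstructed post hoc from the command and movement logs:
from each command, consecutive 5 s intended-movement trials run until the
commanded movement occurs (the trial containing it scores TP, earlier ones
FN); from that movement, consecutive 5 s intended-rest trials run until the
next command (no movement: TN, any movement: FP).  Feedback accuracy is
100 * (TP + TN) / total.  Questionnaire constructs (ownership, agency,
experiential realness, imagery-action binding, plus controls) average three
7-point items each, with induction declared at a mean of >= 1 (inclusive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import EventMarker

logger = logging.getLogger(__name__)

__all__ = [
    "Trial",
    "TrialLedger",
    "ConstructScore",
    "reconstruct_trials",
    "feedback_accuracy",
    "grasp_outcome",
    "rest_move_counts",
    "rest_move_ledger",
    "score_questionnaire",
    "TRIAL_DURATION",
    "CONSTRUCT_ITEMS",
]

#: Reconstructed trials are contiguous 5 s segments.
TRIAL_DURATION = 5.0

#: Movement type that satisfies each explicit command (hand opening is an
#: extension, closing a flexion; grasp = extension then flexion).
_COMMAND_MOVEMENT = {
    "command_close": "movement_flexion",
    "command_open": "movement_extension",
}


@dataclass(frozen=True)
class Trial:
    start: float
    end: float
    intended: str  # "movement" | "rest"
    outcome: str   # "TP" | "FN" | "TN" | "FP"


@dataclass
class TrialLedger:
    """Reconstructed 5 s trials with confusion outcomes."""

    trials: list = field(default_factory=list)
    wrong_polarity: list = field(default_factory=list)  # movement times logged as FN-with-wrong-direction

    @property
    def counts(self) -> dict:
        c = {"TP": 0, "FN": 0, "TN": 0, "FP": 0}
        for t in self.trials:
            c[t.outcome] += 1
        return c

    def __len__(self):
        return len(self.trials)


def _movements_in(movements, start, end):
    return [m for m in movements if start <= m.time < end]


def grasp_outcome(command_time: float, movements, until: float = np.inf,
                  commands=()):
    """When a grasp command (extension then immediately flexion) is satisfied.

    Satisfied at the first flexion directly following an extension, both
    after the command, before ``until`` and with no intervening command.
    Returns the satisfaction time or None.
    """
    seq = sorted(m for m in movements if command_time < m.time < until)
    cmd_times = sorted(c.time for c in commands if command_time < c.time < until)
    prev = None
    for m in seq:
        if prev is not None and prev.label == "movement_extension" and m.label == "movement_flexion":
            if not any(prev.time < ct < m.time for ct in cmd_times):
                return m.time
        prev = m
    return None


def _satisfaction_time(command: EventMarker, movements, until: float, commands):
    if command.label == "command_grasp":
        return grasp_outcome(command.time, movements, until, commands)
    wanted = _COMMAND_MOVEMENT[command.label]
    for m in sorted(movements):
        if command.time < m.time < until and m.label == wanted:
            return m.time
    return None


def reconstruct_trials(commands, movements, session_end: float) -> TrialLedger:
    """Rebuild the 5 s trial structure from command and movement logs.

    Command-relative grids: intended-movement trials start at each command;
    intended-rest trials start at the satisfying movement.  A later command
    supersedes an unsatisfied one (logged); partial trailing segments
    shorter than 5 s are dropped; movements before any command count
    against an implicit initial rest series starting at time zero.
    """
    commands = sorted(commands)
    movements = sorted(movements)
    for c in commands:
        if not c.label.startswith("command_"):
            raise ValueError(f"not a command marker: {c.label!r}")
    for m in movements:
        if not m.label.startswith("movement_"):
            raise ValueError(f"not a movement marker: {m.label!r}")

    ledger = TrialLedger()

    def add_rest_trials(start, stop, exclude_time=None):
        # the series-terminating movement anchors the grid but is not a
        # rest-trial violation itself
        t = start
        while t + TRIAL_DURATION <= stop:
            moved = [m for m in _movements_in(movements, t, t + TRIAL_DURATION)
                     if m.time != exclude_time]
            ledger.trials.append(Trial(t, t + TRIAL_DURATION, "rest", "FP" if moved else "TN"))
            t += TRIAL_DURATION

    _WRONG_DIRECTION = {
        "command_close": "movement_extension",
        "command_open": "movement_flexion",
        "command_grasp": None,  # both directions are legitimate grasp progress
    }

    def add_movement_trials(cmd, stop, satisfied_at):
        """Movement trials on the 5 s grid from the command; the trial
        containing ``satisfied_at`` is TP and ends the series."""
        wrong_label = _WRONG_DIRECTION[cmd.label]
        t = cmd.time
        while t + TRIAL_DURATION <= min(stop, session_end):
            end = t + TRIAL_DURATION
            if satisfied_at is not None and t <= satisfied_at < end:
                ledger.trials.append(Trial(t, end, "movement", "TP"))
                return
            wrong = [m for m in _movements_in(movements, t, end) if m.label == wrong_label]
            if wrong:
                ledger.wrong_polarity.extend(m.time for m in wrong)
            ledger.trials.append(Trial(t, end, "movement", "FN"))
            t += TRIAL_DURATION

    # implicit initial rest series before the first command
    first_cmd = commands[0].time if commands else session_end
    add_rest_trials(0.0, first_cmd)

    for i, cmd in enumerate(commands):
        next_cmd = commands[i + 1].time if i + 1 < len(commands) else session_end
        ts = _satisfaction_time(cmd, movements, next_cmd, commands)
        if ts is None and i + 1 < len(commands):
            logger.info("command at %.1f s superseded unsatisfied by the next command", cmd.time)
        add_movement_trials(cmd, next_cmd, ts)
        if ts is not None:
            add_rest_trials(ts, next_cmd, exclude_time=ts)

    return ledger


def feedback_accuracy(ledger: TrialLedger) -> float:
    """100 x (TP + TN) / total trials."""
    c = ledger.counts
    total = sum(c.values())
    if total == 0:
        raise ValueError("empty trial ledger")
    return 100.0 * (c["TP"] + c["TN"]) / total


def _phase_schedule(phase_events, phase_duration, n_phases):
    if phase_events is not None:
        phases = sorted((e.time, e.label) for e in phase_events
                        if e.label in ("phase_move", "phase_rest"))
        if not phases:
            raise ValueError("no phase markers in the schedule")
    else:
        phases = [(k * phase_duration, "phase_move" if k % 2 == 0 else "phase_rest")
                  for k in range(n_phases)]
    starts = [t for t, _ in phases]
    ends = starts[1:] + [starts[-1] + phase_duration]
    return phases, ends


def _movement_times(movements):
    if hasattr(movements, "movements"):  # ControllerTrace
        return np.asarray(sorted(t for t, _ in movements.movements))
    return np.asarray(sorted(
        m.time if isinstance(m, EventMarker) else float(m) for m in movements))


def rest_move_ledger(movements, phase_events=None, phase_duration: float = 30.0,
                     n_phases: int = 8) -> TrialLedger:
    """5 s trial scoring of the rest-vs-move task.

    Move phases consist solely of intended-movement trials and rest phases
    of intended-rest trials; each phase is cut into 5 s segments on its own
    grid (partial tails dropped).
    """
    times = _movement_times(movements)
    phases, ends = _phase_schedule(phase_events, phase_duration, n_phases)
    ledger = TrialLedger()
    for (t0, label), t1 in zip(phases, ends):
        t = t0
        while t + TRIAL_DURATION <= t1:
            moved = bool(np.any((times >= t) & (times < t + TRIAL_DURATION)))
            if label == "phase_move":
                outcome = "TP" if moved else "FN"
                intended = "movement"
            else:
                outcome = "FP" if moved else "TN"
                intended = "rest"
            ledger.trials.append(Trial(t, t + TRIAL_DURATION, intended, outcome))
            t += TRIAL_DURATION
    return ledger


def rest_move_counts(movements, phase_events=None, phase_duration: float = 30.0,
                     n_phases: int = 8):
    """Movement counts per phase of the rest-vs-move task.

    ``movements`` may be a list of markers or a ControllerTrace.  Phases
    are left-closed right-open intervals taken from ``phase_events``
    (phase_move/phase_rest markers) or from the default schedule of
    ``n_phases`` alternating 30 s phases starting with a move phase.
    Returns ``(move_counts, rest_counts)`` as arrays of per-phase counts.
    """
    times = _movement_times(movements)
    phases, ends = _phase_schedule(phase_events, phase_duration, n_phases)
    if times.size and times.max() >= ends[-1] + phase_duration:
        raise ValueError("movements extend past the phase schedule")

    move_counts, rest_counts = [], []
    for (t0, label), t1 in zip(phases, ends):
        n = int(np.sum((times >= t0) & (times < t1)))
        (move_counts if label == "phase_move" else rest_counts).append(n)
    return np.asarray(move_counts), np.asarray(rest_counts)


# ---------------------------------------------------------------------------
# questionnaire

#: Item keys per phenomenal construct (7-point ratings in -3..+3).
CONSTRUCT_ITEMS = {
    "SoO": ["soo_1", "soo_2", "soo_3"],
    "SoA": ["soa_1", "soa_2", "soa_3"],
    "ER": ["er_1", "er_2", "er_3"],
    "MIAB": ["miab_1", "miab_2", "miab_3"],
    "SoO_control": ["soo_ctrl_1", "soo_ctrl_2"],
    "SoA_control": ["soa_ctrl_1"],
}

_CONTROL_CONSTRUCTS = {"SoO_control", "SoA_control"}
INDUCTION_THRESHOLD = 1.0


@dataclass(frozen=True)
class ConstructScore:
    construct: str
    items: tuple
    mean: float
    induced: bool


def score_questionnaire(ratings: dict) -> list:
    """Average the items of each construct and apply the induction criterion.

    ``ratings`` maps item keys (see :data:`CONSTRUCT_ITEMS`) or construct
    names to integer ratings in [-3, 3].  A construct counts as induced at
    a mean of >= 1; control constructs are scored but never flagged.
    """
    problems = []
    scores = []
    for construct, item_keys in CONSTRUCT_ITEMS.items():
        if construct in ratings:  # construct-level list of ratings
            values = list(ratings[construct])
            if len(values) != len(item_keys):
                problems.append(f"{construct}: expected {len(item_keys)} items")
                continue
        else:
            missing = [k for k in item_keys if k not in ratings]
            if missing:
                problems.append(f"missing items: {', '.join(missing)}")
                continue
            values = [ratings[k] for k in item_keys]
        bad = [v for v in values if not (float(v).is_integer() and -3 <= v <= 3)]
        if bad:
            problems.append(f"{construct}: ratings outside integer range [-3, 3]: {bad}")
            continue
        mean = float(np.mean(values))
        induced = bool(mean >= INDUCTION_THRESHOLD) and construct not in _CONTROL_CONSTRUCTS
        scores.append(ConstructScore(construct, tuple(int(v) for v in values), mean, induced))
    if problems:
        raise ValueError("invalid questionnaire ratings: " + "; ".join(problems))
    return scores
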