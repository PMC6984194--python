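"""Six-state ensemble controller for the robotic hand.

The hand cycles through six states — remaining opened, currently flexing,
just closed, remaining closed, currently extending, just opened — and the
streaming outputs of the three pairwise classifiers are gated by the current
state: only the open-vs-flexion classifier can start a flexion from the open
resting state, only the closed-vs-extension classifier an extension from the
closed resting state, and in the transient "just" states a movement reversal
additionally requires the flexion-vs-extension classifier to agree (both
thresholds ANDed).  Movement states last a fixed movement duration and are
uninterruptible; "just" states time out into the adjacent resting state.

All decisions happen on a fixed update grid (default 50 ms), operating on
the most recent 1.5 s of causally filtered EEG; elapsed times are measured
in whole ticks so traces are exactly reproducible.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, replace

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "HandState",
    "ControllerConfig",
    "ProbabilityStream",
    "ControllerTrace",
    "active_classifiers",
    "step",
    "run_controller",
    "run_online_pipeline",
    "adjust_threshold",
]


class HandState(enum.Enum):
    REMAINING_OPENED = "remaining_opened"
    CURRENTLY_FLEXING = "currently_flexing"
    JUST_CLOSED = "just_closed"
    REMAINING_CLOSED = "remaining_closed"
    CURRENTLY_EXTENDING = "currently_extending"
    JUST_OPENED = "just_opened"


_MOVEMENT_STATES = (HandState.CURRENTLY_FLEXING, HandState.CURRENTLY_EXTENDING)


@dataclass(frozen=True)
class ControllerConfig:
    """Thresholds and timing of the ensemble state machine."""

    theta_of: float = 0.7
    theta_ce: float = 0.7
    theta_ef: float = 0.7
    movement_duration: float = 2.0
    just_state_timeout: float = 2.0
    update_interval: float = 0.05
    window: float = 1.5

    def __post_init__(self):
        for name in ("theta_of", "theta_ce", "theta_ef"):
            th = getattr(self, name)
            if not 0.0 < th < 1.0:
                raise ValueError(f"{name} must be in the open interval (0, 1), got {th}")
        for name in ("movement_duration", "just_state_timeout", "update_interval", "window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ProbabilityStream:
    """Timestamped classifier probabilities on the controller update grid."""

    times: np.ndarray
    p_flexion_of: np.ndarray   # Y_OF: p(flexion vs. remaining open)
    p_extension_ce: np.ndarray  # Y_CE: p(extension vs. remaining closed)
    p_flexion_ef: np.ndarray   # Y_EF: p(flexion vs. extension)

    def __post_init__(self):
        arrays = [self.times, self.p_flexion_of, self.p_extension_ce, self.p_flexion_ef]
        lens = {len(a) for a in arrays}
        if len(lens) != 1:
            raise ValueError("all stream arrays must have equal length")
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("stream timestamps must be strictly increasing")

    def __len__(self):
        return len(self.times)


@dataclass
class ControllerTrace:
    """Audit record of a controller run."""

    times: np.ndarray
    states: list
    movements: list  # (time, "movement_flexion" | "movement_extension")
    stream: ProbabilityStream
    initial_state: HandState = HandState.REMAINING_OPENED

    def movement_times(self, kind=None):
        return np.array([t for t, lab in self.movements if kind is None or lab == kind])


def active_classifiers(state: HandState) -> frozenset:
    """Which classifiers the current hand state listens to."""
    return {
        HandState.REMAINING_OPENED: frozenset({"Y_OF"}),
        HandState.REMAINING_CLOSED: frozenset({"Y_CE"}),
        HandState.JUST_CLOSED: frozenset({"Y_CE", "Y_EF"}),
        HandState.JUST_OPENED: frozenset({"Y_OF", "Y_EF"}),
        HandState.CURRENTLY_FLEXING: frozenset(),
        HandState.CURRENTLY_EXTENDING: frozenset(),
    }[state]


def _check_prob(name, p):
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {p}")


def step(state: HandState, p_flexion_of: float, p_extension_ce: float,
         p_flexion_ef: float, elapsed: float, config: ControllerConfig):
    """One transition decision.

    ``p_flexion_ef`` is the flexion-vs-extension classifier's flexion
    probability; its extension probability is the complement.  Threshold
    comparisons are inclusive (a tie at exactly theta triggers), and in the
    "just" states a threshold crossing at the timeout tick wins over the
    timeout.  Returns ``(new_state, emitted_movement_or_None)``.
    """
    _check_prob("p_flexion_of", p_flexion_of)
    _check_prob("p_extension_ce", p_extension_ce)
    _check_prob("p_flexion_ef", p_flexion_ef)
    if elapsed < 0:
        raise ValueError("elapsed must be >= 0")
    cfg = config
    p_extension_ef = 1.0 - p_flexion_ef

    if state is HandState.REMAINING_OPENED:
        if p_flexion_of >= cfg.theta_of:
            return HandState.CURRENTLY_FLEXING, "movement_flexion"
    elif state is HandState.CURRENTLY_FLEXING:
        if elapsed >= cfg.movement_duration:
            return HandState.JUST_CLOSED, None
    elif state is HandState.JUST_CLOSED:
        if p_extension_ce >= cfg.theta_ce and p_extension_ef >= cfg.theta_ef:
            return HandState.CURRENTLY_EXTENDING, "movement_extension"
        if elapsed >= cfg.just_state_timeout:
            return HandState.REMAINING_CLOSED, None
    elif state is HandState.REMAINING_CLOSED:
        if p_extension_ce >= cfg.theta_ce:
            return HandState.CURRENTLY_EXTENDING, "movement_extension"
    elif state is HandState.CURRENTLY_EXTENDING:
        if elapsed >= cfg.movement_duration:
            return HandState.JUST_OPENED, None
    elif state is HandState.JUST_OPENED:
        if p_flexion_of >= cfg.theta_of and p_flexion_ef >= cfg.theta_ef:
            return HandState.CURRENTLY_FLEXING, "movement_flexion"
        if elapsed >= cfg.just_state_timeout:
            return HandState.REMAINING_OPENED, None
    else:
        raise ValueError(f"invalid state: {state!r}")
    return state, None


def run_controller(stream: ProbabilityStream, config: ControllerConfig = None,
                   initial_state: HandState = HandState.REMAINING_OPENED) -> ControllerTrace:
    """Fold :func:`step` over a probability stream.

    One transition decision per tick; elapsed time in a state is counted in
    whole ticks since entry.  Deterministic: identical streams and configs
    yield identical traces.
    """
    cfg = config or ControllerConfig()
    times = stream.times
    if len(times) > 1:
        dt = np.diff(times)
        if not np.allclose(dt, cfg.update_interval, rtol=1e-6, atol=1e-9):
            raise ValueError("stream must be sampled at the controller update interval")

    state = initial_state
    entered_tick = 0
    states, movements = [], []
    for i in range(len(times)):
        elapsed = (i - entered_tick) * cfg.update_interval
        new_state, event = step(
            state, stream.p_flexion_of[i], stream.p_extension_ce[i],
            stream.p_flexion_ef[i], elapsed, cfg,
        )
        if new_state is not state:
            entered_tick = i
        state = new_state
        states.append(state)
        if event is not None:
            movements.append((float(times[i]), event))
    return ControllerTrace(times=times.copy(), states=states, movements=movements,
                           stream=stream, initial_state=initial_state)


def extract_probability_stream(recording, bank, config: ControllerConfig = None) -> ProbabilityStream:
    """Causal decoding of a recording into the three probability streams.

    Every ``update_interval`` the most recent ``window`` of causally
    band-passed EEG is projected through each classifier's CSP filters,
    log-variance featurized and scored.  Implemented with sliding windows
    over the projected component time series, which is tick-for-tick
    identical to re-featurizing each window.
    """
    from .sigproc import bandpass

    cfg = config or ControllerConfig()
    w = int(round(cfg.window * recording.fs))
    hop = int(round(cfg.update_interval * recording.fs))
    if recording.n_samples < w:
        raise ValueError("recording shorter than one analysis window")

    filtered = bandpass(recording, mode="causal")
    ends = np.arange(w, recording.n_samples + 1, hop)
    times = ends / recording.fs

    probs = {}
    for name, clf in bank.classifiers.items():
        model = bank.csp_models[name]
        if getattr(model, "ch_names_", None) and list(recording.ch_names) != list(model.ch_names_):
            raise ValueError("recording channels do not match the training montage")
        W = model.filters_[:, model.selected_]
        comps = W.T @ filtered.data  # (n_components, n_samples)
        feats = np.empty((len(ends), W.shape[1]))
        for j in range(W.shape[1]):
            windows = np.lib.stride_tricks.sliding_window_view(comps[j], w)[ends - w]
            feats[:, j] = windows.var(axis=1)
        feats = np.log(np.maximum(feats, np.finfo(float).eps))
        probs[name] = clf.predict_proba_pos(feats)

    return ProbabilityStream(
        times=times,
        p_flexion_of=probs["Y_OF"],
        p_extension_ce=probs["Y_CE"],
        p_flexion_ef=probs["Y_EF"],
    )


def run_online_pipeline(recording, bank, config: ControllerConfig = None,
                        initial_state: HandState = HandState.REMAINING_OPENED) -> ControllerTrace:
    """Full online path: causal filtering, CSP features, state-gated
    classification and the state machine, on the 50 ms update grid."""
    cfg = config or ControllerConfig()
    stream = extract_probability_stream(recording, bank, cfg)
    return run_controller(stream, cfg, initial_state)


def adjust_threshold(config: ControllerConfig, classifier_id: str, new_theta: float,
                     audit_log: list = None, time: float = None) -> ControllerConfig:
    """Return a config with one classifier threshold changed (acquaintance-
    phase adjustment, e.g. 0.7 -> 0.8); the change is logged."""
    key = {"Y_OF": "theta_of", "Y_CE": "theta_ce", "Y_EF": "theta_ef"}.get(classifier_id)
    if key is None:
        raise ValueError(f"unknown classifier id: {classifier_id!r}")
    if not 0.0 < new_theta < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {new_theta}")
    old = getattr(config, key)
    entry = {"time": time, "classifier": classifier_id, "old": old, "new": new_theta}
    if audit_log is not None:
        audit_log.append(entry)
    logger.info("threshold adjustment: %s", entry)
    return replace(config, **{key: new_theta})
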