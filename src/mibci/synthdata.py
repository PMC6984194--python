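"""Synthetic sensorimotor-rhythm EEG with ground-truth event-related
desynchronization (ERD).

The generator emulates the data the decoding pipeline assumes: 24-channel EEG
at 500 Hz on a 10-20 montage subset, with band-limited (8-30 Hz) stochastic
oscillators projected through fixed per-class spatial topographies over
central channels, on top of 1/f background and white sensor noise.  Imagined
hand flexion and extension each suppress their own oscillator's amplitude by
sqrt(1 - d) from ERD onset to the end of the imagery period, so the injected
fractional band-power drop is exactly ``d`` — the ground truth every
downstream estimator is tested against.

Three scenario builders are provided: the fixed-structure training block
(~50 runs of rest / flexion / rest / extension), self-paced feedback tasks
driven by a simulated user (:class:`UserModel`), and scripted classifier
probability streams that let controller tests bypass EEG decoding entirely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .io import EventMarker, Recording
from .montage import MONTAGE_24

__all__ = [
    "SimConfig",
    "UserModel",
    "FeedbackScenario",
    "default_topographies",
    "generate_training_recording",
    "generate_feedback_scenario",
    "generate_probability_stream",
    "REST_DURATION",
    "LED_TO_MI",
    "MI_DURATION",
    "RUN_DURATION",
]

# Fixed training-block timing (seconds): each run is
# 5 s rest | LED | 0.3 s | 1.5 s flexion MI | 5 s rest | LED | 0.3 s | 1.5 s extension MI
REST_DURATION = 5.0
LED_TO_MI = 0.3
MI_DURATION = 1.5
RUN_DURATION = 2 * (REST_DURATION + LED_TO_MI + MI_DURATION)  # 13.6 s


def default_topographies(ch_names=None):
    """Per-class spatial weight vectors over the montage.

    Flexion and extension imagery are separated by a mediolateral weight
    shift (flexion weighted toward C3/CP1, extension toward C4/CP2) with a
    shared midline component — the simplest spatial structure that makes the
    two imagery classes CSP-discriminable from each other and from rest.
    """
    ch_names = list(ch_names) if ch_names is not None else list(MONTAGE_24)
    weights = {
        "flexion": {"C3": 1.0, "CP1": 0.6, "FC1": 0.3},
        "extension": {"C4": 1.0, "CP2": 0.6, "FC2": 0.3},
    }
    topo = {}
    for cls, wmap in weights.items():
        v = np.zeros(len(ch_names))
        for ch, w in wmap.items():
            if ch in ch_names:
                v[ch_names.index(ch)] = w
        topo[cls] = v
    return topo


@dataclass
class SimConfig:
    """Configuration of the synthetic EEG generator.

    Amplitudes are in arbitrary microvolt-like units; the oscillators
    dominate the 10-25 Hz band on their carrier channels so that injected
    ERD depths are recoverable from band power.
    """

    n_channels: int = 24
    fs: float = 500.0
    n_runs: int = 50
    tail_duration: float = 2.0  # trailing rest so analysis windows around the last trial fit
    erd_depth: float = 0.3
    erd_latency: float = 0.51
    osc_band: tuple[float, float] = (8.0, 30.0)
    osc_comb: dict = field(default_factory=lambda: {
        "flexion": (11.0, 15.0, 19.0, 23.0),
        "extension": (13.0, 17.0, 21.0),
    })
    amp_jitter: float = 0.05
    osc_amplitude: float = 5.0
    background_scale: float = 2.0
    white_noise_scale: float = 0.5
    topographies: dict = field(default_factory=dict)
    ch_names: list[str] = field(default_factory=lambda: list(MONTAGE_24))
    seed: int = 0

    def __post_init__(self):
        if self.n_channels <= 0:
            raise ValueError("invalid SimConfig.n_channels: must be positive")
        if len(self.ch_names) != self.n_channels:
            if self.n_channels == 24 and self.ch_names == list(MONTAGE_24):
                raise ValueError("invalid SimConfig.n_channels: does not match ch_names")
            raise ValueError("invalid SimConfig.ch_names: length must equal n_channels")
        if self.fs <= 2 * 50.0:
            raise ValueError("invalid SimConfig.fs: must exceed twice the 50 Hz analysis ceiling")
        if self.n_runs <= 0:
            raise ValueError("invalid SimConfig.n_runs: must be positive")
        if self.tail_duration < 0:
            raise ValueError("invalid SimConfig.tail_duration: must be >= 0")
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValueError("invalid SimConfig.erd_depth: must be in [0, 1]")
        if self.erd_latency < 0:
            raise ValueError("invalid SimConfig.erd_latency: must be >= 0")
        if not 0 < self.osc_band[0] < self.osc_band[1] < self.fs / 2:
            raise ValueError("invalid SimConfig.osc_band: must satisfy 0 < low < high < fs/2")
        for cls, comb in self.osc_comb.items():
            if not all(self.osc_band[0] <= f <= self.osc_band[1] for f in comb):
                raise ValueError(f"invalid SimConfig.osc_comb[{cls!r}]: tones must lie inside osc_band")
        if self.amp_jitter < 0:
            raise ValueError("invalid SimConfig.amp_jitter: must be >= 0")
        for name in ("osc_amplitude", "background_scale", "white_noise_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"invalid SimConfig.{name}: must be >= 0")
        if not self.topographies:
            self.topographies = default_topographies(self.ch_names)
        for cls, v in self.topographies.items():
            v = np.asarray(v, dtype=float)
            if v.shape != (self.n_channels,):
                raise ValueError(f"invalid SimConfig.topographies[{cls!r}]: wrong length")
            self.topographies[cls] = v

    @classmethod
    def for_group(cls, group: str, **overrides) -> "SimConfig":
        """Group presets: ERD onset ~0.63 s (stroke) vs ~0.51 s (control).

        The latency defaults mirror the group means observed with this
        paradigm and are simulation conditions, not ground truth about
        stroke neurophysiology.
        """
        if group == "stroke":
            defaults = dict(erd_latency=0.63)
        elif group == "control":
            defaults = dict(erd_latency=0.51)
        else:
            raise ValueError(f"unknown group: {group!r}")
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class UserModel:
    """Simulated participant in the self-paced feedback block."""

    reaction_delay: float = 0.5
    compliance: float = 1.0
    spontaneous_mi_rate: float = 0.5  # uncommanded MI bouts per minute at rest

    def __post_init__(self):
        if self.reaction_delay < 0:
            raise ValueError("invalid UserModel.reaction_delay: must be >= 0")
        if not 0.0 <= self.compliance <= 1.0:
            raise ValueError("invalid UserModel.compliance: must be in [0, 1]")
        if self.spontaneous_mi_rate < 0:
            raise ValueError("invalid UserModel.spontaneous_mi_rate: must be >= 0")


@dataclass
class FeedbackScenario:
    """A simulated feedback task: EEG + markers + latent intention trace.

    ``intention`` codes the user's mental state per sample
    (0 rest, 1 flexion MI, 2 extension MI) and serves as the ground-truth
    oracle for evaluation metrics.
    """

    recording: Recording
    events: list
    intention: np.ndarray
    task: str


# ---------------------------------------------------------------------------
# low-level signal building blocks


def _smr_oscillator(rng, n, fs, comb, amp_jitter=0.05, freq_wander=0.25, tau=2.0):
    """Unit-variance sensorimotor oscillator with a stable envelope.

    A comb of constant-amplitude tones (default 11/15/19/23 Hz) whose
    instantaneous frequencies wander slightly (Ornstein-Uhlenbeck with
    relaxation ``tau`` seconds and stationary spread ``freq_wander`` Hz),
    with a common slow multiplicative amplitude jitter.  The comb spreads
    power across the whole 10-25 Hz analysis band while keeping the
    short-time band power nearly deterministic, so an injected fractional
    ERD is exact at the single-trial level; the burstier amplitude dynamics
    of real SMR can be emulated by raising ``amp_jitter``.
    """
    alpha = math.exp(-1.0 / (tau * fs))
    x = np.zeros(n)
    for f0 in comb:
        if freq_wander > 0:
            eps = rng.standard_normal(n) * (freq_wander * math.sqrt(1.0 - alpha ** 2))
            freq = f0 + np.clip(signal.lfilter([1.0], [1.0, -alpha], eps),
                                -3 * freq_wander, 3 * freq_wander)
        else:
            freq = np.full(n, float(f0))
        phase = 2.0 * np.pi * np.cumsum(freq) / fs + rng.uniform(0, 2 * np.pi)
        x += np.cos(phase)

    if amp_jitter > 0:
        sos = signal.butter(2, 1.0, btype="lowpass", fs=fs, output="sos")
        slow = signal.sosfiltfilt(sos, rng.standard_normal(n))
        sd_slow = slow.std()
        env = 1.0 + (amp_jitter * slow / sd_slow if sd_slow > 0 else 0.0)
        x *= np.maximum(env, 0.1)
    sd_x = x.std()
    return x / sd_x if sd_x > 0 else x


def _one_over_f_noise(rng, n, fs):
    """Unit-variance pink-ish (1/f amplitude) background noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = 1.0 / np.maximum(freqs[nz], 0.5)
    x = np.fft.irfft(spec * shaping, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _background(rng, cfg, n):
    bg = np.empty((cfg.n_channels, n))
    for c in range(cfg.n_channels):
        bg[c] = cfg.background_scale * _one_over_f_noise(rng, n, cfg.fs)
        bg[c] += cfg.white_noise_scale * rng.standard_normal(n)
    return bg


def _synthesize(rng, cfg, envelopes, n):
    """Project per-class enveloped oscillators through their topographies."""
    data = _background(rng, cfg, n)
    for cls, topo in cfg.topographies.items():
        src = cfg.osc_amplitude * _smr_oscillator(
            rng, n, cfg.fs, cfg.osc_comb[cls], amp_jitter=cfg.amp_jitter)
        src = src * envelopes[cls]
        data += np.outer(topo, src)
    return data


def _apply_erd(envelope, cfg, onset_s, duration_s=MI_DURATION, fs=None):
    """Suppress the oscillator by sqrt(1-d) from onset+latency to offset."""
    fs = fs or cfg.fs
    start = int(round((onset_s + cfg.erd_latency) * fs))
    stop = int(round((onset_s + duration_s) * fs))
    if start < stop:
        envelope[start:stop] = math.sqrt(1.0 - cfg.erd_depth)


# ---------------------------------------------------------------------------
# training block


def generate_training_recording(config: SimConfig):
    """Simulate the fixed-structure training block.

    Per run: 5 s rest, LED, 1.5 s flexion imagery, 5 s rest, LED, 1.5 s
    extension imagery.  Class-specific ERD (band-power drop ``erd_depth``
    starting ``erd_latency`` after imagery onset) is injected on the class
    topography.  Returns ``(recording, events)`` with a complete, ordered
    marker list whose times are sample-aligned.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = int(round((cfg.n_runs * RUN_DURATION + cfg.tail_duration) * cfg.fs))

    events = []
    envelopes = {cls: np.ones(n) for cls in cfg.topographies}

    def snap(t):  # sample-aligned event time
        return round(t * cfg.fs) / cfg.fs

    for run in range(cfg.n_runs):
        t0 = run * RUN_DURATION
        for half, cls in ((0.0, "flexion"), (REST_DURATION + LED_TO_MI + MI_DURATION, "extension")):
            rest_t = t0 + half
            led_t = rest_t + REST_DURATION
            mi_t = led_t + LED_TO_MI
            events.append(EventMarker(snap(rest_t), "rest_onset"))
            events.append(EventMarker(snap(led_t), "led_onset"))
            events.append(EventMarker(snap(mi_t), f"{cls}_onset"))
            _apply_erd(envelopes[cls], cfg, snap(mi_t))

    data = _synthesize(rng, cfg, envelopes, n)
    recording = Recording(data=data, fs=cfg.fs, ch_names=list(cfg.ch_names))
    return recording, sorted(events)


# ---------------------------------------------------------------------------
# feedback block

#: Default experimenter command schedule for the command-following tasks:
#: a command every 20 s, alternating close/open with two grasps given while
#: the hand is closed (grasp = extension then flexion).
DEFAULT_COMMANDS = [
    (10.0, "command_close"),
    (30.0, "command_open"),
    (50.0, "command_close"),
    (70.0, "command_grasp"),
    (90.0, "command_open"),
    (110.0, "command_close"),
    (130.0, "command_open"),
    (150.0, "command_close"),
    (170.0, "command_grasp"),
    (190.0, "command_open"),
    (210.0, "command_close"),
    (230.0, "command_open"),
]

_PHASE_DURATION = 30.0
_N_PHASES = 8
_BOUT_GAP = 0.5


def _command_required_classes(label):
    # Hand opening is an extension movement, closing a flexion; grasp is
    # open-then-close, i.e. extension followed by flexion.
    return {
        "command_close": ["flexion"],
        "command_open": ["extension"],
        "command_grasp": ["extension", "flexion"],
    }[label]


def generate_feedback_scenario(config: SimConfig, user: UserModel, task: str,
                               commands=None, duration: float | None = None,
                               n_attempts: int = 3) -> FeedbackScenario:
    """Simulate a self-paced feedback task.

    ``task`` is one of ``rest_move`` (8 alternating 30 s move/rest phases),
    ``follow_commands`` or ``announce_commands`` (timestamped open/close/
    grasp commands; the two differ only in who issues the commands, so they
    share a generative model).  The latent mental-state trace follows the
    user model: after each command the user reacts with ``reaction_delay``
    and, with probability ``compliance``, performs up to ``n_attempts``
    imagery bouts of the required class(es); spontaneous uncommanded bouts
    occur as a Poisson process at ``spontaneous_mi_rate`` per minute.
    """
    cfg = config
    if task not in ("rest_move", "follow_commands", "announce_commands"):
        raise ValueError(f"unknown task: {task!r}")
    rng = np.random.default_rng(cfg.seed)

    if task == "rest_move":
        duration = _N_PHASES * _PHASE_DURATION if duration is None else duration
    else:
        commands = list(DEFAULT_COMMANDS) if commands is None else list(commands)
        duration = (commands[-1][0] + 10.0) if duration is None else duration
        if commands and commands[-1][0] >= duration:
            raise ValueError("schedule error: command schedule extends past recording end")

    n = int(round(duration * cfg.fs))
    events: list[EventMarker] = []
    bouts: list[tuple[float, str]] = []  # (onset seconds, class)

    def add_spontaneous(t_start, t_stop):
        rate = user.spontaneous_mi_rate / 60.0
        t = t_start
        while rate > 0:
            t += rng.exponential(1.0 / rate)
            if t + MI_DURATION > t_stop:
                break
            bouts.append((t, "flexion" if rng.random() < 0.5 else "extension"))

    if task == "rest_move":
        for k in range(_N_PHASES):
            t0 = k * _PHASE_DURATION
            label = "phase_move" if k % 2 == 0 else "phase_rest"
            events.append(EventMarker(t0, label))
            if label == "phase_move":
                # deliberate bouts, alternating flexion/extension to toggle the hand
                t = t0 + user.reaction_delay
                i = 0
                while t + MI_DURATION <= t0 + _PHASE_DURATION:
                    if rng.random() < user.compliance:
                        bouts.append((t, "flexion" if i % 2 == 0 else "extension"))
                    i += 1
                    t += MI_DURATION + 4.5  # one attempt roughly every 6 s
                add_spontaneous(t0, t0 + _PHASE_DURATION)  # rate-driven extras
            else:
                add_spontaneous(t0, t0 + _PHASE_DURATION)
    else:
        cmd_times = [t for t, _ in commands] + [duration]
        for (t_cmd, label), t_next in zip(commands, cmd_times[1:]):
            events.append(EventMarker(t_cmd, label))
            if rng.random() < user.compliance:
                t = t_cmd + user.reaction_delay
                for cls in _command_required_classes(label):
                    for _ in range(n_attempts):
                        if t + MI_DURATION > t_next:
                            break
                        bouts.append((t, cls))
                        t += MI_DURATION + _BOUT_GAP
        add_spontaneous(0.0, duration)

    # latent intention trace + ERD envelopes
    intention = np.zeros(n, dtype=np.int8)
    envelopes = {cls: np.ones(n) for cls in cfg.topographies}
    code = {"flexion": 1, "extension": 2}
    for t, cls in sorted(bouts):
        s0 = int(round(t * cfg.fs))
        s1 = min(int(round((t + MI_DURATION) * cfg.fs)), n)
        intention[s0:s1] = code[cls]
        _apply_erd(envelopes[cls], cfg, t)

    data = _synthesize(rng, cfg, envelopes, n)
    recording = Recording(data=data, fs=cfg.fs, ch_names=list(cfg.ch_names))
    return FeedbackScenario(recording, sorted(events), intention, task)


# ---------------------------------------------------------------------------
# scripted probability streams


def generate_probability_stream(script, update_interval: float = 0.05):
    """Piecewise-constant classifier probability stream at the update rate.

    ``script`` is a list of ``(duration_s, p_EF, p_OF, p_CE)`` segments,
    where p_EF is the flexion-vs-extension classifier's flexion probability,
    p_OF the open-vs-flexion classifier's flexion probability and p_CE the
    closed-vs-extension classifier's extension probability.  Returns a
    :class:`mibci.controller.ProbabilityStream` with one tick per
    ``update_interval`` (default 50 ms).
    """
    from .controller import ProbabilityStream

    if update_interval <= 0:
        raise ValueError("update_interval must be positive")
    p_ef, p_of, p_ce = [], [], []
    for seg in script:
        dur, ef, of, ce = seg
        if dur <= 0:
            raise ValueError("script segment durations must be positive")
        for name, p in (("p_EF", ef), ("p_OF", of), ("p_CE", ce)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} outside [0, 1]: {p}")
        n_ticks = int(round(dur / update_interval))
        p_ef += [ef] * n_ticks
        p_of += [of] * n_ticks
        p_ce += [ce] * n_ticks
    n = len(p_ef)
    times = (np.arange(n) + 1) * update_interval
    return ProbabilityStream(
        times=times,
        p_flexion_of=np.asarray(p_of, dtype=float),
        p_extension_ce=np.asarray(p_ce, dtype=float),
        p_flexion_ef=np.asarray(p_ef, dtype=float),
    )
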