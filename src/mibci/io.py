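"""Core containers and file I/O.

A :class:`Recording` is continuous multichannel EEG (channels x samples) with
a sampling rate and channel labels; :class:`EventMarker` is a timestamped
label.  Events and command logs round-trip through tab-separated files and
JSON; recordings interoperate with MNE (EDF reading, FIF persistence).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "EventMarker",
    "EVENT_LABELS",
    "read_events_tsv",
    "write_events_tsv",
    "read_events_json",
    "write_events_json",
    "read_edf",
    "recording_from_mne",
]

#: Permitted event labels for schedules, command logs and controller output.
EVENT_LABELS = frozenset(
    {
        "rest_onset",
        "led_onset",
        "flexion_onset",
        "extension_onset",
        "command_open",
        "command_close",
        "command_grasp",
        "movement_flexion",
        "movement_extension",
        "phase_move",
        "phase_rest",
    }
)


@dataclass(frozen=True, order=True)
class EventMarker:
    """A timestamped event. ``time`` is seconds from recording start."""

    time: float
    label: str

    def __post_init__(self):
        if self.label not in EVENT_LABELS:
            raise ValueError(f"unknown event label: {self.label!r}")
        if not np.isfinite(self.time) or self.time < 0:
            raise ValueError(f"event time must be finite and >= 0, got {self.time}")


@dataclass
class Recording:
    """Continuous EEG: ``data`` has shape (n_channels, n_samples)."""

    data: np.ndarray
    fs: float
    ch_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("Recording.data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.ch_names and len(self.ch_names) != self.data.shape[0]:
            raise ValueError("ch_names length must match channel count")
        if not self.ch_names:
            self.ch_names = [f"ch{i}" for i in range(self.data.shape[0])]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray) -> "Recording":
        return replace(self, data=data, ch_names=list(self.ch_names))

    def to_mne(self):
        """Convert to an :class:`mne.io.RawArray` (data assumed in microvolts)."""
        import mne

        info = mne.create_info(list(self.ch_names), self.fs, ch_types="eeg")
        return mne.io.RawArray(self.data * 1e-6, info, verbose="error")

    def save_fif(self, path) -> None:
        self.to_mne().save(path, overwrite=True, verbose="error")


def recording_from_mne(raw) -> Recording:
    """Build a :class:`Recording` (microvolts) from an MNE Raw object."""
    return Recording(
        data=raw.get_data() * 1e6,
        fs=float(raw.info["sfreq"]),
        ch_names=list(raw.ch_names),
    )


def read_edf(path) -> Recording:
    """Read an EDF(+) recording via MNE."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return recording_from_mne(raw)


def write_events_tsv(events, path) -> None:
    """Write events as a TSV with columns ``time_s`` and ``label``."""
    df = pd.DataFrame(
        {"time_s": [e.time for e in events], "label": [e.label for e in events]}
    )
    df.to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> list[EventMarker]:
    df = pd.read_csv(path, sep="\t")
    return [EventMarker(float(t), str(l)) for t, l in zip(df["time_s"], df["label"])]


def write_events_json(events, path) -> None:
    with open(path, "w") as fh:
        json.dump([{"time_s": e.time, "label": e.label} for e in events], fh, indent=1)


def read_events_json(path) -> list[EventMarker]:
    with open(path) as fh:
        return [EventMarker(float(d["time_s"]), str(d["label"])) for d in json.load(fh)]
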