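"""Electrode montage of the 24-channel mobile EEG cap (10-20 subset)."""

#: Channel order of the recording cap (AFz ground, FCz reference, not recorded).
MONTAGE_24 = [
    "FP1", "FP2", "F7", "F8", "FZ", "FC1", "FC2", "T7", "C3", "CZ", "C4",
    "T8", "TP9", "CP5", "CP1", "CPz", "CP2", "CP6", "TP10", "P3", "PZ",
    "P4", "O1", "O2",
]

#: Channels over sensorimotor cortex used by the physiological-plausibility
#: proxies (CSP component selection and the filter-quality rubric).
SENSORIMOTOR_CHANNELS = frozenset(
    {"C3", "CZ", "C4", "FC1", "FC2", "CP1", "CPz", "CP2", "CP5", "CP6"}
)


def channel_indices(ch_names, subset):
    """Indices of ``subset`` channels within ``ch_names`` (order preserved)."""
    subset = set(subset)
    return [i for i, ch in enumerate(ch_names) if ch in subset]
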