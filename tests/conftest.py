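"""Shared fixtures: all test data is generated programmatically."""

import logging
import warnings

import numpy as np
import pytest

from mibci import decode
from mibci.sigproc import bandpass, epoch_training, reject_artifacts
from mibci.synthdata import SimConfig, generate_training_recording

logging.getLogger("mibci").setLevel(logging.ERROR)
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def training50():
    """A full-length (50-run) training block with a 40% ERD at 0.4 s."""
    cfg = SimConfig(erd_depth=0.4, erd_latency=0.4, n_runs=50, seed=7)
    recording, events = generate_training_recording(cfg)
    return cfg, recording, events


@pytest.fixture(scope="session")
def strong_training():
    """A compact block with a deep, early ERD (clearly decodable classes)."""
    cfg = SimConfig(erd_depth=0.7, erd_latency=0.1, n_runs=20, seed=42)
    recording, events = generate_training_recording(cfg)
    return cfg, recording, events


@pytest.fixture(scope="session")
def strong_epochs(strong_training):
    _, recording, events = strong_training
    epochs, _ = reject_artifacts(epoch_training(bandpass(recording), events))
    return epochs


@pytest.fixture(scope="session")
def strong_bank(strong_epochs):
    return decode.train_bank(strong_epochs, shrinkage=0.2)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
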