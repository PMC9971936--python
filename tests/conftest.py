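"""Shared fixtures: CPU-sized study configurations and small datasets."""

import numpy as np
import pytest

from rpaf.recurrence import RpConfig
from rpaf.signal_prep import PrepConfig
from rpaf.synthetic_ecg import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def synth_cfg():
    """Default-statistics generator at a CPU-friendly sampling rate."""
    return SynthConfig(fs=100.0, duration=10.0)


@pytest.fixture(scope="session")
def prep_cfg():
    return PrepConfig(target_fs=100.0, segment_len=10.0, seed=3)


@pytest.fixture(scope="session")
def rp_small_cfg():
    """RP conversion sized for the 32x32 test profile of the classifier."""
    return RpConfig(target_points=300, size=32)


@pytest.fixture(scope="session")
def small_dataset(synth_cfg):
    """20 AF + 20 NSR records, deterministic."""
    return generate_dataset(synth_cfg, 20, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
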