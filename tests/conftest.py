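import logging

import numpy as np
import pytest

from comica.evoked_data import EpochSet, EvokedRecording, SensorArray
from comica.simulator import SimConfig, SourceSpec, build_synthetic_head

logging.getLogger("comica").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def sensors8():
    return SensorArray.generic(8)


@pytest.fixture
def small_config():
    """Fast simulation conditions for unit tests (full-size study uses defaults)."""
    return SimConfig(n_trials=20, n_sens=32, n_src=16, seed=5)


@pytest.fixture
def small_head(small_config):
    return build_synthetic_head(small_config.n_sens, small_config.n_src,
                                small_config.seed)


@pytest.fixture
def two_recordings(rng, sensors8):
    """Two full-rank 8-channel recordings sharing a strong source."""
    t = np.linspace(0, 1, 120, endpoint=False)
    shared = np.sin(2 * np.pi * 3 * t) * np.exp(-((t - 0.4) ** 2) / 0.02)
    pattern = rng.normal(size=8)
    recs = []
    for k in range(2):
        unique = rng.normal(size=(8, t.size)) * 0.05
        data = np.outer(pattern, shared) + unique
        recs.append(EvokedRecording(data, sfreq=120.0, tmin=0.0,
                                    sensors=sensors8))
    return recs


def make_epochs(data, sfreq=100.0, tmin=-0.1):
    data = np.asarray(data, dtype=float)
    return EpochSet(data, sfreq, tmin, SensorArray.generic(data.shape[1]))
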