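import numpy as np
import pytest

from mieeg import synthgen
from mieeg.core import EpochSet


@pytest.fixture(scope="session")
def small_config() -> synthgen.GeneratorConfig:
    """Small 8-channel session config used by fast unit tests."""
    return synthgen.GeneratorConfig(
        preset="custom", fs=100.0, n_channels=8, n_trials_per_class=20,
        erd_depth=0.4, ers_gain=0.1, snr_db=10.0, seed=7,
    )


@pytest.fixture(scope="session")
def small_session(small_config) -> EpochSet:
    return synthgen.generate_session(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_epochs(n_trials=24, n_channels=4, n_samples=200, fs=100.0, seed=0,
                cue_index=None) -> EpochSet:
    """Plain white-noise EpochSet with balanced labels (no class structure)."""
    if cue_index is None:
        cue_index = n_samples // 2
    g = np.random.default_rng(seed)
    labels = np.array(["left", "right"] * (n_trials // 2), dtype=object)
    names = ["C3", "C4", "Cz", "Pz", "F3", "F4", "P3", "P4"][:n_channels]
    return EpochSet(
        data=g.normal(size=(n_trials, n_channels, n_samples)),
        labels=labels[:n_trials],
        fs=fs,
        channel_names=names,
        cue_index=cue_index,
    )
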