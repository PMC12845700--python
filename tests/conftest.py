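import numpy as np
import pytest

from frozenemg import SynthConfig
from frozenemg.pipeline import ExperimentConfig
from frozenemg.preprocess import GlrConfig
from frozenemg.vmd import VmdConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_synth():
    """A quick-to-generate recording configuration for unit tests."""
    return SynthConfig(n_channels=4, n_classes=3, n_repetitions=4,
                       motion_duration=(300, 40), rest_duration=(120, 20),
                       seed=7)


@pytest.fixture
def small_experiment(small_synth):
    """A scaled-down pipeline configuration (short windows, thin bank)."""
    return ExperimentConfig(
        synth=small_synth,
        window_len=360,
        n_filters=32,
        seeds=(42,),
        test_repetitions=(2, 4),
        cv_folds=2,
    )


@pytest.fixture
def two_tone():
    """0.3 Hz + 5 Hz unit tones at fs=100 over 1100 samples."""
    t = np.arange(1100) / 100.0
    return np.sin(2 * np.pi * 0.3 * t) + np.sin(2 * np.pi * 5.0 * t)
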