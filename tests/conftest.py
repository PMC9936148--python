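import numpy as np
import pytest

from mibrainnet import EpochSet, PipelineConfig, generate, preset


@pytest.fixture(scope="session")
def twoclass_epochs():
    """Two classes, 10:1 variance contrast on channel 1 (index 0)."""
    epochs, truth = generate(preset("twoclass", seed=0, n_trials_per_class=20))
    return epochs, truth


@pytest.fixture(scope="session")
def easy4_small():
    """Scaled-down easy4 preset (15 trials/class) for unit tests."""
    epochs, truth = generate(preset("easy4", seed=0, n_trials_per_class=15))
    return epochs, truth


@pytest.fixture()
def tiny_epochs():
    rng = np.random.default_rng(11)
    data = rng.standard_normal((12, 4, 256))
    labels = np.r_[np.ones(6, int), 2 * np.ones(6, int)]
    return EpochSet(data, labels, fs=128.0)


@pytest.fixture()
def config():
    return PipelineConfig(seed=0)
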