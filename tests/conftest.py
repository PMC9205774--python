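import numpy as np
import pytest

from swarmpath.classifier import Hyperparams
from swarmpath.synthetic import SyntheticConfig


@pytest.fixture
def tiny_config() -> SyntheticConfig:
    """Three small cohorts in feature mode, low-dimensional for speed."""
    return SyntheticConfig(
        patients_per_cohort=(12, 30, 18),
        tiles_per_patient=8,
        feature_dim=24,
        seed=11,
    )


@pytest.fixture
def image_config() -> SyntheticConfig:
    return SyntheticConfig(
        n_cohorts=2,
        patients_per_cohort=(3, 4),
        tiles_per_patient=10,
        image_size=32,
        blank_fraction=0.2,
        mode="images",
        seed=5,
    )


@pytest.fixture
def fast_hp() -> Hyperparams:
    return Hyperparams(batch_size=16, learning_rate=0.05)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
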