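import numpy as np
import pytest

from microfusion.synth import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """A compact dataset: 3 subjects x 4 trials of 10 s."""
    return GeneratorConfig(n_subjects=3, trials_per_subject=4, trial_seconds=10.0, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
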