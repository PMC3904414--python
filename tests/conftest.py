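import numpy as np
import pytest
from hypothesis import settings

from hiecod.config import GeneratorConfig

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """Three-subject configuration for pipeline-level tests."""
    return GeneratorConfig(n_subjects=3, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
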