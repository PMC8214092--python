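import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import modbit as mb

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


TINY_CFG = mb.CorpusConfig(n_image_classes=2, n_sound_classes=2,
                           samples_per_class=10, seed=7)


@pytest.fixture(scope="session")
def tiny_cfg() -> mb.CorpusConfig:
    return TINY_CFG


@pytest.fixture(scope="session")
def tiny_entity() -> mb.BimodalDataset:
    return mb.assemble_entity(TINY_CFG)


@pytest.fixture(scope="session")
def tiny_concept() -> mb.BimodalDataset:
    return mb.assemble_concept(TINY_CFG)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
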