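import numpy as np
import pytest

from ebpb.config import ModelConfig, default_config
from ebpb.connectome import Connectome, build_connectome


@pytest.fixture(scope="session")
def config() -> ModelConfig:
    return default_config()


@pytest.fixture(scope="session")
def connectome(config) -> Connectome:
    return build_connectome(config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
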