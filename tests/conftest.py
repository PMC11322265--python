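import numpy as np
import pytest

from deastrain import (
    DeviceConfig,
    SamplingScheme,
    VoltageStrainCurve,
    build_dataset,
)


@pytest.fixture(scope="session")
def config() -> DeviceConfig:
    return DeviceConfig()

@pytest.fixture(scope="session")
def curve() -> VoltageStrainCurve:
    return VoltageStrainCurve()


@pytest.fixture(scope="session")
def small_dataset(config, curve):
    """300/40 uniform-strain dataset for unit-level model tests."""
    return build_dataset(300, 40, SamplingScheme(seed=7), config, curve)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
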