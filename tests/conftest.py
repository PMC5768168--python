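import numpy as np
import pytest

from cpditools import Environment, ReceiverSpec

# parameters shared by the deep-water scenarios: 300 m water column,
# 1,530 m/s sound speed, 260 ms blanking, AMDR 843 m
SOUND_SPEED = 1530.0
BLANKING = 0.260


@pytest.fixture
def deep_env() -> Environment:
    return Environment(water_depth=300.0, sound_speed=SOUND_SPEED)


@pytest.fixture
def deep_spec() -> ReceiverSpec:
    return ReceiverSpec(amdr=843.0, blanking_interval=BLANKING)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20140607)
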