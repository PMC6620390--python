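import warnings

import numpy as np
import pytest

from sasmorph.pipeline import analyze_volume
from sasmorph.synthetic import ScenarioConfig, generate_scene

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_config() -> ScenarioConfig:
    """One modest stack: ~13.4 um^3, ~50 synapses."""
    return ScenarioConfig(
        volume_shape=(448, 448, 112), n_dendrites=10,
        synapse_density=4.0, seed=7)


@pytest.fixture(scope="session")
def small_scene(small_config):
    return generate_scene(small_config)


@pytest.fixture(scope="session")
def small_records(small_scene):
    vol, _ = small_scene
    return analyze_volume(vol)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260919)
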