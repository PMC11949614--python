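import numpy as np
import pytest

from oscillome import SynthConfig, synth_connectome


@pytest.fixture(scope="session")
def small_sc():
    """20-node bilaterally mirrored synthetic connectome."""
    return synth_connectome(
        SynthConfig(regions_per_hemisphere=10, dropout_range=(12, 16), seed=42)
    )


@pytest.fixture(scope="session")
def medium_sc():
    """60-node synthetic connectome for dynamics and recovery tests."""
    return synth_connectome(
        SynthConfig(regions_per_hemisphere=30, dropout_range=(40, 52), seed=7)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
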