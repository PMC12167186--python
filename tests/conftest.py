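import numpy as np
import pytest

from mapquant import QCConfig
from mapquant.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def clean_exam():
    """Artifact-free default phantom shared across read-only tests."""
    return generate_phantom(PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def textured_exam():
    """Phantom with the shared anatomical modulation NCC needs."""
    return generate_phantom(PhantomSpec(seed=12, texture_amp=0.05))


@pytest.fixture()
def optimized_config():
    return QCConfig.optimized()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
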