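import numpy as np
import pytest

from divlab.filament import FilamentEnv, FilamentGenotype


@pytest.fixture
def small_env() -> FilamentEnv:
    """A short filament in the essential-cooperation, local-diffusion regime."""
    return FilamentEnv(L=30, phi=0.0, eta=0.1)


@pytest.fixture
def random_genotype() -> FilamentGenotype:
    """Random specialisation at a moderate helper probability."""
    return FilamentGenotype(q=0.33)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
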