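import numpy as np
import pytest

from pdpmanifold import GeometrySpec, default_panel, generate_imaging_dataset


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def small_dataset(panel):
    """A small synthetic activity dataset shared by read-only tests."""
    spec = GeometrySpec(n_neurons=150, duration=6.0, onset=1.0, n_trials=3)
    return generate_imaging_dataset(spec, panel, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
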