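import numpy as np
import pytest

from weedphenom import (
    DegradationSpec,
    generate_dicot,
    generate_monocot,
    sample_point_cloud,
)


@pytest.fixture(scope="session")
def dicot():
    return generate_dicot(12.0, n_leaves=6, seed=7)


@pytest.fixture(scope="session")
def small_dicot():
    return generate_dicot(7.25, n_leaves=4, seed=1)


@pytest.fixture(scope="session")
def monocot():
    return generate_monocot(20.0, n_leaves=5, seed=3)


@pytest.fixture(scope="session")
def clean_dicot_cloud(dicot):
    """Noise-free dense sampling of the dicot surface."""
    return sample_point_cloud(
        dicot, DegradationSpec(point_density=60.0, seed=11)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
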