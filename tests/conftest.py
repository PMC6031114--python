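import numpy as np
import pytest

import ramanmix as rm


@pytest.fixture(scope="session")
def axis():
    """Default fingerprint-region axis, 300-1800 cm^-1 step 4."""
    return rm.regular_axis()


@pytest.fixture(scope="session")
def library(axis):
    return rm.builtin_library(axis)


@pytest.fixture(scope="session")
def simplex_scene():
    """Noiseless 3-component simplex scene with planted pure pixels."""
    return rm.make_scene("simplex", (8, 10), k=3, seed=11)


@pytest.fixture(scope="session")
def spruce_scene():
    """Noiseless spruce scene, small grid for unit tests."""
    return rm.make_scene("spruce", (24, 24), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
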