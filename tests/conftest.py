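import numpy as np
import pytest

from nirsdot.forward import default_optical_properties, make_slab_phantom, standard_layout


@pytest.fixture(scope="session")
def head():
    return make_slab_phantom((12, 12, 10), 2.0, (4.0, 2.0, 2.0, 4.0, None))


@pytest.fixture(scope="session")
def layout(head):
    return standard_layout(head)


@pytest.fixture(scope="session")
def props690():
    return default_optical_properties(690)


@pytest.fixture(scope="session")
def props830():
    return default_optical_properties(830)


@pytest.fixture(scope="session")
def toy_scene():
    from nirsdot.harness import build_toy_scene

    return build_toy_scene()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
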