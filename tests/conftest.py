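import numpy as np
import pytest

import genpol as g


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_scattering(rng, shape=(8, 8), reciprocal=True):
    def c(scale=1.0):
        return scale * (rng.standard_normal(shape)
                        + 1j * rng.standard_normal(shape))
    hv = c(0.5)
    return g.ScatteringImage(c(), hv, hv.copy() if reciprocal else c(0.5), c())


@pytest.fixture()
def random_image(rng):
    return random_scattering(rng)


@pytest.fixture(scope="session")
def default_scene_stack():
    """Six-date default synthetic scene, shared across tests (read-only)."""
    layout = g.default_layout()
    schedule = g.default_phenology_schedule()
    imgs, mask = g.build_stack(layout, schedule, seed=7)
    return imgs, mask, layout, schedule
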