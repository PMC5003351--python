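import numpy as np
import pytest
from hypothesis import settings

import microwell_mc as mw

# Deterministic hypothesis runs across environments.
settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def well():
    """The full-scale 60 x 60 x 80 microwell domain."""
    return mw.build_well_domain()


@pytest.fixture(scope="session")
def half_well():
    """Half-scale 30 x 30 x 40 well used for runtime-bounded simulations."""
    return mw.build_well_domain((30, 30, 40), R=15.0, z_split=15)


@pytest.fixture(scope="session")
def tiny_box():
    """A 6 x 6 x 6 open box (walls on all faces, exempt top)."""
    return mw.build_box_domain((6, 6, 6))


@pytest.fixture()
def rng():
    return mw.RngStream(1234)


def make_snapshot(coords, dims, time=0.0, N=None):
    coords = np.asarray(coords, dtype=np.int32).reshape(-1, 3)
    n = coords.shape[0]
    if N is None:
        N = int(np.prod(dims))
    return mw.Snapshot(coords=coords, time=time, theta=n / N,
                       meta={"dims": list(dims)})
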