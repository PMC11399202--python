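import numpy as np
import pytest

from hardigen.gradients import design_scheme, split_scheme
from hardigen.phantom import make_crossing_phantom, simulate_signal


@pytest.fixture(scope="session")
def scheme64():
    """A 64-direction b=3000 scheme with one leading b0 (modest restarts)."""
    return design_scheme(64, seed=7, n_restarts=10)


@pytest.fixture(scope="session")
def split64(scheme64):
    return split_scheme(scheme64, 32)


@pytest.fixture(scope="session")
def crossing_phantom(scheme64):
    """Noiseless 32^3 two-bundle 90-degree crossing phantom."""
    bundles = make_crossing_phantom(90.0, (32, 32, 32))
    return simulate_signal(bundles, scheme64, (32, 32, 32), S0=100.0)


@pytest.fixture(scope="session")
def single_fiber_region(crossing_phantom):
    vol, truth = crossing_phantom
    mask = truth.bundle_masks[0] & ~truth.bundle_masks[1]
    direction = truth.fiber_directions[0][mask][0]
    return vol, truth, mask, direction


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
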