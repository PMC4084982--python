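import numpy as np
import pytest

from ribofit import synthetic
from ribofit.structure import AtomicModel


@pytest.fixture(scope="session")
def small_toy():
    """Small ratchet assembly shared by read-only tests."""
    spec = synthetic.ToyRibosomeSpec(n_large=40, n_small=28, n_head=14,
                                     n_trna=6, seed=5)
    return synthetic.make_toy_ribosome(spec)


@pytest.fixture(scope="session")
def small_maps(small_toy):
    return synthetic.make_state_maps(small_toy.endpoints, resolution=10.0,
                                     spacing=2.0)


def random_model(rng, n=20, box=10.0):
    coords = rng.uniform(-box, box, size=(n, 3))
    masses = rng.uniform(10.0, 30.0, size=n)
    return AtomicModel(
        names=np.array(["C"] * n), elements=np.array(["C"] * n),
        resnames=np.array(["BEA"] * n), resnums=np.arange(1, n + 1),
        chains=np.array(["A"] * n), coords=coords, masses=masses)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
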