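import numpy as np
import pytest

from serialct.phantom import NoduleSpec, PhantomSpec, make_phantom_pair
from serialct.volume import ImageVolume


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def phantom_cache():
    """Session cache so expensive phantom pairs are generated once."""
    cache: dict = {}

    def factory(spec: PhantomSpec):
        if spec not in cache:
            cache[spec] = make_phantom_pair(spec)
        return cache[spec]

    return factory


def light_spec(shape=(48, 48, 48), seed=5, warp_amplitude=3.0, noise_sd=0.02,
               nodules=()):
    return PhantomSpec(shape=shape, seed=seed, warp_amplitude=warp_amplitude,
                       noise_sd=noise_sd, nodules=tuple(nodules))


@pytest.fixture(scope="session")
def small_pair(phantom_cache):
    """48-cube pair: smooth global warp plus one growing nodule."""
    return phantom_cache(light_spec(
        nodules=[NoduleSpec(radius=4.5, change="grow", factor=1.25, center=(14.0, 33.0, 30.0))],
    ))


@pytest.fixture
def ball_volume():
    """A bright sphere (radius 6) in dark background on a 32-cube grid."""
    x = np.stack(np.meshgrid(*[np.arange(32.0)] * 3, indexing="ij"))
    d = np.sqrt(((x - 16.0) ** 2).sum(axis=0))
    data = np.where(d <= 6.0, 0.8, 0.05)
    return ImageVolume(data, np.ones(3), np.zeros(3))
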