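import numpy as np
import pytest

from cryocdae.phantoms import Component, Orientation, PhantomVolume, make_phantom
from cryocdae.simulate import SimulationPlan, build_datasets
from cryocdae.stack import ImageStack, SNRLevel


@pytest.fixture(scope="session")
def small_phantom() -> PhantomVolume:
    return make_phantom(side=32, n_components=3, seed=11)


@pytest.fixture(scope="session")
def centered_blob() -> PhantomVolume:
    """A single isotropic Gaussian exactly at the cube center (symmetric)."""
    side = 32
    c = (side - 1) / 2.0
    comp = Component("gaussian", (c, c, c), (4.0, 4.0, 4.0), 1.0)
    return PhantomVolume(grid=comp.rasterize(side), side=side, spec=[comp])


@pytest.fixture(scope="session")
def tiny_datasets():
    """Desk-scale aligned tiers + labeled test stack (32x32 images)."""
    plan = SimulationPlan(
        phantom=make_phantom(32, 3, seed=5),
        orientations=[
            Orientation((0.0, 0.0, 0.0)),
            Orientation((0.0, 90.0, 0.0)),
            Orientation((90.0, 45.0, 0.0)),
            Orientation((30.0, 120.0, 60.0)),
        ],
        n_per_class=10,
        seed=7,
    )
    return build_datasets(plan)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture()
def noisy_pair(rng) -> tuple[ImageStack, ImageStack]:
    """(clean, noisy) 16x16 stacks with known Gaussian noise."""
    clean = ImageStack(np.clip(rng.random((40, 16, 16), dtype=np.float32), 0, 1))
    from cryocdae.simulate import add_noise

    noisy = add_noise(clean, SNRLevel(0.4, "mid"), seed=99)
    return clean, noisy
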