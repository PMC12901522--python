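import numpy as np
import pytest

from mcdose.dose import compute_clean_dose
from mcdose.phantoms import PhantomSpec, generate_phantom
from mcdose.plans import random_arc
from mcdose.volumes import Volume


@pytest.fixture(scope="session")
def water_phantom():
    """Uniform water-ellipsoid phantom, 48x48x32 at 0.25 cm voxels."""
    return generate_phantom(
        PhantomSpec(shape=(48, 48, 32), semi_axes=(5.0, 4.5, 3.6)), seed=0
    )


@pytest.fixture(scope="session")
def hetero_phantom():
    """Phantom with lung-like and bone-like inserts."""
    from mcdose.phantoms import Insert

    return generate_phantom(
        PhantomSpec(
            shape=(48, 48, 32),
            semi_axes=(5.0, 4.5, 3.6),
            inserts=(
                Insert("lung", (-2.0, 0.0, 0.0), (1.5, 1.5, 1.2)),
                Insert("bone", (2.5, 1.0, 0.0), (0.8, 0.8, 0.8)),
            ),
        ),
        seed=1,
    )


@pytest.fixture(scope="session")
def arc_dose(water_phantom):
    """A deterministic clean arc dose on the water phantom."""
    rng = np.random.default_rng(11)
    plan = random_arc(water_phantom.center(), rng)
    return plan, compute_clean_dose(water_phantom, plan)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_volume(rng, shape=(16, 16, 16), voxel=(0.2, 0.2, 0.2), low=0.2, high=1.0):
    return Volume(rng.uniform(low, high, shape), voxel)
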