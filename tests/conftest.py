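import numpy as np
import pytest

from pgk.assembly import SphereAssembly


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def two_sphere_assembly():
    return SphereAssembly(
        positions=[[0.0, 0.0, 0.0], [300.0, 0.0, 0.0]],
        radii=[105.0, 105.0],
        box=[1000.0, 1000.0, 1000.0],
        periodic=[True, True, True])


@pytest.fixture
def random_assembly(rng):
    """A dilute random periodic assembly (no guaranteed non-overlap)."""
    n = 60
    box = np.array([800.0, 900.0, 700.0])
    pos = rng.uniform(0, 1, (n, 3)) * box
    radii = rng.uniform(20.0, 40.0, n)
    return SphereAssembly(pos, radii, box, [True, True, True])


@pytest.fixture(scope="session")
def small_jammed_packing():
    """One marginally jammed monodisperse packing, shared across tests."""
    from pgk.lattices import JamSpec, generate_jammed_packing

    return generate_jammed_packing(JamSpec(n=256, seed=7))
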