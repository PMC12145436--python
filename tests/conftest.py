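import numpy as np
import pytest

from brainkrig import (
    SynthesisSpec,
    build_icosphere,
    build_sphere_lattice,
    mesh_eigenmodes,
    synth_map,
)


@pytest.fixture(scope="session")
def ico2():
    return build_icosphere(2)  # 162 vertices


@pytest.fixture(scope="session")
def ico3():
    return build_icosphere(3)  # 642 vertices


@pytest.fixture(scope="session")
def ico4():
    return build_icosphere(4)  # 2562 vertices


@pytest.fixture(scope="session")
def basis3(ico3):
    """101 eigenmodes on the 642-vertex sphere (shared across tests)."""
    return mesh_eigenmodes(ico3, 101)


@pytest.fixture(scope="session")
def basis4(ico4):
    """201 eigenmodes on the 2562-vertex sphere."""
    return mesh_eigenmodes(ico4, 201)


@pytest.fixture(scope="session")
def smooth_map3(ico3, basis3):
    spec = SynthesisSpec(spectrum_decay=3.0, n_modes=100, noise_sd=0.05,
                         seed=7)
    return synth_map(ico3, spec, basis=basis3)


@pytest.fixture(scope="session")
def lattice2():
    """Two-level sphere lattice (42 + 162 nodes)."""
    return build_sphere_lattice(2, base_subdivision=1, alpha=(1.0, 0.25))


@pytest.fixture(scope="session")
def lattice1():
    """Single-level 42-node sphere lattice."""
    return build_sphere_lattice(1, base_subdivision=1, alpha=(1.0,))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
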