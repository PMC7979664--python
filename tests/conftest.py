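import numpy as np
import pytest

from hypercell import build_sphere_mesh, material_from_E_nu, precompute_reference


@pytest.fixture(scope="session")
def ball_coarse():
    """Coarse ball mesh (~360 vertices), radius 1."""
    return build_sphere_mesh(1.0, subdivisions=2, seed=0)


@pytest.fixture(scope="session")
def ball_coarse_ref(ball_coarse):
    return precompute_reference(ball_coarse)


@pytest.fixture(scope="session")
def ball_default():
    """Default-resolution ball mesh (~2300 vertices, ~12000 tets), radius 1."""
    return build_sphere_mesh(1.0, subdivisions=3, seed=0)


@pytest.fixture(scope="session")
def mat_nh():
    """Neo-Hookean material with unit shear modulus (E = 2 mu (1+nu))."""
    return material_from_E_nu(2.96, 0.48, w=1.0)


@pytest.fixture(scope="session")
def mat_mr():
    """Mooney-Rivlin material with w = 0.5, unit shear modulus."""
    return material_from_E_nu(2.96, 0.48, w=0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
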