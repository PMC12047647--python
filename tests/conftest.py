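"""Shared fixtures: small phantoms, bases and lead fields built once."""

import numpy as np
import pytest

from nibsim.conductivity import isotropic_tensor_field
from nibsim.em import compute_field_basis, leadfield_reciprocity
from nibsim.phantom import (build_sphere_phantom, place_electrodes_1010,
                            synth_connectome, tessellate_cortex)

#: Small validation phantom: 33^3 voxels, thick GM shell so interior mesh
#: vertices keep their field-sampling stencils inside grey matter.
SMALL_RADII = (60.0, 52.0, 46.0, 40.0, 20.0)
SMALL_SIGMA = (0.4, 0.01, 1.8, 0.3, 0.15)

EIGHT_CHANNELS = ["Fz", "Cz", "Pz", "C3", "C4", "T7", "T8", "Oz"]


@pytest.fixture(scope="session")
def small_phantom():
    return build_sphere_phantom(radii_mm=SMALL_RADII, conductivities=SMALL_SIGMA,
                                spacing=4.0)


@pytest.fixture(scope="session")
def small_sigma(small_phantom):
    return isotropic_tensor_field(small_phantom)


@pytest.fixture(scope="session")
def small_montage(small_phantom):
    return place_electrodes_1010(small_phantom, subset=EIGHT_CHANNELS,
                                 reference="Cz")


@pytest.fixture(scope="session")
def small_basis(small_sigma, small_montage):
    return compute_field_basis(small_sigma, small_montage, tol=1e-10)


@pytest.fixture(scope="session")
def small_mesh(small_phantom):
    return tessellate_cortex(small_phantom, 42, n_regions=8)


@pytest.fixture(scope="session")
def small_leadfield(small_basis, small_mesh):
    return leadfield_reciprocity(small_basis, small_mesh)


@pytest.fixture(scope="session")
def default_phantom():
    """Head-sized phantom at the coarse pipeline resolution (49^3)."""
    return build_sphere_phantom(radii_mm=(92.0, 84.0, 78.0, 74.0, 62.0),
                                conductivities=SMALL_SIGMA, spacing=4.0)


@pytest.fixture(scope="session")
def default_montage(default_phantom):
    return place_electrodes_1010(default_phantom)


@pytest.fixture(scope="session")
def connectome84():
    return synth_connectome(84, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
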