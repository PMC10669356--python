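import numpy as np
import pytest

from periofem.geometry import ToothParams, build_tooth
from periofem.materials import MaterialSpec
from periofem.meshing import box_mesh, generate_mesh
from periofem.solver import (LoadProtocol, apply_supports, assemble,
                             solve_terminal, traction_load)


@pytest.fixture(scope="session")
def single_model():
    return build_tooth(ToothParams.single())


@pytest.fixture(scope="session")
def multi_model():
    return build_tooth(ToothParams.multi())


@pytest.fixture(scope="session")
def coarse_single_mesh(single_model):
    """Coarse quadratic half mesh of the default single-rooted model."""
    return generate_mesh(single_model, size=1.8, order=2)


@pytest.fixture(scope="session")
def coarse_single_solution(single_model, coarse_single_mesh):
    mesh = coarse_single_mesh
    system = apply_supports(assemble(mesh), mesh, "outer_bone_boundary")
    return solve_terminal(system, LoadProtocol())


def solve_block(dims, size, materials, support, traction_vec,
                traction_on="zmax", order=2, classify=None):
    """Small driver for verification problems on box meshes."""
    mesh = box_mesh(dims, size=size, order=order, classify=classify)
    system = apply_supports(assemble(mesh, materials), mesh, support,
                            use_symmetry=False)
    fs = mesh.facet_sets[traction_on]
    f = traction_load(mesh, traction_on, np.asarray(traction_vec, float))
    u = system.solve(f)
    return mesh, system, u


@pytest.fixture(scope="session")
def steel():
    return MaterialSpec("steel", 200_000.0, 0.3)
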