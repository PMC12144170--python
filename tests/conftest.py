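import numpy as np
import pytest

import fracturetwin as ft
from fracturetwin.grids import LabelMap
from fracturetwin.materials import MaterialTable


@pytest.fixture(scope="session")
def small_spec() -> ft.ConstructSpec:
    """A small nail-only construct used across module tests."""
    return ft.ConstructSpec(
        bone_length=40.0, outer_radius=6.0, cortical_thickness=2.0,
        canal_radius=3.0, gap_position=20.0, gap_width=4.0,
        nail_radius=2.0, nail_length=30.0, voxel_spacing=1.0, seed=0,
    )


@pytest.fixture(scope="session")
def small_construct(small_spec):
    return ft.generate_construct(small_spec)


@pytest.fixture(scope="session")
def small_mesh(small_construct):
    _, labels = small_construct
    return ft.voxels_to_tetmesh(labels, element_order=1)


def make_block_mesh(nx, ny, nz, spacing=1.0, order=1):
    """Voxel-mesh a solid cuboid of a single region."""
    lm = LabelMap(labels=np.ones((nx, ny, nz), dtype=np.int16), spacing=spacing)
    return ft.voxels_to_tetmesh(lm, element_order=order)


def uniform_materials(mesh, E=1000.0, nu=0.0):
    ne = mesh.n_elements
    return MaterialTable(
        E=np.full(ne, float(E)),
        nu=np.full(ne, float(nu)),
        provenance=np.full(ne, "fixed", dtype=object),
    )


def make_bar(n_side=4, n_len=20, spacing=1.0, order=1, E=1000.0, nu=0.0):
    """Prismatic bar with end node sets and a lateral pin, ready to load."""
    mesh = make_block_mesh(n_side, n_side, n_len, spacing, order)
    W = n_side * spacing
    L = n_len * spacing
    eps = spacing / 4.0
    ft.define_cuboid_nodeset(mesh, "DISTAL_FIX",
                             ((-eps, W + eps), (-eps, W + eps), (-eps, eps)))
    ft.define_cuboid_nodeset(mesh, "PROXIMAL_LOAD",
                             ((-eps, W + eps), (-eps, W + eps), (L - eps, L + eps)))
    ft.define_cuboid_nodeset(mesh, "PIN",
                             ((-eps, eps), (-eps, W + eps), (-eps, eps)))
    return mesh, uniform_materials(mesh, E, nu), W, L
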