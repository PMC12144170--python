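import numpy as np
import pytest
import scipy.sparse.linalg as spla

import fracturetwin as ft
from fracturetwin.solver import (
    DirichletBC,
    LoadCase,
    NeumannBC,
    assemble_and_solve,
    assemble_stiffness,
    recover_fields,
)

from conftest import make_bar, make_block_mesh, uniform_materials


def bar_load(F=(0.0, 0.0, 100.0), distribution="area"):
    return LoadCase(
        "bar",
        dirichlet=[DirichletBC("DISTAL_FIX", None, None, 0.0),
                   DirichletBC("PIN", 0.0, 0.0, None)],
        neumann=[NeumannBC("PROXIMAL_LOAD", F, distribution=distribution)],
    )


class TestAxialBar:
    @pytest.mark.parametrize("order", [1, 2])
    def test_tip_displacement_matches_closed_form(self, order):
        mesh, mat, W, L = make_bar(order=order)
        F, E, A = 100.0, 1000.0, W * W
        sol = assemble_and_solve(mesh, mat, bar_load((0, 0, F)))
        tip = sol.displacements[mesh.node_sets["PROXIMAL_LOAD"], 2].mean()
        assert abs(tip / (F * L / (E * A)) - 1.0) < 1e-10

    def test_strain_field_is_uniform_and_exact(self):
        mesh, mat, W, L = make_bar()
        F, E, A = 100.0, 1000.0, W * W
        sol = assemble_and_solve(mesh, mat, bar_load((0, 0, F)))
        assert np.allclose(sol.strain[:, 2, 2], F / (E * A), rtol=1e-10)
        off = sol.strain.copy()
        off[:, 2, 2] = 0.0
        assert np.abs(off).max() < 1e-14

    def test_uniaxial_stress_with_zero_poisson_has_no_lateral_stress(self):
        mesh, mat, W, _ = make_bar(nu=0.0)
        sol = assemble_and_solve(mesh, mat, bar_load((0, 0, 100.0)))
        assert np.abs(sol.stress[:, 0, 0]).max() < 1e-10
        assert np.abs(sol.stress[:, 1, 1]).max() < 1e-10


class TestBasicProperties:
    def test_zero_force_zero_displacement(self):
        mesh, mat, _, _ = make_bar(n_len=6)
        load = LoadCase("none", dirichlet=[DirichletBC("DISTAL_FIX", 0, 0, 0)])
        sol = assemble_and_solve(mesh, mat, load)
        assert np.abs(sol.displacements).max() == 0.0
        assert np.abs(sol.strain).max() == 0.0

    def test_linearity_in_load(self):
        mesh, mat, _, _ = make_bar(n_len=8, nu=0.3)
        load1 = LoadCase("l1", [DirichletBC("DISTAL_FIX", 0, 0, 0)],
                         [NeumannBC("PROXIMAL_LOAD", (10.0, -5.0, 40.0))])
        load2 = LoadCase("l2", [DirichletBC("DISTAL_FIX", 0, 0, 0)],
                         [NeumannBC("PROXIMAL_LOAD", (30.0, -15.0, 120.0))])
        s1 = assemble_and_solve(mesh, mat, load1)
        s2 = assemble_and_solve(mesh, mat, load2)
        for a, b in ((s1.displacements, s2.displacements),
                     (s1.strain, s2.strain), (s1.stress, s2.stress),
                     (s1.reactions, s2.reactions)):
            assert np.allclose(3.0 * a, b, rtol=1e-10, atol=1e-12)

    def test_global_equilibrium_residual(self):
        mesh, mat, _, _ = make_bar(n_len=10, nu=0.25)
        load = LoadCase("eq", [DirichletBC("DISTAL_FIX", 0, 0, 0)],
                        [NeumannBC("PROXIMAL_LOAD", (25.0, 10.0, -80.0))])
        sol = assemble_and_solve(mesh, mat, load)
        assert sol.equilibrium_residual() < 1e-8

    def test_rigid_body_translation_gives_zero_strain(self):
        mesh = make_block_mesh(2, 2, 4)
        mat = uniform_materials(mesh, nu=0.3)
        u = np.tile([0.3, -0.7, 1.1], (mesh.n_nodes, 1))
        strain, stress = recover_fields(mesh, mat, u)
        assert np.abs(strain).max() < 1e-12
        assert np.abs(stress).max() < 1e-9

    def test_underconstrained_system_rejected_with_mode_count(self):
        mesh = make_block_mesh(2, 2, 4)
        mat = uniform_materials(mesh)
        ft.define_cuboid_nodeset(mesh, "ONE", ((-0.1, 0.1), (-0.1, 0.1), (-0.1, 0.1)))
        load = LoadCase("bad", [DirichletBC("ONE", 0, 0, 0)],
                        [NeumannBC("ONE", (1, 0, 0))])
        with pytest.raises(ValueError, match="3 unconstrained rigid-body"):
            assemble_and_solve(mesh, mat, load)

    def test_unknown_node_set_rejected(self):
        mesh, mat, _, _ = make_bar(n_len=4)
        load = LoadCase("bad", [DirichletBC("MISSING", 0, 0, 0)])
        with pytest.raises(ValueError, match="MISSING"):
            assemble_and_solve(mesh, mat, load)


class TestPatchTest:
    @pytest.mark.parametrize("order", [1, 2])
    def test_linear_field_reproduced_exactly(self, order):
        mesh = make_block_mesh(3, 3, 3, order=order)
        mat = uniform_materials(mesh, E=500.0, nu=0.3)
        rng = np.random.default_rng(0)
        A = rng.normal(size=(3, 3)) * 1e-3
        b = rng.normal(size=3)
        target = mesh.nodes @ A.T + b
        bn = mesh.boundary_nodes()
        mesh.node_sets["BOUNDARY"] = bn
        load = LoadCase("patch", [DirichletBC(
            "BOUNDARY", target[bn, 0], target[bn, 1], target[bn, 2])])
        sol = assemble_and_solve(mesh, mat, load)
        assert np.abs(sol.displacements - target).max() < 1e-10
        eps_exact = 0.5 * (A + A.T)
        assert np.abs(sol.strain - eps_exact).max() < 1e-10


class TestFrameObjectivity:
    def test_rotated_problem_gives_rotated_solution(self):
        # rotate mesh, loads and constraints by a rigid rotation; the
        # displacement field must rotate correspondingly
        from scipy.spatial.transform import Rotation

        mesh, mat, _, _ = make_bar(n_side=2, n_len=6, nu=0.3)
        load = LoadCase("l", [DirichletBC("DISTAL_FIX", 0, 0, 0)],
                        [NeumannBC("PROXIMAL_LOAD", (5.0, 0.0, 30.0))])
        sol = assemble_and_solve(mesh, mat, load)

        Q = Rotation.from_rotvec([0.3, -0.5, 0.9]).as_matrix()
        mesh_r = ft.TetMesh(
            nodes=mesh.nodes @ Q.T,
            elements=mesh.elements.copy(),
            element_label=mesh.element_label.copy(),
            legend=dict(mesh.legend),
            element_order=1,
            node_sets={k: v.copy() for k, v in mesh.node_sets.items()},
        )
        F_r = tuple(Q @ np.array([5.0, 0.0, 30.0]))
        load_r = LoadCase("lr", [DirichletBC("DISTAL_FIX", 0, 0, 0)],
                          [NeumannBC("PROXIMAL_LOAD", F_r)])
        sol_r = assemble_and_solve(mesh_r, mat, load_r)
        assert np.allclose(sol_r.displacements, sol.displacements @ Q.T,
                           rtol=1e-9, atol=1e-12)
        assert np.allclose(sol_r.strain, Q @ sol.strain @ Q.T,
                           rtol=1e-8, atol=1e-12)


class TestSolverPaths:
    def test_block_tridiagonal_matches_direct_factorization(self):
        mesh, mat, _, _ = make_bar(n_side=5, n_len=24, nu=0.3)
        load = LoadCase("l", [DirichletBC("DISTAL_FIX", 0, 0, 0)],
                        [NeumannBC("PROXIMAL_LOAD", (12.0, -7.0, -90.0))])
        direct = assemble_and_solve(mesh, mat, load)
        layered = assemble_and_solve(mesh, mat, load, direct_max_dof=10)
        assert layered.solver_info["method"] == "block_tridiagonal"
        denom = np.abs(direct.displacements).max()
        assert np.abs(layered.displacements - direct.displacements).max() \
            < 1e-9 * denom

    def test_prescribed_displacements_reproduced_exactly(self):
        mesh, mat, _, _ = make_bar(n_len=6)
        load = LoadCase("d", [DirichletBC("DISTAL_FIX", 0.0, 0.0, -0.25)],
                        [NeumannBC("PROXIMAL_LOAD", (0, 0, 10.0))])
        sol = assemble_and_solve(mesh, mat, load)
        ids = mesh.node_sets["DISTAL_FIX"]
        assert np.all(sol.displacements[ids, 2] == -0.25)


class TestCantileverConvergence:
    def test_monotone_convergence_to_euler_bernoulli(self):
        # slender 2x2x20 mm cantilever, transverse tip load; voxel meshes
        # at h = 1, 0.5, 0.25 mm must approach the EB deflection
        # monotonically; order-2 at h = 0.5 must beat order-1 at h = 0.5
        W, L, E, F = 2.0, 20.0, 1000.0, 1.0
        I = W**4 / 12.0
        eb = F * L**3 / (3.0 * E * I)

        def tip_error(h, order):
            n = int(W / h)
            nz = int(L / h)
            mesh = make_block_mesh(n, n, nz, spacing=h, order=order)
            eps = h / 4.0
            ft.define_cuboid_nodeset(mesh, "DISTAL_FIX",
                                     ((-1, W + 1), (-1, W + 1), (-eps, eps)))
            ft.define_cuboid_nodeset(mesh, "PROXIMAL_LOAD",
                                     ((-1, W + 1), (-1, W + 1), (L - eps, L + eps)))
            mat = uniform_materials(mesh, E=E, nu=0.0)
            load = LoadCase("c", [DirichletBC("DISTAL_FIX", 0, 0, 0)],
                            [NeumannBC("PROXIMAL_LOAD", (F, 0, 0),
                                       distribution="area")])
            sol = assemble_and_solve(mesh, mat, load)
            tip = sol.displacements[mesh.node_sets["PROXIMAL_LOAD"], 0].mean()
            return abs(tip / eb - 1.0)

        e1 = [tip_error(h, 1) for h in (1.0, 0.5, 0.25)]
        assert e1[0] > e1[1] > e1[2]
        assert e1[2] <= 0.10
        e2 = tip_error(0.5, 2)
        assert e2 < e1[1]
        assert e2 <= 0.10
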