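import numpy as np
import pytest

from fracturetwin.mechanobiology import (
    ZONES,
    HealingZoneConfig,
    classify_healing,
    classify_zone,
    peak_stress,
    strain_invariants,
    von_mises,
)

from helpers import random_rotations, zone_oracle


class TestStrainInvariants:
    def test_hydrostatic_state_has_zero_shear(self):
        gamma, eps_vol = strain_invariants(np.diag([0.05, 0.05, 0.05]))
        assert gamma == pytest.approx(0.0, abs=1e-15)
        assert eps_vol == pytest.approx(0.15, abs=1e-15)

    def test_uniaxial_hand_computed_value(self):
        gamma, eps_vol = strain_invariants(np.diag([0.03, 0.0, 0.0]))
        expected = (2.0 / 3.0) * np.sqrt(0.0009 + 0.0 + 0.0009)
        assert abs(gamma - expected) < 1e-12
        assert abs(gamma - 0.028284271247) < 1e-9
        assert eps_vol == pytest.approx(0.03, abs=1e-15)

    def test_trace_of_mixed_state(self):
        _, eps_vol = strain_invariants(np.diag([0.01, -0.02, 0.005]))
        assert eps_vol == pytest.approx(-0.005, abs=1e-15)

    def test_asymmetric_tensor_rejected(self):
        bad = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            strain_invariants(bad)


class TestVonMises:
    def test_hydrostatic_pressure_vanishes(self):
        assert von_mises(-37.0 * np.eye(3)) == pytest.approx(0.0, abs=1e-12)

    def test_uniaxial_definition(self):
        s = np.zeros((3, 3))
        s[0, 0] = 100.0
        assert von_mises(s) == pytest.approx(100.0, rel=1e-14)

    def test_pure_shear_hand_computed(self):
        s = np.zeros((3, 3))
        s[0, 1] = s[1, 0] = 50.0
        assert abs(von_mises(s) - 50.0 * np.sqrt(3.0)) < 1e-12
        assert von_mises(s) == pytest.approx(86.6025403784, abs=1e-9)


class TestFrameInvariance:
    def test_invariants_unchanged_under_1000_rotations(self):
        rng = np.random.default_rng(42)
        eps = rng.normal(scale=0.02, size=(3, 3))
        eps = 0.5 * (eps + eps.T)
        sig = rng.normal(scale=80.0, size=(3, 3))
        sig = 0.5 * (sig + sig.T)
        g0, v0 = strain_invariants(eps)
        m0 = von_mises(sig)
        Q = random_rotations(1000, seed=7)
        eps_r = Q @ eps @ np.transpose(Q, (0, 2, 1))
        sig_r = Q @ sig @ np.transpose(Q, (0, 2, 1))
        g, v = strain_invariants(eps_r, tol=1e-6)
        m = von_mises(sig_r, tol=1e-6)
        assert np.abs(g / g0 - 1.0).max() < 1e-10
        assert np.abs(v - v0).max() < 1e-10 * max(1.0, abs(v0))
        assert np.abs(m / m0 - 1.0).max() < 1e-10


class TestClassification:
    def test_matches_brute_force_oracle_on_dense_grid(self):
        cfg = HealingZoneConfig()
        g = np.linspace(0.0, 0.2, 200)
        v = np.linspace(-0.2, 0.2, 200)
        G, V = np.meshgrid(g, v, indexing="ij")
        fast = classify_zone(G.ravel(), V.ravel(), cfg)
        slow = np.array([zone_oracle(gg, vv, cfg)
                         for gg, vv in zip(G.ravel(), V.ravel())], dtype=object)
        assert np.all(fast == slow)

    def test_boundary_belongs_to_lower_strain_zone(self):
        cfg = HealingZoneConfig()
        assert classify_zone(cfg.gamma_im, 0.0, cfg)[0] == "intramembranous"
        assert classify_zone(cfg.gamma_ec, 0.0, cfg)[0] == "endochondral"
        assert classify_zone(cfg.gamma_ec + 1e-12, 0.06, cfg)[0] == "excessive"

    def test_default_window_example(self):
        res = classify_healing(
            np.full(10, 0.02), np.full(10, -0.01), np.ones(10)
        )
        assert res.volume_fractions["intramembranous"] == 1.0
        assert res.healing_window_volume_fraction == 1.0

    def test_fractions_partition_to_one(self):
        rng = np.random.default_rng(1)
        g = np.abs(rng.normal(scale=0.08, size=500))
        v = rng.normal(scale=0.08, size=500)
        vol = rng.uniform(0.5, 2.0, size=500)
        res = classify_healing(g, v, vol)
        assert sum(res.volume_fractions.values()) == pytest.approx(1.0, abs=1e-12)
        assert sum(res.count_fractions.values()) == pytest.approx(1.0, abs=1e-12)

    def test_volume_and_count_fractions_coincide_on_equal_volumes(self):
        rng = np.random.default_rng(2)
        g = np.abs(rng.normal(scale=0.08, size=300))
        v = rng.normal(scale=0.08, size=300)
        res = classify_healing(g, v, np.full(300, 1.0 / 6.0))
        for z in ZONES:
            assert res.volume_fractions[z] == pytest.approx(
                res.count_fractions[z], abs=1e-12)

    def test_empty_callus_rejected(self):
        with pytest.raises(ValueError, match="no fracture region"):
            classify_healing(np.array([]), np.array([]), np.array([]))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            HealingZoneConfig(gamma_low=0.1, gamma_im=0.05).validate()


class TestPeakStress:
    def test_bar_peak_equals_force_over_area(self):
        import fracturetwin as ft
        from conftest import make_bar
        from fracturetwin.solver import DirichletBC, LoadCase, NeumannBC, \
            assemble_and_solve

        mesh, mat, W, _ = make_bar()
        F = 64.0
        load = LoadCase(
            "bar",
            [DirichletBC("DISTAL_FIX", None, None, 0.0),
             DirichletBC("PIN", 0.0, 0.0, None)],
            [NeumannBC("PROXIMAL_LOAD", (0, 0, F), distribution="area")],
        )
        sol = assemble_and_solve(mesh, mat, load)
        region = mesh.legend[int(mesh.element_label[0])]
        vm, eid = peak_stress(sol, region)
        assert vm == pytest.approx(F / (W * W), rel=1e-10)
        assert 0 <= eid < mesh.n_elements

    def test_region_monotonicity_and_errors(self, small_construct):
        import fracturetwin as ft
        from fracturetwin.materials import assign_materials
        from fracturetwin.cases import add_end_nodesets, make_load_case, LoadSpec

        volume, labels = small_construct
        mesh = ft.voxels_to_tetmesh(labels)
        spec_like = type("S", (), {"bone_length": 40.0, "outer_radius": 6.0})
        add_end_nodesets(mesh, spec_like)
        mat = assign_materials(mesh, volume, labels)
        load = make_load_case(spec_like, LoadSpec(axial_N=-100.0,
                                                  transverse_N=20.0))
        sol = ft.assemble_and_solve(mesh, mat, load)
        peak_nail, _ = peak_stress(sol, "nail")
        assert peak_nail > 0
        with pytest.raises(ValueError, match="plate"):
            peak_stress(sol, "plate")
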