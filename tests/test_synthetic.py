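import dataclasses

import numpy as np
import pytest

import fracturetwin as ft
from fracturetwin.synthetic import (
    DEFAULT_GREYVALUES,
    ProminenceSpec,
    WristParams,
    generate_wrist_scene,
)


class TestConstructGeneration:
    def test_no_nail_means_no_nail_voxels(self, small_spec):
        spec = dataclasses.replace(small_spec, nail_radius=0.0)
        _, labels = ft.generate_construct(spec)
        assert labels.count("nail") == 0

    def test_noise_free_greyvalues_equal_tissue_levels(self, small_construct):
        volume, labels = small_construct
        for rid, name in labels.legend.items():
            mask = labels.labels == rid
            if mask.any():
                assert np.all(volume.values[mask] == DEFAULT_GREYVALUES[name])

    def test_gap_width_in_voxel_layers(self):
        # 4 mm gap at 1 mm spacing, centered between voxel layers -> the
        # callus slab is exactly 4 voxel layers thick along the axis
        spec = ft.ConstructSpec(
            bone_length=40.0, outer_radius=6.0, cortical_thickness=2.0,
            canal_radius=3.0, gap_position=20.0, gap_width=4.0,
            nail_radius=0.0, voxel_spacing=1.0,
        )
        _, labels = ft.generate_construct(spec)
        zs = labels.voxel_centers()[2]
        callus_layers = np.unique(
            np.nonzero(labels.labels == labels.region_id("callus"))[2]
        )
        # oracle: voxel centers falling inside [18, 22)
        expected = np.flatnonzero((zs >= 18.0) & (zs < 22.0))
        assert np.array_equal(callus_layers, expected)
        assert callus_layers.size == 4

    def test_determinism_bit_identical(self, small_spec):
        spec = dataclasses.replace(small_spec, noise_sd=25.0, seed=7)
        v1, l1 = ft.generate_construct(spec)
        v2, l2 = ft.generate_construct(spec)
        assert np.array_equal(v1.values, v2.values)
        assert np.array_equal(l1.labels, l2.labels)

    def test_nail_volume_converges_with_refinement(self):
        # voxel-counted nail volume approaches pi r^2 L; error at least
        # halves when the spacing is halved
        errors = []
        for h in (1.0, 0.5):
            spec = ft.ConstructSpec(
                bone_length=40.0, outer_radius=6.0, cortical_thickness=2.0,
                canal_radius=3.0, gap_position=20.0, gap_width=4.0,
                nail_radius=2.5, nail_length=30.0, voxel_spacing=h,
            )
            _, labels = ft.generate_construct(spec)
            measured = labels.count("nail") * labels.voxel_volume_mm3()
            exact = np.pi * spec.nail_radius**2 * spec.nail_length
            errors.append(abs(measured - exact) / exact)
        assert errors[1] <= errors[0] / 2.0

    def test_label_precedence_implant_over_callus(self, small_construct):
        _, labels = small_construct
        # the nail crosses the gap: the gap slab must contain nail voxels
        # and no callus voxel may lie inside the nail radius
        zs = labels.voxel_centers()[2]
        gap = (zs >= 18.0) & (zs < 22.0)
        nail_in_gap = labels.labels[:, :, gap] == labels.region_id("nail")
        assert nail_in_gap.any()
        xs, ys, _ = labels.voxel_centers()
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        inside_nail = np.hypot(X, Y) <= 2.0
        callus = labels.labels[:, :, gap] == labels.region_id("callus")
        assert not np.any(callus[inside_nail, :])

    @pytest.mark.parametrize(
        "field,value,message",
        [
            ("nail_radius", 5.0, "nail_radius"),
            ("canal_radius", 5.0, "canal_radius"),
            ("gap_width", 0.0, "gap_width"),
            ("voxel_spacing", -1.0, "voxel_spacing"),
            ("noise_sd", -1.0, "noise_sd"),
        ],
    )
    def test_invalid_specs_are_rejected_by_name(self, small_spec, field, value,
                                                message):
        spec = dataclasses.replace(small_spec, **{field: value})
        with pytest.raises(ValueError, match=message):
            ft.generate_construct(spec)

    def test_plate_sits_on_periosteal_surface(self, small_spec):
        spec = dataclasses.replace(
            small_spec, plate=ft.PlateSpec(length=20.0, width=6.0, thickness=2.0)
        )
        _, labels = ft.generate_construct(spec)
        pid = labels.region_id("plate")
        idx = np.nonzero(labels.labels == pid)
        assert idx[0].size > 0
        xs, ys, _ = labels.voxel_centers()
        r = np.hypot(xs[idx[0]], ys[idx[1]])
        assert np.all(r > spec.outer_radius)
        assert np.all(r <= spec.outer_radius + 2.0)


class TestWristScene:
    def test_clearance_is_positive_by_construction(self):
        params = WristParams()
        assert params.clearance > 0
        scene = generate_wrist_scene(params)
        assert scene.watertight["carpal"]
        assert not scene.watertight["radius"]  # open articular patch

    def test_no_clearance_rejected(self):
        with pytest.raises(ValueError, match="clear"):
            generate_wrist_scene(WristParams(carpal_radius=8.0, center_offset=8.0))

    def test_axis_vectors_unit_norm(self):
        scene = generate_wrist_scene(WristParams(prominence=ProminenceSpec()))
        assert np.isclose(np.linalg.norm(scene.rotation_axis), 1.0)
        assert np.isclose(np.linalg.norm(scene.radius_anatomical_axis), 1.0)

    def test_prominence_reduces_local_cup_radius(self):
        pr = ProminenceSpec(angular_position=25.0, angular_half_width=5.0,
                            height=2.0)
        scene = generate_wrist_scene(WristParams(prominence=pr))
        r = np.linalg.norm(scene.radius_mesh.vertices, axis=1)
        assert r.min() < 15.0 - 1.5  # bump protrudes inward
        assert np.isclose(r.max(), 15.0)
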