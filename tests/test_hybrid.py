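"""Hybrid model construction: linking, interface fill, DRR assembly."""

import numpy as np
import pytest

from tartrack.drr import (DRRVolume, IMPLANT_REFERENCE_INTENSITY,
                          IMPLANT_INTENSITY_GAIN, hollow_implant,
                          isolate_bone, mesh_to_binary_stack)
from tartrack.geometry import (ChainingError, Pose, RigidTransform, compose,
                               invert, rotation_angle_deg)
from tartrack.hybrid import (HybridModel, InterfaceOverlapError,
                             assemble_hybrid_drr, fill_interface,
                             link_implant_to_bone)
from tartrack.volume import Grid

from conftest import random_rotation


def pose(R, t, src="ct"):
    return Pose(RigidTransform(R, np.asarray(t, float), src, "mbt"))


class TestLinkImplantToBone:
    def test_identical_poses_give_identity_link(self, rng):
        R = random_rotation(rng)
        t = rng.normal(size=3)
        link = link_implant_to_bone(pose(R, t), pose(R, t, "cad"))
        assert np.allclose(link.matrix, np.eye(4), atol=1e-9)
        assert link.source_space == "cad"
        assert link.target_space == "ct"

    def test_pure_translation_poses_give_identity_rotation(self):
        b = pose(np.eye(3), [1.0, 2.0, 3.0])
        i = pose(np.eye(3), [4.0, 0.0, 3.0], "cad")
        link = link_implant_to_bone(b, i)
        assert np.allclose(link.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(link.translation, [3.0, -2.0, 0.0])

    def test_recovers_known_relative_placement(self, rng):
        # place implant at a known offset in bone space, pick an arbitrary
        # world pose for the bone, and check the chain recovers the offset
        true_link = RigidTransform(random_rotation(rng), rng.normal(size=3),
                                   "cad", "ct")
        bone = pose(random_rotation(rng), rng.normal(size=3))
        implant = Pose(compose(bone.transform, true_link))
        est = link_implant_to_bone(bone, implant)
        assert np.allclose(est.matrix, true_link.matrix, atol=1e-9)

    def test_link_places_implant_mesh_in_bone_space(self, coarse_scene, rng):
        bone = pose(random_rotation(rng), rng.normal(size=3))
        implant = Pose(compose(bone.transform, coarse_scene.tray_to_tibia))
        est = link_implant_to_bone(bone, implant)
        verts = coarse_scene.tray_mesh.vertices
        expected = coarse_scene.tray_to_tibia.apply(verts)
        assert np.max(np.abs(est.apply(verts) - expected)) < 1e-8


class TestFillInterface:
    def grid_spacing(self):
        return np.array([1.0, 1.0, 1.0])

    def test_zero_gap_masks_unchanged(self):
        bone = np.zeros((20, 20, 20), bool)
        implant = np.zeros_like(bone)
        bone[:, :, 10:] = True
        implant[:, :, :10] = True  # touching at the z=10 plane
        out = fill_interface(bone, implant, self.grid_spacing(), 3.0)
        assert np.array_equal(out, bone)

    def test_planar_gap_filled_with_exact_slab_count(self):
        # full-cross-section slabs with a 2-voxel gap: the fill adds
        # exactly the analytic slab volume
        bone = np.zeros((12, 10, 20), bool)
        implant = np.zeros_like(bone)
        bone[:, :, 10:] = True
        implant[:, :, :8] = True
        out = fill_interface(bone, implant, self.grid_spacing(), 3.0)
        added = out & ~bone
        assert added.sum() == 12 * 10 * 2
        assert added[:, :, 8:10].all()

    def test_gap_wider_than_max_gap_warns_and_leaves_unchanged(self):
        bone = np.zeros((10, 10, 30), bool)
        implant = np.zeros_like(bone)
        bone[:, :, 20:] = True
        implant[:, :, :5] = True  # 15-voxel gap
        with pytest.warns(UserWarning, match="gap"):
            out = fill_interface(bone, implant, self.grid_spacing(), 3.0)
        assert np.array_equal(out, bone)

    def test_overlapping_masks_raise(self):
        bone = np.zeros((8, 8, 8), bool)
        implant = np.zeros_like(bone)
        bone[:, :, 2:6] = True
        implant[:, :, 5:] = True
        with pytest.raises(InterfaceOverlapError):
            fill_interface(bone, implant, self.grid_spacing(), 3.0)

    def test_idempotent(self, coarse_scene):
        scene = coarse_scene
        tray_ct = scene.tray_mesh.copy()
        tray_ct.apply_transform(scene.tray_to_tibia.matrix)
        implant = mesh_to_binary_stack(tray_ct, scene.grid)
        once = fill_interface(scene.tibia_mask_initial, implant,
                              scene.grid.spacing, 3.0)
        twice = fill_interface(once, implant, scene.grid.spacing, 3.0)
        assert np.array_equal(once, twice)

    def test_closes_phantom_interface(self, coarse_scene):
        scene = coarse_scene
        dome_ct = scene.dome_mesh.copy()
        dome_ct.apply_transform(scene.dome_to_talus.matrix)
        implant = mesh_to_binary_stack(dome_ct, scene.grid)
        filled = fill_interface(scene.talus_mask_initial, implant,
                                scene.grid.spacing, 3.0)
        from scipy import ndimage
        assert (ndimage.binary_dilation(filled) & implant).any()


class TestAssembleHybridDrr:
    def setup_drrs(self):
        grid = Grid((16, 16, 16), (1, 1, 1), (0, 0, 0))
        bone = np.zeros(grid.shape, np.float32)
        bone[2:8, 2:14, 2:14] = 1000.0
        implant = np.zeros(grid.shape, np.float32)
        implant[10:14, 4:12, 4:12] = 1.0
        return (DRRVolume(bone, grid, "bone"),
                DRRVolume(implant, grid, "implant"))

    def test_identity_link_disjoint_supports_merge(self):
        bone, implant = self.setup_drrs()
        link = RigidTransform.identity("cad", "ct")
        out = assemble_hybrid_drr(bone, implant, link)
        assert out.provenance == "hybrid"
        # bone voxels dimmed to 60 %, implant edge at the magnified value
        assert out.intensities[3, 3, 3] == pytest.approx(600.0)
        expected_edge = IMPLANT_REFERENCE_INTENSITY * IMPLANT_INTENSITY_GAIN
        assert out.intensities.max() == pytest.approx(expected_edge)
        support = bone.support | implant.support
        assert np.array_equal(out.support, support)

    def test_implant_wins_where_coincident(self):
        bone, implant = self.setup_drrs()
        implant.intensities[3, 3, 3] = 1.0  # overlap one bone voxel
        out = assemble_hybrid_drr(bone, implant,
                                  RigidTransform.identity("cad", "ct"))
        expected_edge = IMPLANT_REFERENCE_INTENSITY * IMPLANT_INTENSITY_GAIN
        assert out.intensities[3, 3, 3] == pytest.approx(expected_edge)

    def test_implant_leaving_grid_raises(self):
        bone, implant = self.setup_drrs()
        link = RigidTransform(np.eye(3), [0, 0, 40.0], "cad", "ct")
        with pytest.raises(ValueError, match="clipped"):
            assemble_hybrid_drr(bone, implant, link)

    def test_phantom_hybrid_max_is_magnified_implant(self, coarse_scene):
        scene = coarse_scene
        bone_drr = isolate_bone(scene.volume, scene.tibia_mask)
        tray_mask = mesh_to_binary_stack(
            scene.tray_mesh, Grid((40, 40, 24), scene.grid.spacing,
                                  scene.tray_mesh.bounds[0] - 2.0))
        implant_drr = DRRVolume(hollow_implant(tray_mask).astype(np.float32),
                                Grid((40, 40, 24), scene.grid.spacing,
                                     scene.tray_mesh.bounds[0] - 2.0),
                                "implant")
        out = assemble_hybrid_drr(bone_drr, implant_drr, scene.tray_to_tibia)
        assert out.intensities.max() == pytest.approx(
            IMPLANT_REFERENCE_INTENSITY * IMPLANT_INTENSITY_GAIN)


def test_hybrid_bundle_roundtrip(tmp_path, coarse_scene):
    scene = coarse_scene
    bone_drr = isolate_bone(scene.volume, scene.tibia_mask)
    grid = Grid((40, 40, 24), scene.grid.spacing,
                scene.tray_mesh.bounds[0] - 2.0)
    tray_mask = mesh_to_binary_stack(scene.tray_mesh, grid)
    implant_drr = DRRVolume(hollow_implant(tray_mask).astype(np.float32),
                            grid, "implant")
    hybrid_drr = assemble_hybrid_drr(bone_drr, implant_drr,
                                     scene.tray_to_tibia)
    hollow_ct = mesh_to_binary_stack(
        scene.tray_mesh, scene.grid)  # placeholder hollow mask on CT grid
    model = HybridModel(scene.tibia_mesh, scene.tibia_mask, scene.tray_mesh,
                        hollow_implant(hollow_ct).astype(bool),
                        scene.tray_to_tibia, hybrid_drr, "left")
    model.save(tmp_path / "bundle")
    back = HybridModel.load(tmp_path / "bundle")
    assert back.side == "left"
    assert np.allclose(back.link.matrix, model.link.matrix, atol=1e-9)
    assert np.allclose(back.drr.intensities, model.drr.intensities, atol=1e-3)
    assert np.array_equal(back.bone_mask, model.bone_mask)
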