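"""Synthetic phantom: volume construction, artifact, trajectory, rendering."""

import hashlib

import numpy as np
import pytest

from tartrack.kinematics import joint_angle_series
from tartrack.frames import build_talus_frame, build_tibia_frame
from tartrack.phantom import (PhantomConfig, PhantomConfigError,
                              build_phantom, render_fluoro_sequence,
                              simulate_metal_artifact,
                              synthesize_gait_trajectory)
from tartrack.projection import default_biplane_rig, project_volume

from conftest import COARSE


class TestBuildPhantom:
    def test_deterministic_for_fixed_seed(self, coarse_scene, coarse_config):
        again, vol2 = build_phantom(coarse_config, seed=0)
        h1 = hashlib.sha256(coarse_scene.volume.intensities.tobytes()).hexdigest()
        h2 = hashlib.sha256(vol2.intensities.tobytes()).hexdigest()
        assert h1 == h2
        assert np.array_equal(coarse_scene.tibia_mask, again.tibia_mask)

    def test_intensity_tiers_present(self, coarse_scene):
        cfg = coarse_scene.config
        vals = coarse_scene.clean_volume.intensities
        assert vals.max() == cfg.implant_intensity
        assert (vals == cfg.cortical_intensity).any()
        assert (vals == cfg.trabecular_intensity).any()
        assert (vals == cfg.soft_tissue_intensity).any()

    def test_zero_implant_config_has_no_metal(self):
        cfg = PhantomConfig(**COARSE, include_implants=False)
        _scene, vol = build_phantom(cfg, seed=0)
        assert vol.intensities.max() <= cfg.cortical_intensity

    def test_implants_and_bones_disjoint(self, coarse_scene):
        assert not (coarse_scene.tibia_mask & coarse_scene.tray_mask).any()
        assert not (coarse_scene.talus_mask & coarse_scene.dome_mask).any()

    def test_initial_segmentation_stops_short_of_implants(self, coarse_scene):
        assert coarse_scene.tibia_mask_initial.sum() < coarse_scene.tibia_mask.sum()
        assert not (coarse_scene.tibia_mask_initial
                    & ~coarse_scene.tibia_mask).any()

    def test_implant_meshes_watertight(self, coarse_scene):
        for mesh in (coarse_scene.tray_mesh, coarse_scene.insert_mesh,
                     coarse_scene.dome_mesh):
            assert mesh.is_watertight

    def test_oversized_implant_rejected(self):
        with pytest.raises(PhantomConfigError):
            PhantomConfig(**COARSE, tray_half_width=20.0).validate()


class TestMetalArtifact:
    def test_zero_strength_is_identity(self, coarse_scene):
        out = simulate_metal_artifact(coarse_scene.clean_volume,
                                      coarse_scene.tray_mask, strength=0.0)
        assert np.array_equal(out.intensities,
                              coarse_scene.clean_volume.intensities)

    def test_corruption_confined_to_band(self, coarse_scene):
        from scipy import ndimage
        band_mm = 5.0
        mask = coarse_scene.tray_mask | coarse_scene.dome_mask
        out = simulate_metal_artifact(coarse_scene.clean_volume, mask,
                                      strength=1.0, band_mm=band_mm, seed=1)
        changed = out.intensities != coarse_scene.clean_volume.intensities
        dist = ndimage.distance_transform_edt(
            ~mask, sampling=coarse_scene.grid.spacing)
        assert not changed[dist > band_mm].any()
        assert changed[(dist > 0) & (dist <= band_mm)].any()

    def test_corruption_monotone_in_strength(self, coarse_scene):
        mask = coarse_scene.tray_mask
        clean = coarse_scene.clean_volume
        means = []
        for strength in (0.5, 1.0, 2.0):
            out = simulate_metal_artifact(clean, mask, strength, seed=3)
            means.append(np.abs(out.intensities - clean.intensities).mean())
        assert means[0] < means[1] < means[2]

    def test_negative_strength_rejected(self, coarse_scene):
        with pytest.raises(ValueError):
            simulate_metal_artifact(coarse_scene.clean_volume,
                                    coarse_scene.tray_mask, strength=-1.0)


class TestGaitTrajectory:
    def test_seeded_call_reproducible(self, coarse_scene):
        a = synthesize_gait_trajectory(coarse_scene, seed=5, n_stance_frames=10)
        b = synthesize_gait_trajectory(coarse_scene, seed=5, n_stance_frames=10)
        for pa, pb in zip(a.talus_poses, b.talus_poses):
            assert np.array_equal(pa.rotation, pb.rotation)
            assert np.array_equal(pa.translation, pb.translation)

    def test_true_angles_self_consistent_with_kinematics(self, coarse_scene,
                                                         coarse_trajectory):
        tf = build_tibia_frame(coarse_scene.tibia_frame_selections(), "left")
        lf = build_talus_frame(coarse_scene.talus_frame_selections(), "left")
        ja = joint_angle_series(coarse_trajectory.tibia_poses,
                                coarse_trajectory.talus_poses, tf, lf)
        for k, v in ja.as_dict().items():
            assert np.max(np.abs(v - coarse_trajectory.true_angles_deg[k])) \
                < 1e-6

    def test_force_crosses_five_percent_exactly_twice(self, coarse_trajectory):
        f = coarse_trajectory.force_n
        thr = 0.05 * f.max()
        crossings = np.sum(np.diff((f > thr).astype(int)) != 0)
        assert crossings == 2
        assert (f >= 0).all()

    def test_pose_continuity_at_full_frame_rate(self, coarse_scene):
        from tartrack.geometry import rotation_angle_deg
        traj = synthesize_gait_trajectory(coarse_scene, seed=2,
                                          n_stance_frames=140,
                                          frame_rate_hz=200.0)
        for poses in (traj.tibia_poses, traj.talus_poses):
            for a, b in zip(poses, poses[1:]):
                assert rotation_angle_deg(a.rotation.T @ b.rotation) < 3.0
                assert np.linalg.norm(b.translation - a.translation) < 3.0

    def test_invalid_stance_duration_rejected(self, coarse_config):
        with pytest.raises(PhantomConfigError):
            PhantomConfig(**COARSE, stance_duration_s=-0.5).validate()


@pytest.fixture(scope="module")
def short_render(coarse_scene):
    traj = synthesize_gait_trajectory(coarse_scene, seed=2, n_stance_frames=2)
    cams = default_biplane_rig((0.0, 0.0, 35.0), resolution=96, fov_mm=140)
    stacks = render_fluoro_sequence(coarse_scene, traj, cams, seed=0)
    return traj, cams, stacks


class TestRenderFluoroSequence:
    def test_shapes_and_nonempty(self, short_render):
        traj, cams, stacks = short_render
        assert len(stacks) == 2
        assert stacks[0].shape == (traj.n_frames, 96, 96)
        assert stacks[0].max() > 0

    def test_silhouette_consistent_with_reprojected_mask(self, coarse_scene,
                                                         short_render):
        traj, cams, stacks = short_render
        grid = coarse_scene.grid
        tib = (coarse_scene.tibia_mask | coarse_scene.tray_mask)
        tal = (coarse_scene.talus_mask | coarse_scene.dome_mask)
        sil_mask = (
            project_volume(tib.astype(np.float32), grid,
                           traj.tibia_poses[0].transform, cams[0]) > 0) | (
            project_volume(tal.astype(np.float32), grid,
                           traj.talus_poses[0].transform, cams[0]) > 0)
        rendered = stacks[0][0] > 0
        dice = 2 * (sil_mask & rendered).sum() / (sil_mask.sum() + rendered.sum())
        assert dice > 0.95

    def test_poisson_noise_is_seeded(self, coarse_scene):
        traj = synthesize_gait_trajectory(coarse_scene, seed=2,
                                          n_stance_frames=2)
        cams = default_biplane_rig((0.0, 0.0, 35.0), resolution=64, fov_mm=140)
        a = render_fluoro_sequence(coarse_scene, traj, cams,
                                   poisson_noise=True, seed=9)
        b = render_fluoro_sequence(coarse_scene, traj, cams,
                                   poisson_noise=True, seed=9)
        c = render_fluoro_sequence(coarse_scene, traj, cams,
                                   poisson_noise=True, seed=10)
        assert np.array_equal(a[0], b[0])
        assert not np.array_equal(a[0], c[0])

    def test_single_camera_rejected(self, coarse_scene, coarse_trajectory):
        cams = default_biplane_rig((0, 0, 35.0), resolution=32)
        with pytest.raises(ValueError):
            render_fluoro_sequence(coarse_scene, coarse_trajectory, cams[:1])
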