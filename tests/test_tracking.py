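"""Model-based tracking: edge images, cost function, frame optimization.

Heavy multi-frame accuracy checks live in the acceptance suite; here the
tracker is exercised on a small single-object phantom where each contract
can be verified in seconds.
"""

import numpy as np
import pytest

from tartrack.drr import DRRVolume
from tartrack.geometry import Pose, RigidTransform, rotation_angle_deg
from tartrack.projection import default_biplane_rig, project_volume
from tartrack.tracking import (CompoundDRR, pose_cost, project_drr,
                               sobel_edges, track_frame, track_sequence)
from tartrack.volume import Grid


@pytest.fixture(scope="module")
def ball_setup():
    """A small two-ball rigid object imaged by a tiny biplane rig."""
    grid = Grid((40, 40, 40), (1.2, 1.2, 1.2), (-23.4, -23.4, -23.4))
    ii, jj, kk = np.mgrid[0:40, 0:40, 0:40]
    vol = np.zeros(grid.shape, np.float32)
    vol[(ii - 14) ** 2 + (jj - 20) ** 2 + (kk - 20) ** 2 <= 49] = 800.0
    vol[22:32, 18:26, 12:20] = 1500.0  # box: pins every rotation axis
    drr = DRRVolume(vol, grid, "bone")
    cams = default_biplane_rig((0, 0, 0), resolution=96, fov_mm=80)
    truth = RigidTransform(np.eye(3), [1.0, -2.0, 0.5], "ct", "mbt")
    images = [project_volume(vol, grid, truth, c) for c in cams]
    return drr, cams, truth, images


class TestSobelEdges:
    def test_constant_image_gives_zeros(self):
        assert not sobel_edges(np.full((16, 16), 5.0)).any()

    def test_vertical_step_edge_peaks_on_the_edge(self):
        img = np.zeros((16, 16), np.float32)
        img[:, 8:] = 1.0
        edges = sobel_edges(img)
        assert edges[:, 7:9].max() == pytest.approx(1.0)
        assert edges[:, :5].max() == 0.0
        assert edges[:, 11:].max() == 0.0

    def test_matches_direct_convolution_oracle(self, rng):
        from scipy.ndimage import convolve
        img = rng.random((24, 24)).astype(np.float32)
        kx = np.array([[1, 0, -1], [2, 0, -2], [1, 0, -1]]) / 8.0
        gx = convolve(img, kx, mode="reflect")
        gy = convolve(img, kx.T, mode="reflect")
        mag = np.hypot(gx, gy)
        expected = mag / mag.max()
        assert np.allclose(sobel_edges(img), expected, atol=1e-5)

    def test_tiny_image_rejected(self):
        with pytest.raises(ValueError):
            sobel_edges(np.zeros((2, 5)))


class TestPoseCost:
    def test_own_projection_scores_zero(self, ball_setup):
        drr, cams, truth, images = ball_setup
        assert pose_cost(truth, drr, images, cams) < 1e-6

    def test_uncorrelated_noise_scores_near_one(self, ball_setup):
        drr, cams, truth, _ = ball_setup
        costs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            noise = [rng.random((96, 96)).astype(np.float32) for _ in range(2)]
            costs.append(pose_cost(truth, drr, noise, cams))
        assert np.mean(costs) == pytest.approx(1.0, abs=0.1)

    def test_truth_beats_two_millimetre_offset(self, ball_setup):
        drr, cams, truth, images = ball_setup
        wins = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            d = rng.normal(size=3)
            d *= 2.0 / np.linalg.norm(d)
            off = RigidTransform(truth.rotation, truth.translation + d,
                                 "ct", "mbt")
            wins += (pose_cost(truth, drr, images, cams)
                     < pose_cost(off, drr, images, cams))
        assert wins >= 38  # >= 95 %

    def test_view_count_enforced(self, ball_setup):
        drr, cams, truth, images = ball_setup
        with pytest.raises(ValueError):
            pose_cost(truth, drr, images[:1], cams[:1])

    def test_invariant_under_joint_rigid_motion(self, ball_setup, rng):
        # moving scene and cameras together leaves the cost unchanged
        from conftest import random_rotation
        from tartrack.projection import CameraModel
        drr, cams, truth, images = ball_setup
        R = random_rotation(rng)
        t = rng.normal(scale=15, size=3)
        moved_cams = tuple(
            CameraModel(R @ c.source + t, R @ c.detector_origin + t,
                        R @ c.u_axis, R @ c.v_axis, c.pixel_pitch_mm,
                        c.resolution) for c in cams)
        moved_truth = RigidTransform(R @ truth.rotation,
                                     R @ truth.translation + t, "ct", "mbt")
        base = pose_cost(truth, drr, images, cams)
        moved = pose_cost(moved_truth, drr, images, moved_cams)
        assert moved == pytest.approx(base, abs=1e-5)


class TestTrackFrame:
    def test_init_at_truth_stays_at_truth(self, ball_setup):
        drr, cams, truth, images = ball_setup
        pose, cost, flags = track_frame(drr, images, cams, Pose(truth),
                                        seed=0, n_restarts=0, max_evals=80)
        assert np.linalg.norm(pose.translation - truth.translation) < 1e-3
        assert rotation_angle_deg(pose.rotation.T @ truth.rotation) < 1e-2
        assert not flags["review"]

    def test_two_millimetre_offset_recovered(self, ball_setup):
        drr, cams, truth, images = ball_setup
        from tartrack.tracking import _rotvec_matrix
        init = Pose(RigidTransform(
            _rotvec_matrix(np.array([1.2, -0.9, 0.8])) @ truth.rotation,
            truth.translation + [1.2, -1.0, 0.9], "ct", "mbt"))
        pose, cost, flags = track_frame(drr, images, cams, init, seed=0,
                                        n_restarts=1, max_evals=400)
        assert np.linalg.norm(pose.translation - truth.translation) < 0.3
        assert rotation_angle_deg(pose.rotation.T @ truth.rotation) < 0.63

    def test_far_initialization_raises_review_flag(self, ball_setup):
        drr, cams, truth, images = ball_setup
        init = Pose(RigidTransform(truth.rotation,
                                   truth.translation + [20.0, 0, 0],
                                   "ct", "mbt"))
        _pose, cost, flags = track_frame(drr, images, cams, init, seed=0,
                                         n_restarts=1, max_evals=60)
        assert flags["review"]


class TestTrackSequence:
    def test_static_sequence_has_tiny_pose_variance(self, ball_setup):
        drr, cams, truth, images = ball_setup
        stacks = (np.stack([images[0]] * 3), np.stack([images[1]] * 3))
        result = track_sequence(drr, stacks, cams, Pose(truth), seed=0,
                                n_restarts=0, max_evals=60)
        ts = np.stack([p.translation for p in result.poses])
        assert ts.std(axis=0).max() < 0.1
        angs = [rotation_angle_deg(result.poses[0].rotation.T @ p.rotation)
                for p in result.poses[1:]]
        assert max(angs) < 0.1

    def test_single_frame_equals_track_frame(self, ball_setup):
        drr, cams, truth, images = ball_setup
        stacks = (images[0][None], images[1][None])
        result = track_sequence(drr, stacks, cams, Pose(truth), seed=0,
                                n_restarts=0, max_evals=60)
        pose, cost, _ = track_frame(drr, images, cams, Pose(truth), seed=0,
                                    n_restarts=0, max_evals=60)
        assert np.allclose(result.poses[0].translation, pose.translation,
                           atol=1e-9)
        assert result.costs[0] == pytest.approx(cost)

    def test_empty_sequence_raises(self, ball_setup):
        drr, cams, truth, _ = ball_setup
        with pytest.raises(ValueError):
            track_sequence(drr, (np.empty((0, 8, 8)), np.empty((0, 8, 8))),
                           cams, Pose(truth))

    def test_review_report_lists_flagged_frames(self, ball_setup):
        drr, cams, truth, images = ball_setup
        bad = [np.random.default_rng(0).random(im.shape).astype(np.float32)
               for im in images]
        stacks = (np.stack([images[0], bad[0]]), np.stack([images[1], bad[1]]))
        result = track_sequence(drr, stacks, cams, Pose(truth), seed=0,
                                n_restarts=0, max_evals=40)
        report = result.review_report()
        assert report["n_frames"] == 2
        assert 1 in report["flagged_frames"]


def test_compound_drr_projection_matches_sum(ball_setup, rng):
    drr, cams, truth, _ = ball_setup
    offset = RigidTransform(np.eye(3), [4.0, 0.0, -2.0], "cad", "ct")
    compound = CompoundDRR([(drr, None), (drr, offset)])
    img = project_drr(compound, truth, cams[0])
    from tartrack.geometry import compose
    expect = (project_drr(drr, truth, cams[0])
              + project_drr(drr, compose(truth, offset), cams[0]))
    assert np.allclose(img, expect, rtol=1e-5, atol=1e-3)


class TestRegisterStatic:
    def test_init_at_truth_returns_truth(self, ball_setup):
        from tartrack.hybrid import register_static
        drr, cams, truth, images = ball_setup
        mean = register_static(drr, [images], cams, Pose(truth), seed=0,
                               n_restarts=0, max_evals=60)
        assert np.linalg.norm(mean.translation - truth.translation) < 1e-3
        assert rotation_angle_deg(mean.rotation.T @ truth.rotation) < 1e-2

    def test_single_frame_equals_track_frame(self, ball_setup):
        from tartrack.hybrid import register_static
        drr, cams, truth, images = ball_setup
        mean = register_static(drr, [images], cams, Pose(truth), seed=0,
                               n_restarts=0, max_evals=60)
        pose, _c, _f = track_frame(drr, images, cams, Pose(truth), seed=0,
                                   n_restarts=0, max_evals=60)
        assert np.allclose(mean.translation, pose.translation, atol=1e-9)
        assert np.allclose(mean.rotation, pose.rotation, atol=1e-9)

    def test_majority_failure_raises(self, ball_setup):
        from tartrack.hybrid import StaticTrackingError, register_static
        drr, cams, truth, images = ball_setup
        noise = [np.random.default_rng(0).random(im.shape).astype(np.float32)
                 for im in images]
        with pytest.raises(StaticTrackingError):
            register_static(drr, [noise, noise], cams, Pose(truth), seed=0,
                            n_restarts=0, max_evals=30)

    def test_frame_count_bounds(self, ball_setup):
        from tartrack.hybrid import register_static
        drr, cams, truth, images = ball_setup
        with pytest.raises(ValueError):
            register_static(drr, [], cams, Pose(truth))
        with pytest.raises(ValueError):
            register_static(drr, [images] * 21, cams, Pose(truth))
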