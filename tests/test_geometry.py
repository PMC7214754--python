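"""Rigid-transform algebra, frame transforms and static pose averaging."""

import numpy as np
import pytest

from tartrack.geometry import (CoordinateFrame, RigidTransform, Pose,
                               ChainingError, InvalidFrameError, GLOBAL_FRAME,
                               average_poses, compose, invert, standard_frame,
                               transform_ct_to_global, transform_global_to_mbt,
                               rotation_angle_deg, poses_to_csv, poses_from_csv)

from conftest import random_rotation


def rot_z(deg):
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def rot_x(deg):
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


class TestCoordinateFrame:
    def test_rejects_non_unit_basis(self):
        with pytest.raises(InvalidFrameError):
            CoordinateFrame(np.zeros(3), np.eye(3) * 2.0)

    def test_rejects_non_orthogonal_basis(self):
        basis = np.eye(3)
        basis[1] = [0.8, 0.6, 0.0]
        with pytest.raises(InvalidFrameError):
            CoordinateFrame(np.zeros(3), basis)

    def test_handedness_recorded(self):
        left = np.diag([-1.0, 1.0, 1.0])
        assert CoordinateFrame(np.zeros(3), left).handedness == -1
        assert standard_frame().handedness == 1


class TestCtToGlobal:
    def test_identical_frames_give_identity(self):
        f = standard_frame((3.0, 4.0, 5.0))
        T = transform_ct_to_global(f, f)
        assert np.allclose(T.rotation, np.eye(3))
        assert np.allclose(T.translation, 0.0)

    def test_standard_basis_reduces_to_identity_rotation(self):
        # bounding-box frames share the global basis, so the rotation is I
        # and the translation is the origin difference
        ct = standard_frame((10.0, 20.0, 30.0), "ct")
        T = transform_ct_to_global(ct, GLOBAL_FRAME)
        assert np.allclose(T.rotation, np.eye(3))
        assert np.allclose(T.translation, [-10.0, -20.0, -30.0])

    def test_rotated_ct_basis_against_point_mapping_oracle(self, rng):
        R30 = rot_z(30.0)
        origin = np.array([5.0, -2.0, 7.0])
        ct = CoordinateFrame(origin, R30.T)  # rows = rotated axes
        T = transform_ct_to_global(ct)
        pts = rng.normal(scale=40.0, size=(100, 3))
        # oracle: a point embedded at CT-local coordinates x maps to the
        # point with the same global-local coordinates, i.e. to x itself
        assert np.allclose(T.apply(ct.embed(pts)), pts, atol=1e-9)
        # the frame-alignment map takes the CT origin to the global origin
        # and CT axes onto global axes
        assert np.allclose(T.apply(origin), np.zeros(3), atol=1e-9)
        assert np.allclose(T.apply(origin + ct.basis[0]), [1, 0, 0], atol=1e-9)


class TestGlobalToMbt:
    def test_identity(self):
        assert np.allclose(
            transform_global_to_mbt(standard_frame()).matrix, np.eye(4))

    def test_rx90_frame_against_point_mapping_oracle(self):
        R = rot_x(90.0)
        frame = CoordinateFrame([1.0, 0.0, 0.0], R.T)
        T = transform_global_to_mbt(frame)
        assert np.allclose(T.rotation, R, atol=1e-9)
        assert np.allclose(T.translation, [1.0, 0.0, 0.0], atol=1e-9)
        # mapping the global origin lands on the tracked frame's origin,
        # and global axes land on the tracked axes
        assert np.allclose(T.apply(np.zeros(3)), frame.origin, atol=1e-9)
        assert np.allclose(T.apply([0, 0, 1.0]), frame.origin + frame.basis[2],
                           atol=1e-9)

    def test_chain_matches_compose(self):
        ct = standard_frame((2.0, 3.0, 4.0), "ct")
        mbt = CoordinateFrame([1.0, -1.0, 0.5], rot_z(40.0).T, "mbt")
        chained = compose(transform_global_to_mbt(mbt),
                          transform_ct_to_global(ct))
        assert chained.source_space == "ct"
        assert chained.target_space == "mbt"


class TestComposeInvert:
    def test_compose_with_identity(self, rng):
        T = RigidTransform(random_rotation(rng), rng.normal(size=3), "ct", "mbt")
        I = RigidTransform.identity("ct", "ct")
        assert np.allclose(compose(T, I).matrix, T.matrix)

    def test_compose_matches_sequential_application(self, rng):
        A = RigidTransform(rot_x(90.0), [0.0, 1.0, 2.0], "global", "mbt")
        B = RigidTransform(rot_z(90.0), [1.0, 0.0, 0.0], "ct", "global")
        pts = rng.normal(size=(50, 3))
        assert np.allclose(compose(A, B).apply(pts), A.apply(B.apply(pts)),
                           atol=1e-12)

    def test_label_mismatch_raises(self):
        A = RigidTransform.identity("global", "mbt")
        B = RigidTransform.identity("ct", "ct")
        with pytest.raises(ChainingError):
            compose(A, B)

    def test_inverse_roundtrip_and_linear_solve_oracle(self, rng):
        T = RigidTransform(random_rotation(rng), rng.normal(size=3), "ct", "mbt")
        assert np.allclose(compose(invert(T), T).matrix, np.eye(4), atol=1e-9)
        assert np.allclose(invert(invert(T)).matrix, T.matrix, atol=1e-9)
        pts = rng.normal(size=(100, 3))
        # oracle: invert(T) @ p solves T x = p for each point
        solved = np.linalg.solve(
            np.broadcast_to(T.rotation, (100, 3, 3)),
            (pts - T.translation)[..., None])[..., 0]
        assert np.allclose(invert(T).apply(pts), solved, atol=1e-9)

    def test_mesh_roundtrip_ct_mbt_ct(self, rng, coarse_scene):
        T = RigidTransform(random_rotation(rng), rng.normal(size=3), "ct", "mbt")
        verts = coarse_scene.tibia_mesh.vertices
        back = invert(T).apply(T.apply(verts))
        assert np.max(np.abs(back - verts)) < 1e-9

    def test_determinant_preserved_under_algebra(self, rng):
        T = RigidTransform(random_rotation(rng), rng.normal(size=3), "a", "b")
        U = RigidTransform(random_rotation(rng), rng.normal(size=3), "b", "c")
        for X in (compose(U, T), invert(T)):
            assert np.linalg.det(X.rotation) == pytest.approx(1.0, abs=1e-9)


class TestAveragePoses:
    def test_single_and_identical_poses(self, rng):
        T = RigidTransform(random_rotation(rng), rng.normal(size=3))
        poses = [Pose(T, i) for i in range(20)]
        mean = average_poses(poses)
        assert np.allclose(mean.rotation, T.rotation, atol=1e-9)
        assert np.allclose(mean.translation, T.translation, atol=1e-12)
        single = average_poses(poses[:1])
        assert np.allclose(single.rotation, T.rotation, atol=1e-12)

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            average_poses([])

    def test_noisy_static_trial_mean_recovers_truth(self):
        # 100 seeded replicates of 20 poses jittered by sigma = 0.5 deg:
        # the quaternion eigen-mean should land within 0.3 deg of truth
        base = np.random.default_rng(0)
        truth = random_rotation(base)
        worst = 0.0
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            poses = []
            for i in range(20):
                axis = rng.normal(size=3)
                axis /= np.linalg.norm(axis)
                ang = np.radians(rng.normal(scale=0.5))
                K = np.array([[0, -axis[2], axis[1]],
                              [axis[2], 0, -axis[0]],
                              [-axis[1], axis[0], 0]])
                dR = (np.eye(3) + np.sin(ang) * K
                      + (1 - np.cos(ang)) * K @ K)
                poses.append(Pose(RigidTransform(dR @ truth, np.zeros(3)), i))
            mean = average_poses(poses)
            worst = max(worst, rotation_angle_deg(mean.rotation.T @ truth))
        assert worst < 0.3

    def test_widely_spread_rotations_warn(self):
        poses = [Pose(RigidTransform(np.eye(3), np.zeros(3)), 0),
                 Pose(RigidTransform(rot_z(45.0), np.zeros(3)), 1)]
        with pytest.warns(UserWarning, match="spread"):
            average_poses(poses)


def test_pose_csv_roundtrip(tmp_path, rng):
    poses = [Pose(RigidTransform(random_rotation(rng), rng.normal(size=3)),
                  i, frame_rate_hz=200.0) for i in range(5)]
    path = tmp_path / "poses.csv"
    poses_to_csv(poses, path)
    back = poses_from_csv(path)
    for a, b in zip(poses, back):
        assert np.allclose(a.rotation, b.rotation, atol=1e-9)
        assert np.allclose(a.translation, b.translation, atol=1e-9)
        assert a.frame_index == b.frame_index
        assert a.timestamp == pytest.approx(b.timestamp)


# -- property-based checks ---------------------------------------------------

from hypothesis import given, settings, strategies as st


@settings(max_examples=50, deadline=None, derandomize=True)
@given(rotvec=st.lists(st.floats(-3.0, 3.0), min_size=3, max_size=3),
       translation=st.lists(st.floats(-100.0, 100.0), min_size=3, max_size=3),
       point=st.lists(st.floats(-50.0, 50.0), min_size=3, max_size=3))
def test_rigid_roundtrip_property(rotvec, translation, point):
    """invert(T) ∘ T is the identity for any proper rigid transform."""
    from scipy.spatial.transform import Rotation
    R = Rotation.from_rotvec(rotvec).as_matrix()
    T = RigidTransform(R, translation, "ct", "mbt")
    p = np.asarray(point)
    assert np.allclose(invert(T).apply(T.apply(p)), p, atol=1e-9)
    assert np.linalg.det(compose(invert(T), T).rotation) == pytest.approx(
        1.0, abs=1e-9)
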