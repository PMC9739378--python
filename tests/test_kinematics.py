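import numpy as np
import pytest

from gaitblur import (ANGLE_NAMES, GaitConfig, KeypointSet, compute_all_angles,
                      compute_frame_angles, euler_zxy, generate_gait_sequence,
                      shoulder_frame, trunk_frame, vector_angle_pair)
from gaitblur.errors import GeometryError
from gaitblur.keypoints import KEYPOINT_INDEX
from gaitblur.kinematics import Frame3D, compose_zxy, elbow_flexion, neck_angles

from conftest import random_rotation


def _pose_from(neutral, **overrides):
    xyz = neutral.sequence.data[0].copy()
    for name, value in overrides.items():
        xyz[KEYPOINT_INDEX[name]] = value
    return KeypointSet(xyz)


# --- trunk and shoulder frames ---------------------------------------------

def test_trunk_frame_axis_aligned_example():
    xyz = np.zeros((17, 3))
    xyz[KEYPOINT_INDEX["N"]] = [0, 500, 0]
    xyz[KEYPOINT_INDEX["HR"]] = [100, 0, 0]
    xyz[KEYPOINT_INDEX["HL"]] = [-100, 0, 0]
    # keep the remaining points non-degenerate but irrelevant
    xyz[KEYPOINT_INDEX["H"]] = [0, 700, 0]
    f = trunk_frame(KeypointSet(xyz))
    np.testing.assert_allclose(f.Y, [0, 1, 0], atol=1e-12)
    np.testing.assert_allclose(f.X, [0, 0, 1], atol=1e-12)
    np.testing.assert_allclose(f.Z, [-1, 0, 0], atol=1e-12)
    np.testing.assert_allclose(f.origin, [0, 0, 0], atol=1e-12)


def test_trunk_frame_degenerate_geometry_raises():
    xyz = np.zeros((17, 3))
    xyz[KEYPOINT_INDEX["N"]] = [0, 500, 0]
    xyz[KEYPOINT_INDEX["HR"]] = [0, -100, 0]   # hip line parallel to HC->N
    xyz[KEYPOINT_INDEX["HL"]] = [0, 100, 0]
    with pytest.raises(GeometryError):
        trunk_frame(KeypointSet(xyz))


def test_frames_satisfy_orthonormality_invariants(short_gait):
    for i in range(0, short_gait.sequence.n_frames, 13):
        kp = short_gait.sequence.frame(i)
        for frame in (trunk_frame(kp), shoulder_frame(kp, "right"),
                      shoulder_frame(kp, "left")):
            M = frame.basis
            np.testing.assert_allclose(M.T @ M, np.eye(3), atol=1e-9)
            assert np.linalg.det(M) == pytest.approx(1.0, abs=1e-9)


def test_frame_equivariance_under_rigid_motion(short_gait, rng):
    """Rotating all keypoints rotates trunk/shoulder frames identically."""
    kp = short_gait.sequence.frame(7)
    for _ in range(20):
        Q = random_rotation(rng)
        t = rng.normal(scale=500.0, size=3)
        kp2 = KeypointSet(kp.xyz @ Q.T + t)
        for builder in (trunk_frame, lambda p: shoulder_frame(p, "right")):
            f1, f2 = builder(kp), builder(kp2)
            np.testing.assert_allclose(f2.basis, Q @ f1.basis, atol=1e-9)


def test_straight_arm_falls_back_to_trunk_axis(neutral_pose):
    kp0 = neutral_pose.sequence.frame(0)
    s = kp0.get("SR")
    kp = _pose_from(neutral_pose, ER=s + [0, -300, 0], WR=s + [0, -550, 0])
    trunk = trunk_frame(kp)
    f = shoulder_frame(kp, "right", trunk=trunk)
    np.testing.assert_allclose(f.basis.T @ f.basis, np.eye(3), atol=1e-9)
    with pytest.raises(GeometryError):
        shoulder_frame(kp, "right")          # no trunk frame to resolve it


# --- Euler ZXY ---------------------------------------------------------------

def test_euler_identity_and_known_composition():
    assert euler_zxy(np.eye(3)) == pytest.approx((0.0, 0.0, 0.0))
    z, x, y = euler_zxy(compose_zxy(30.0, 10.0, -20.0))
    assert (z, x, y) == pytest.approx((30.0, 10.0, -20.0), abs=1e-9)


def test_euler_round_trip_on_random_rotations(rng):
    """1000 random rotations recompose within 1e-9 Frobenius."""
    worst = 0.0
    for _ in range(1000):
        R = random_rotation(rng)
        z, x, y = euler_zxy(R)
        worst = max(worst, np.linalg.norm(compose_zxy(z, x, y) - R))
    assert worst < 1e-9


def test_euler_angle_round_trip_away_from_gimbal(rng):
    for _ in range(1000):
        z, x, y = rng.uniform(-179, 179), rng.uniform(-89, 89), rng.uniform(-179, 179)
        got = euler_zxy(compose_zxy(z, x, y))
        np.testing.assert_allclose(got, (z, x, y), atol=1e-8)


def test_euler_gimbal_lock_convention():
    R = compose_zxy(25.0, 90.0, 10.0)
    z, x, y = euler_zxy(R)
    assert x == pytest.approx(90.0, abs=1e-6)
    assert y == 0.0
    np.testing.assert_allclose(compose_zxy(z, x, y), R, atol=1e-9)


# --- individual angles -------------------------------------------------------

def test_vector_angle_pair_basics():
    assert vector_angle_pair([1, 2, 3], [1, 2, 3]) == 0.0
    assert vector_angle_pair([1, 0, 0], [0, 1, 0]) == pytest.approx(90.0)
    # clamping at the antipodal boundary must not produce NaN
    assert vector_angle_pair([1, 0, 0], [-1, 1e-16, 0]) == pytest.approx(180.0)
    with pytest.raises(GeometryError):
        vector_angle_pair([0, 0, 0], [1, 0, 0])


def test_elbow_angles_straight_and_right_angle(neutral_pose):
    kp0 = neutral_pose.sequence.frame(0)
    s = kp0.get("SR")
    straight = _pose_from(neutral_pose, ER=s + [0, -300, 0], WR=s + [0, -600, 0])
    assert elbow_flexion(straight, "right") == pytest.approx(0.0, abs=1e-9)
    bent = _pose_from(neutral_pose, ER=s + [0, -300, 0], WR=s + [0, -300, 250])
    assert elbow_flexion(bent, "right") == pytest.approx(90.0, abs=1e-9)


def test_neck_tilt_decomposes_into_flexion_and_side_bend(neutral_pose):
    kp0 = neutral_pose.sequence.frame(0)
    n = kp0.get("N")
    trunk = trunk_frame(kp0)
    for deg, axis, expect in [(20.0, trunk.X, ("flexion", 20.0)),
                              (15.0, trunk.Z, ("side_bend", 15.0))]:
        a = np.radians(deg)
        h = n + 200.0 * (np.cos(a) * trunk.Y + np.sin(a) * axis)
        kp = _pose_from(neutral_pose, H=h)
        flex, side = neck_angles(kp, trunk)
        if expect[0] == "flexion":
            assert flex == pytest.approx(expect[1], abs=1e-9)
            assert side == pytest.approx(0.0, abs=1e-9)
        else:
            assert side == pytest.approx(expect[1], abs=1e-9)
            assert flex == pytest.approx(0.0, abs=1e-9)


def test_neutral_standing_pose_has_all_zero_lower_limb_angles(neutral_pose):
    angles = compute_frame_angles(neutral_pose.sequence.frame(0), "right")
    for name in ("hip_abduction", "knee_flexion", "femur_flexion",
                 "femur_abduction", "pelvis_abduction", "ankle_flexion"):
        assert angles[name] == pytest.approx(0.0, abs=1e-9), name


def test_pelvis_roll_recovered_exactly():
    gait = generate_gait_sequence(
        GaitConfig(n_cycles=1, cycle_duration_s=1.0, pelvis_roll_amp=5.0,
                   hip_flexion_amp=0.0, knee_flexion_amp=0.0,
                   ankle_flexion_amp=0.0))
    series = compute_all_angles(gait.sequence, side_policy="right").values
    truth = gait.truth_series("right").values
    np.testing.assert_allclose(series["pelvis_abduction"],
                               truth["pelvis_abduction"], atol=1e-6)
    assert series["pelvis_abduction"].max() == pytest.approx(5.0, abs=1e-6)


def test_single_axis_shoulder_rotations_map_to_flexion_and_abduction():
    from gaitblur.kinematics import shoulder_angles

    trunk = Frame3D(origin=np.zeros(3), X=[0, 0, 1], Y=[0, 1, 0], Z=[-1, 0, 0])
    T = trunk.basis
    for (z, x), expect in [((45.0, 0.0), (45.0, 0.0)), ((0.0, -30.0), (0.0, -30.0)),
                           ((0.0, 0.0), (0.0, 0.0))]:
        S = T @ compose_zxy(z, x, 0.0)
        sh = Frame3D(origin=np.zeros(3), X=S[:, 0], Y=S[:, 1], Z=S[:, 2])
        flex, abd = shoulder_angles(trunk, sh)
        assert (flex, abd) == pytest.approx(expect, abs=1e-9)


# --- whole-sequence invariants ----------------------------------------------

def test_series_shape_and_names(short_gait):
    series = compute_all_angles(short_gait.sequence)
    assert tuple(series.values.columns) == ANGLE_NAMES
    assert series.n_frames == short_gait.sequence.n_frames
    assert np.isfinite(series.values.to_numpy()).all()


def test_static_pose_gives_constant_series(neutral_pose):
    series = compute_all_angles(neutral_pose.sequence).values
    assert (series.nunique() == 1).all()


def test_rigid_motion_invariance_of_angles(short_gait, rng):
    """Angles are invariant under rotation+translation; pelvis obliquity,
    being referenced to the world horizontal, is checked under yaw only."""
    seq = short_gait.sequence
    base = compute_all_angles(seq).values

    Q = random_rotation(rng)
    t = rng.normal(scale=1000.0, size=3)
    from gaitblur import MotionSequence
    moved = MotionSequence(seq.data @ Q.T + t, seq.frame_rate)
    got = compute_all_angles(moved).values
    free = [a for a in ANGLE_NAMES if a != "pelvis_abduction"]
    np.testing.assert_allclose(got[free], base[free], atol=1e-6)

    yaw = np.radians(73.0)
    Qy = np.array([[np.cos(yaw), 0, np.sin(yaw)], [0, 1, 0],
                   [-np.sin(yaw), 0, np.cos(yaw)]])
    yawed = MotionSequence(seq.data @ Qy.T + t, seq.frame_rate)
    got = compute_all_angles(yawed).values
    np.testing.assert_allclose(got, base, atol=1e-6)


def test_scale_invariance_of_angles(short_gait):
    from gaitblur import MotionSequence
    seq = short_gait.sequence
    base = compute_all_angles(seq).values
    scaled = compute_all_angles(MotionSequence(seq.data * 3.7, seq.frame_rate)).values
    np.testing.assert_allclose(scaled, base, atol=1e-6)


def test_degenerate_frame_yields_missing_not_fatal(neutral_pose):
    data = np.repeat(neutral_pose.sequence.data[:1], 3, axis=0).copy()
    # collapse the hip line in frame 1 only
    data[1, KEYPOINT_INDEX["HL"]] = data[1, KEYPOINT_INDEX["HR"]]
    from gaitblur import MotionSequence
    series = compute_all_angles(MotionSequence(data, 60.0)).values
    assert series.iloc[0].notna().all()
    assert series.iloc[1].isna().all()
    assert series.iloc[2].notna().all()
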