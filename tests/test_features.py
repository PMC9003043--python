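"""Angle computation, normalization bounds, and view-invariance."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from posturekit.exceptions import ConfigError, DegenerateGeometryError, SentinelFrameError
from posturekit.features import (
    ANGLE_NAMES,
    FEATURE_NAMES,
    absolute_roll_pitch,
    compute_angles,
    extract_features,
    feature_table,
    joint_angle,
    segment_vector,
)
from posturekit.skeleton import CameraExtrinsics, JointName, SkeletonFrame, rototranslate
from posturekit.synthetic import NoiseModel, PostureScript, generate_recording, keyframe_pose

from conftest import random_rotation


def vertical_rotation(theta: float, tx: float = 0.0, ty: float = 0.0) -> CameraExtrinsics:
    R = np.array(
        [
            [np.cos(theta), -np.sin(theta), 0.0],
            [np.sin(theta), np.cos(theta), 0.0],
            [0.0, 0.0, 1.0],
        ]
    )
    return CameraExtrinsics(R, np.array([tx, ty, 0.0]))


class TestJointAngle:
    @pytest.mark.parametrize(
        "u, v, expected",
        [
            ((0, 0, 1), (0, 0, 2), 0.0),        # parallel
            ((1, 0, 0), (0, 1, 0), 90.0),       # orthogonal
            ((1, 0, 0), (-1, 0, 0), 180.0),     # antiparallel
            ((1, 1, 0), (1, 0, 0), 45.0),
        ],
    )
    def test_reference_angles(self, u, v, expected):
        assert joint_angle(np.array(u, float), np.array(v, float)) == pytest.approx(expected)

    def test_zero_vector_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            joint_angle(np.zeros(3), np.ones(3))

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_range_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        u, v = rng.standard_normal(3), rng.standard_normal(3)
        a = joint_angle(u, v)
        assert 0.0 <= a <= 180.0
        assert joint_angle(v, u) == pytest.approx(a)


class TestAbsoluteRollPitch:
    def test_vertical_segment_is_90(self):
        seg = np.array([0.0, 0.0, 1.0])
        assert absolute_roll_pitch(seg, "pitch") == pytest.approx(90.0)
        assert absolute_roll_pitch(seg, "roll") == pytest.approx(90.0)

    def test_in_plane_segment_has_zero_pitch(self):
        assert absolute_roll_pitch(np.array([0.0, 1.0, 0.0]), "pitch") == pytest.approx(0.0)

    def test_45_degree_elevation(self):
        seg = np.array([0.0, 1.0, 1.0]) / np.sqrt(2)
        # independent trigonometric check: atan2(1, 1) = 45 degrees
        assert absolute_roll_pitch(seg, "pitch") == pytest.approx(45.0)

    def test_downward_segment_is_negative(self):
        assert absolute_roll_pitch(np.array([0.0, 1.0, -1.0]), "pitch") == pytest.approx(-45.0)

    def test_bad_which_rejected(self):
        with pytest.raises(ConfigError):
            absolute_roll_pitch(np.ones(3), "yaw")


class TestSegments:
    def test_head_segment_is_neck_to_head(self):
        pose = keyframe_pose("standing", 1.70, seed=0, variation_sd=0.0)
        expected = pose.joint("Head") - pose.joint("Neck")
        assert np.allclose(segment_vector(pose, "head"), expected)

    def test_trunk_runs_hip_midpoint_to_shoulder_midpoint(self):
        pose = keyframe_pose("standing", 1.70, seed=0, variation_sd=0.0)
        hip_mid = 0.5 * (pose.joint("HipL") + pose.joint("HipR"))
        sh_mid = 0.5 * (pose.joint("ShoulderL") + pose.joint("ShoulderR"))
        assert np.allclose(segment_vector(pose, "trunk"), sh_mid - hip_mid)

    @pytest.mark.parametrize("seed", range(5))
    def test_segment_length_invariant_under_rototranslation(self, seed):
        rng = np.random.default_rng(seed)
        pose = keyframe_pose("sitting", 1.80, seed=seed)
        ext = CameraExtrinsics(random_rotation(rng), rng.standard_normal(3))
        moved = SkeletonFrame(0.0, "c", ext.apply(pose.joints))
        for seg in ("head", "trunk", "thigh_l", "foot_r"):
            assert np.linalg.norm(segment_vector(pose, seg)) == pytest.approx(
                np.linalg.norm(segment_vector(moved, seg)), abs=1e-9
            )

    def test_coincident_endpoints_rejected(self):
        joints = np.ones((17, 3))  # all joints coincide
        with pytest.raises(DegenerateGeometryError):
            segment_vector(SkeletonFrame(0.0, "c", joints), "head")


class TestComputeAngles:
    def test_all_21_angles_populated(self):
        pose = keyframe_pose("standing", 1.70, seed=0)
        angles = compute_angles(pose).as_dict()
        assert set(angles) == set(ANGLE_NAMES)
        assert len(angles) == 21
        assert all(np.isfinite(v) for v in angles.values())

    def test_standing_pose_geometry(self):
        pose = keyframe_pose("standing", 1.70, seed=None, variation_sd=0.0)
        angles = compute_angles(pose)
        assert angles.xi < 10.0          # head nearly aligned with trunk
        assert angles.B_pitch > 80.0     # trunk near vertical

    def test_supine_pose_has_horizontal_trunk(self):
        pose = keyframe_pose("lying", 1.70, seed=None, variation_sd=0.0)
        assert abs(compute_angles(pose).B_pitch) < 10.0

    def test_joint_angles_in_range(self):
        for posture in ("standing", "sitting", "lying", "dangerous_sitting"):
            angles = compute_angles(keyframe_pose(posture, 1.75, seed=3)).as_dict()
            for name, value in angles.items():
                if name in ("A_roll", "A_pitch", "B_roll", "B_pitch"):
                    assert -90.0 <= value <= 90.0, name
                else:
                    assert 0.0 <= value <= 180.0, name

    def test_mirrored_pose_swaps_paired_angles(self):
        pose = keyframe_pose("sitting", 1.70, seed=7)
        mirrored = pose.joints.copy()
        mirrored[:, 0] = -mirrored[:, 0]
        # swap left/right joints so the mirror is anatomically consistent
        order = np.arange(17)
        for left, right in [(2, 3), (4, 5), (6, 7), (9, 10), (11, 12), (13, 14), (15, 16)]:
            order[[left, right]] = order[[right, left]]
        mirrored = mirrored[order]
        a = compute_angles(pose).as_dict()
        b = compute_angles(SkeletonFrame(0.0, "c", mirrored)).as_dict()
        for base in ("mu", "tau", "eta", "theta", "delta", "gamma", "beta", "alpha"):
            assert a[f"{base}1"] == pytest.approx(b[f"{base}2"], abs=1e-9)
            assert a[f"{base}2"] == pytest.approx(b[f"{base}1"], abs=1e-9)
        for unpaired in ("xi", "A_pitch", "B_pitch"):
            assert a[unpaired] == pytest.approx(b[unpaired], abs=1e-9)
        for roll in ("A_roll", "B_roll"):
            assert abs(a[roll]) == pytest.approx(abs(b[roll]), abs=1e-9)

    def test_sentinel_frame_rejected(self):
        with pytest.raises(SentinelFrameError):
            compute_angles(SkeletonFrame.sentinel(0.0, "c"))


class TestExtractFeatures:
    def test_right_angle_maps_to_half(self):
        assert joint_angle(np.array([1.0, 0, 0]), np.array([0, 1.0, 0])) / 180.0 == 0.5

    def test_head_height_ratio(self):
        pose = keyframe_pose("standing", 1.70, seed=None, variation_sd=0.0)
        joints = pose.joints.copy()
        joints[int(JointName.Head), 2] = 1.70
        values, is_sent = extract_features(SkeletonFrame(0.0, "c", joints), 1.70)
        assert not is_sent
        assert values[FEATURE_NAMES.index("Z_Head")] == pytest.approx(1.0)

    def test_sentinel_frame_yields_ten_999s(self):
        values, is_sent = extract_features(SkeletonFrame.sentinel(0.0, "c"), 1.70)
        assert is_sent
        assert values.shape == (10,)
        assert np.all(values == 999.0)

    def test_non_positive_height_rejected(self):
        pose = keyframe_pose("standing", 1.70, seed=0)
        with pytest.raises(ConfigError):
            extract_features(pose, 0.0)

    def test_normalization_bounds(self):
        rec, _ = generate_recording(
            PostureScript.default(cycles=1), noise=NoiseModel(jitter_sd=0.01), seed=5
        )
        df = feature_table(rec)
        clean = df[~df.is_sentinel]
        for name in ("xi", "mu2", "delta2"):
            assert clean[name].between(0.0, 1.0).all()
        for name in ("A_pitch", "A_roll", "B_pitch", "B_roll"):
            assert clean[name].between(-0.5, 0.5).all()


class TestViewInvariance:
    @pytest.mark.parametrize("seed", range(5))
    def test_features_invariant_under_vertical_rotation_and_shift(self, seed):
        rng = np.random.default_rng(seed)
        rec, _ = generate_recording(
            PostureScript.default(cycles=1),
            noise=NoiseModel(jitter_sd=0.02, burst_start_prob=0.01),
            seed=seed,
        )
        ext = vertical_rotation(
            float(rng.uniform(0, 2 * np.pi)), *rng.uniform(-5, 5, 2)
        )
        f0 = feature_table(rec)[list(FEATURE_NAMES)].to_numpy()
        f1 = feature_table(rototranslate(rec, ext))[list(FEATURE_NAMES)].to_numpy()
        assert np.max(np.abs(f0 - f1)) < 1e-9
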