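"""Skeleton CSV round-trips, rigid transforms, and temporal-hole filling."""

import numpy as np
import pytest

from posturekit.exceptions import (
    ConfigError,
    OrderingError,
    SchemaError,
    SentinelFrameError,
    SkeletonParseError,
)
from posturekit.skeleton import (
    JOINT_NAMES,
    CameraExtrinsics,
    JointName,
    Recording,
    SkeletonFrame,
    fill_temporal_holes,
    load_extrinsics,
    read_recording,
    rototranslate,
    rototranslate_frame,
    write_extrinsics,
    write_recording,
)

from conftest import make_recording, random_rotation


class TestJointLayout:
    def test_seventeen_canonical_joints(self):
        assert len(JointName) == 17
        assert len(set(JOINT_NAMES)) == 17

    def test_frame_requires_full_joint_set(self):
        with pytest.raises(SchemaError):
            SkeletonFrame(0.0, "cam0", np.zeros((16, 3)))


class TestReadWrite:
    def test_three_row_file_parses_to_three_frames(self, tmp_path):
        rec = make_recording(np.random.default_rng(0), n_frames=3)
        path = tmp_path / "rec.csv"
        write_recording(rec, path)
        back = read_recording(path)
        assert len(back) == 3
        assert back.frame(0).joints.shape == (17, 3)

    def test_header_metadata_passthrough(self, tmp_path):
        rec = make_recording(np.random.default_rng(1))
        path = tmp_path / "rec.csv"
        write_recording(rec, path)
        back = read_recording(path)
        assert back.subject_height == 1.70
        assert back.subject_id == "sub"
        assert back.camera_id == "cam0"
        assert back.frame_rate == 30.0

    @pytest.mark.parametrize("seed", range(5))
    def test_round_trip_is_bit_exact(self, tmp_path, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 20))
        mask = rng.random(n) < 0.2
        rec = make_recording(rng, n_frames=n, sentinel_mask=mask)
        path = tmp_path / "rec.csv"
        write_recording(rec, path)
        back = read_recording(path)
        assert np.array_equal(back.timestamps, rec.timestamps)
        assert np.array_equal(back.coords, rec.coords)
        assert np.array_equal(back.is_sentinel, rec.is_sentinel)

    def test_empty_recording_writes_header_only(self, tmp_path):
        rec = Recording("s", 1.6, "c", np.empty(0), np.empty((0, 17, 3)))
        path = tmp_path / "empty.csv"
        write_recording(rec, path)
        assert len(read_recording(path)) == 0

    def test_sentinel_frame_serializes_as_999_row(self, tmp_path):
        rec = make_recording(np.random.default_rng(2), n_frames=1, sentinel_mask=[True])
        path = tmp_path / "sent.csv"
        write_recording(rec, path)
        data_line = path.read_text().strip().splitlines()[-1]
        values = data_line.split(",")[1:]
        assert all(float(v) == 999.0 for v in values)

    def test_malformed_row_names_line(self, tmp_path):
        rec = make_recording(np.random.default_rng(3), n_frames=2)
        path = tmp_path / "bad.csv"
        write_recording(rec, path)
        with path.open("a") as fh:
            fh.write("0.5,not_a_number\n")
        with pytest.raises(SkeletonParseError, match="bad.csv:8"):
            read_recording(path)

    def test_non_increasing_timestamps_rejected(self, tmp_path):
        rec = make_recording(np.random.default_rng(4), n_frames=2)
        path = tmp_path / "rev.csv"
        write_recording(rec, path)
        lines = path.read_text().splitlines()
        lines[-1], lines[-2] = lines[-2], lines[-1]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(OrderingError):
            read_recording(path)

    def test_missing_header_key_rejected(self, tmp_path):
        rec = make_recording(np.random.default_rng(5), n_frames=1)
        path = tmp_path / "nohdr.csv"
        write_recording(rec, path)
        lines = [l for l in path.read_text().splitlines() if "camera_id" not in l]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(SchemaError):
            read_recording(path)


class TestRotoTranslation:
    def test_identity_leaves_frame_unchanged(self):
        frame = make_recording(np.random.default_rng(0)).frame(0)
        out = rototranslate_frame(frame, CameraExtrinsics.identity())
        assert np.allclose(out.joints, frame.joints)

    def test_pure_translation_shifts_every_joint(self):
        frame = make_recording(np.random.default_rng(1)).frame(0)
        ext = CameraExtrinsics(np.eye(3), np.array([1.0, 2.0, 0.5]))
        out = rototranslate_frame(frame, ext)
        assert np.allclose(out.joints - frame.joints, [1.0, 2.0, 0.5])

    @pytest.mark.parametrize("seed", range(8))
    def test_random_rotation_is_isometry(self, seed):
        rng = np.random.default_rng(seed)
        frame = make_recording(rng).frame(0)
        ext = CameraExtrinsics(random_rotation(rng), rng.standard_normal(3))
        out = rototranslate_frame(frame, ext)
        d_before = np.linalg.norm(frame.joints[:, None] - frame.joints[None], axis=-1)
        d_after = np.linalg.norm(out.joints[:, None] - out.joints[None], axis=-1)
        assert np.max(np.abs(d_before - d_after)) < 1e-9

    def test_sentinel_frame_rejected(self):
        frame = SkeletonFrame.sentinel(0.0, "cam0")
        with pytest.raises(SentinelFrameError):
            rototranslate_frame(frame, CameraExtrinsics.identity())

    def test_improper_rotation_rejected(self):
        R = np.diag([1.0, 1.0, -1.0])  # reflection
        with pytest.raises(ConfigError):
            CameraExtrinsics(R, np.zeros(3))

    def test_inverse_round_trip(self):
        rng = np.random.default_rng(9)
        rec = make_recording(rng)
        ext = CameraExtrinsics(random_rotation(rng), rng.standard_normal(3))
        back = rototranslate(rototranslate(rec, ext), ext.inverse())
        assert np.allclose(back.coords, rec.coords, atol=1e-12)


class TestFillTemporalHoles:
    def test_six_period_gap_inserts_five_sentinels(self):
        rec = make_recording(np.random.default_rng(0), n_frames=2)
        rec.timestamps = np.array([0.0, 6.0 / 30.0])
        out = fill_temporal_holes(rec)
        assert len(out) == 7
        assert out.is_sentinel.sum() == 5
        assert np.all(np.diff(out.timestamps) > 0)

    def test_regular_stream_is_untouched(self):
        rec = make_recording(np.random.default_rng(1), n_frames=10)
        out = fill_temporal_holes(rec)
        assert len(out) == 10
        assert not out.is_sentinel.any()

    @pytest.mark.parametrize("seed", range(6))
    def test_inserted_count_matches_bruteforce_recount(self, seed):
        rng = np.random.default_rng(seed)
        period = 1.0 / 30.0
        # random gap pattern in whole periods (1 = regular step)
        steps = rng.integers(1, 9, size=12)
        ts = np.cumsum(steps) * period
        rec = make_recording(rng, n_frames=12)
        rec.timestamps = ts
        expected_inserts = sum(int(round(g / period)) - 1 for g in np.diff(ts)
                               if g > 1.5 * period)
        out = fill_temporal_holes(rec)
        assert len(out) == len(rec) + expected_inserts

    def test_idempotent(self):
        rng = np.random.default_rng(7)
        rec = make_recording(rng, n_frames=6)
        rec.timestamps = np.array([0.0, 0.04, 0.3, 0.32, 0.6, 1.0])
        once = fill_temporal_holes(rec)
        twice = fill_temporal_holes(once)
        assert np.array_equal(once.timestamps, twice.timestamps)
        assert np.array_equal(once.is_sentinel, twice.is_sentinel)

    def test_collision_with_sentinel_value_warns(self):
        rng = np.random.default_rng(8)
        rec = make_recording(rng, n_frames=2)
        coords = rec.coords.copy()
        coords[0, 0, 0] = 999.0
        with pytest.warns(UserWarning, match="999"):
            Recording("s", 1.7, "c", rec.timestamps, coords)


class TestExtrinsicsConfig:
    @pytest.mark.parametrize("fmt", ["yaml", "json"])
    def test_round_trip(self, tmp_path, fmt):
        rng = np.random.default_rng(0)
        cams = {
            "cam0": CameraExtrinsics.identity(),
            "cam1": CameraExtrinsics(random_rotation(rng), rng.standard_normal(3)),
        }
        path = tmp_path / f"ext.{fmt}"
        write_extrinsics(cams, path)
        back = load_extrinsics(path)
        assert set(back) == {"cam0", "cam1"}
        assert np.allclose(back["cam1"].rotation, cams["cam1"].rotation)
        assert np.allclose(back["cam1"].translation, cams["cam1"].translation)
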