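"""Skeleton stream I/O and geometry.

A recording is a 30 Hz stream of skeleton frames from one depth camera: per
frame, the 3-D coordinates (meters) of 17 canonical body joints.  Frames from
each camera are roto-translated into a common room-fixed reference system
whose ``z`` axis is vertical.  Temporal holes — stretches where the tracker
produced no skeleton — are regularized by inserting *sentinel* frames whose
every coordinate equals 999, so that downstream windowing sees a gap-free
stream at the nominal frame rate.

File format (plain CSV):

.. code-block:: text

    #subject_id=s01
    #subject_height_m=1.70
    #camera_id=cam0
    #frame_rate_hz=30
    timestamp,Head_x,Head_y,Head_z,...,FootR_z
    0.000,0.01,0.02,1.64,...

Coordinates are serialized with ``repr`` precision so that a write/read
round-trip is bit-exact.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from enum import IntEnum
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import yaml

from .exceptions import (
    ConfigError,
    OrderingError,
    SchemaError,
    SentinelFrameError,
    SkeletonParseError,
)

SENTINEL = 999.0

#: Period multiple above which a gap between consecutive timestamps counts as
#: a temporal hole.  1.5 periods is robust to timestamp jitter while never
#: triggering inside a regular stream.
GAP_THRESHOLD_PERIODS = 1.5


class JointName(IntEnum):
    """The 17 canonical skeleton joints, in file-column order."""

    Head = 0
    Neck = 1
    ShoulderL = 2
    ShoulderR = 3
    ElbowL = 4
    ElbowR = 5
    WristL = 6
    WristR = 7
    SpineBase = 8
    HipL = 9
    HipR = 10
    KneeL = 11
    KneeR = 12
    AnkleL = 13
    AnkleR = 14
    FootL = 15
    FootR = 16


JOINT_NAMES: tuple[str, ...] = tuple(j.name for j in JointName)
N_JOINTS = len(JOINT_NAMES)

_COORD_COLUMNS: tuple[str, ...] = tuple(
    f"{name}_{axis}" for name in JOINT_NAMES for axis in "xyz"
)


@dataclass(frozen=True)
class CameraExtrinsics:
    """Rigid transform from camera-local to room coordinates: ``p_room = R p + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise SchemaError(f"extrinsics must be 3x3 + 3, got {R.shape} and {t.shape}")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ConfigError("rotation matrix is not orthonormal (tol 1e-9)")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise ConfigError("rotation matrix must be proper (det = +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map points (..., 3) from camera to room coordinates."""
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "CameraExtrinsics":
        R_inv = self.rotation.T
        return CameraExtrinsics(R_inv, -R_inv @ self.translation)

    @staticmethod
    def identity() -> "CameraExtrinsics":
        return CameraExtrinsics(np.eye(3), np.zeros(3))


@dataclass(frozen=True)
class SkeletonFrame:
    """One timestamped 17-joint skeleton from one camera."""

    timestamp: float
    camera_id: str
    joints: np.ndarray  # (17, 3) meters
    is_sentinel: bool = False

    def __post_init__(self) -> None:
        J = np.asarray(self.joints, dtype=float)
        if J.shape != (N_JOINTS, 3):
            raise SchemaError(f"joints must be (17, 3), got {J.shape}")
        if self.is_sentinel:
            if not np.all(J == SENTINEL):
                raise SchemaError("sentinel frame must carry 999 in every coordinate")
        elif not np.all(np.isfinite(J)):
            raise SchemaError("non-sentinel frame has non-finite coordinates")
        object.__setattr__(self, "joints", J)

    def joint(self, name: JointName | str) -> np.ndarray:
        idx = JointName[name] if isinstance(name, str) else name
        return self.joints[int(idx)]

    @staticmethod
    def sentinel(timestamp: float, camera_id: str) -> "SkeletonFrame":
        return SkeletonFrame(
            timestamp, camera_id, np.full((N_JOINTS, 3), SENTINEL), is_sentinel=True
        )


@dataclass
class Recording:
    """An ordered skeleton stream from one camera, stored column-wise.

    ``coords`` has shape ``(n_frames, 17, 3)``; sentinel frames carry 999 in
    every coordinate and are flagged in ``is_sentinel``.
    """

    subject_id: str
    subject_height: float
    camera_id: str
    timestamps: np.ndarray
    coords: np.ndarray
    is_sentinel: np.ndarray = field(default=None)  # type: ignore[assignment]
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.timestamps)
        if self.coords.shape != (n, N_JOINTS, 3):
            raise SchemaError(
                f"coords must be (n, 17, 3); got {self.coords.shape} for n={n}"
            )
        if self.is_sentinel is None:
            self.is_sentinel = np.all(self.coords == SENTINEL, axis=(1, 2))
        self.is_sentinel = np.asarray(self.is_sentinel, dtype=bool)
        if self.is_sentinel.shape != (n,):
            raise SchemaError("is_sentinel must be (n,)")
        if self.subject_height <= 0:
            raise ConfigError(f"subject_height must be > 0, got {self.subject_height}")
        if self.frame_rate <= 0:
            raise ConfigError(f"frame_rate must be > 0, got {self.frame_rate}")
        if n > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise OrderingError("timestamps must be strictly increasing")
        clean = self.coords[~self.is_sentinel]
        if clean.size and np.any(clean == SENTINEL):
            warnings.warn(
                "non-sentinel frame carries the literal value 999; "
                "this collides with the missing-frame sentinel",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def n_frames(self) -> int:
        return len(self.timestamps)

    def frame(self, i: int) -> SkeletonFrame:
        return SkeletonFrame(
            float(self.timestamps[i]),
            self.camera_id,
            self.coords[i],
            bool(self.is_sentinel[i]),
        )

    def __iter__(self) -> Iterator[SkeletonFrame]:
        for i in range(len(self)):
            yield self.frame(i)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def rototranslate_frame(frame: SkeletonFrame, extrinsics: CameraExtrinsics) -> SkeletonFrame:
    """Map every joint of ``frame`` through the rigid transform ``R p + t``."""
    if frame.is_sentinel:
        raise SentinelFrameError("cannot roto-translate a sentinel frame")
    return replace(frame, joints=extrinsics.apply(frame.joints))


def rototranslate(recording: Recording, extrinsics: CameraExtrinsics) -> Recording:
    """Apply :func:`rototranslate_frame` to every non-sentinel frame of a recording."""
    coords = recording.coords.copy()
    keep = ~recording.is_sentinel
    coords[keep] = extrinsics.apply(coords[keep])
    return replace(recording, coords=coords, is_sentinel=recording.is_sentinel.copy())


# ---------------------------------------------------------------------------
# Temporal regularization
# ---------------------------------------------------------------------------

def fill_temporal_holes(recording: Recording, sentinel: float = SENTINEL) -> Recording:
    """Insert sentinel frames wherever the stream skips more than 1.5 periods.

    A gap of ``g`` seconds between consecutive frames receives
    ``round(g / period) - 1`` sentinel frames at nominal period spacing, so
    that the output approximates a regular stream at ``frame_rate``.
    Idempotent: a second application is a no-op.
    """
    if recording.frame_rate <= 0:
        raise ConfigError("frame_rate must be positive")
    period = 1.0 / recording.frame_rate
    ts = recording.timestamps
    if len(ts) < 2:
        return recording

    out_ts: list[np.ndarray] = []
    out_coords: list[np.ndarray] = []
    out_sent: list[np.ndarray] = []
    sent_coords = np.full((N_JOINTS, 3), sentinel)
    for i in range(len(ts)):
        out_ts.append(ts[i : i + 1])
        out_coords.append(recording.coords[i : i + 1])
        out_sent.append(recording.is_sentinel[i : i + 1])
        if i + 1 < len(ts):
            gap = ts[i + 1] - ts[i]
            if gap > GAP_THRESHOLD_PERIODS * period:
                n_insert = int(round(gap / period)) - 1
                if n_insert > 0:
                    fill_ts = ts[i] + period * np.arange(1, n_insert + 1)
                    out_ts.append(fill_ts)
                    out_coords.append(np.broadcast_to(sent_coords, (n_insert, N_JOINTS, 3)))
                    out_sent.append(np.ones(n_insert, dtype=bool))
    return replace(
        recording,
        timestamps=np.concatenate(out_ts),
        coords=np.concatenate(out_coords),
        is_sentinel=np.concatenate(out_sent),
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_recording(recording: Recording, path: str | Path) -> None:
    """Serialize a recording to the skeleton CSV dialect (bit-exact round-trip)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"#subject_id={recording.subject_id}\n")
        fh.write(f"#subject_height_m={recording.subject_height!r}\n")
        fh.write(f"#camera_id={recording.camera_id}\n")
        fh.write(f"#frame_rate_hz={recording.frame_rate!r}\n")
        fh.write("timestamp," + ",".join(_COORD_COLUMNS) + "\n")
        flat = recording.coords.reshape(len(recording), 3 * N_JOINTS)
        for i in range(len(recording)):
            row = [repr(float(recording.timestamps[i]))]
            row.extend(repr(float(v)) for v in flat[i])
            fh.write(",".join(row) + "\n")


def read_recording(
    path: str | Path, extrinsics: CameraExtrinsics | None = None
) -> Recording:
    """Read a skeleton CSV; optionally roto-translate into the room frame."""
    path = Path(path)
    header: dict[str, str] = {}
    rows: list[list[float]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "=" not in line:
                    raise SkeletonParseError(f"{path}:{lineno}: malformed header line")
                key, _, value = line[1:].partition("=")
                header[key.strip()] = value.strip()
                continue
            fields = line.split(",")
            if fields[0] == "timestamp":
                if tuple(f.strip() for f in fields[1:]) != _COORD_COLUMNS:
                    raise SchemaError(
                        f"{path}:{lineno}: column header does not match the "
                        f"17-joint layout ({len(fields) - 1} coordinate columns)"
                    )
                continue
            if len(fields) != 1 + 3 * N_JOINTS:
                raise SkeletonParseError(
                    f"{path}:{lineno}: expected {1 + 3 * N_JOINTS} fields, got {len(fields)}"
                )
            try:
                rows.append([float(v) for v in fields])
            except ValueError as exc:
                raise SkeletonParseError(f"{path}:{lineno}: {exc}") from None

    for key in ("subject_id", "subject_height_m", "camera_id", "frame_rate_hz"):
        if key not in header:
            raise SchemaError(f"{path}: missing header line #{key}=")

    if len(rows):
        data = np.asarray(rows, dtype=float)
        timestamps = data[:, 0]
        coords = data[:, 1:].reshape(len(rows), N_JOINTS, 3)
    else:
        timestamps = np.empty(0)
        coords = np.empty((0, N_JOINTS, 3))
    if len(rows) > 1 and not np.all(np.diff(timestamps) > 0):
        raise OrderingError(f"{path}: timestamps are not strictly increasing")

    rec = Recording(
        subject_id=header["subject_id"],
        subject_height=float(header["subject_height_m"]),
        camera_id=header["camera_id"],
        timestamps=timestamps,
        coords=coords,
        frame_rate=float(header["frame_rate_hz"]),
    )
    if extrinsics is not None:
        rec = rototranslate(rec, extrinsics)
    return rec


def load_extrinsics(path: str | Path) -> dict[str, CameraExtrinsics]:
    """Load per-camera extrinsics from a YAML or JSON mapping.

    Each entry is keyed by camera id and holds ``rotation`` (9 numbers,
    row-major) and ``translation`` (3 numbers, meters).
    """
    path = Path(path)
    text = path.read_text()
    raw: Mapping = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise SchemaError(f"{path}: expected a mapping keyed by camera_id")
    out: dict[str, CameraExtrinsics] = {}
    for cam, entry in raw.items():
        R = np.asarray(entry["rotation"], dtype=float).reshape(3, 3)
        t = np.asarray(entry["translation"], dtype=float).reshape(3)
        out[str(cam)] = CameraExtrinsics(R, t)
    return out


def write_extrinsics(extrinsics: Mapping[str, CameraExtrinsics], path: str | Path) -> None:
    path = Path(path)
    payload = {
        cam: {
            "rotation": [float(v) for v in ext.rotation.ravel()],
            "translation": [float(v) for v in ext.translation],
        }
        for cam, ext in extrinsics.items()
    }
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload))
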