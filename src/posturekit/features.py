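"""Joint-angle and normalized-coordinate features.

Per frame, 17 joint angles (angle between two adjacent body-segment
vectors, in [0°, 180°]) and 4 absolute angles (signed roll/pitch of the head
and trunk segments relative to the room-horizontal plane, in [-90°, 90°])
are computed.  Ten candidate features feed the classifiers:

====== =====================================================================
name    definition
====== =====================================================================
A_pitch head-segment pitch / 180
A_roll  head-segment roll / 180
B_pitch trunk-segment pitch / 180
B_roll  trunk-segment roll / 180
xi      head–trunk joint angle / 180
mu2     head–right-shoulder joint angle / 180
delta2  trunk–right-hip joint angle / 180
Z_Head  vertical coordinate of the head / subject height
Z_C7    vertical coordinate of the shoulder midpoint / subject height
Z_Hc    vertical coordinate of the hip midpoint / subject height
====== =====================================================================

Roll and pitch are decomposed in a *body-attached* horizontal frame (right
axis = horizontal projection of the combined hip and shoulder lines, forward
= vertical x right), so that all ten features are invariant to rotations of
the subject about the vertical axis and to horizontal translation — the
property that makes a multi-camera setup consistent.

Sentinel (missing) frames propagate: every feature of a sentinel frame is
the literal 999.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dataclass_fields

import numpy as np
import pandas as pd

from .exceptions import ConfigError, DegenerateGeometryError, SentinelFrameError
from .skeleton import JointName, Recording, SENTINEL, SkeletonFrame

#: The 10 candidate features, in canonical column order.
FEATURE_NAMES: tuple[str, ...] = (
    "A_pitch",
    "A_roll",
    "B_pitch",
    "B_roll",
    "xi",
    "mu2",
    "delta2",
    "Z_Head",
    "Z_C7",
    "Z_Hc",
)

N_FEATURES = len(FEATURE_NAMES)

_J = JointName  # brevity

#: Body segments as (proximal, distal) joint pairs; "shoulder_mid" and
#: "hip_mid" denote midpoints.  Directions run proximal -> distal.
SEGMENTS: dict[str, tuple] = {
    "head": (_J.Neck, _J.Head),
    "trunk": ("hip_mid", "shoulder_mid"),
    "shoulder_l": (_J.Neck, _J.ShoulderL),
    "shoulder_r": (_J.Neck, _J.ShoulderR),
    "arm_l": (_J.ShoulderL, _J.ElbowL),
    "arm_r": (_J.ShoulderR, _J.ElbowR),
    "forearm_l": (_J.ElbowL, _J.WristL),
    "forearm_r": (_J.ElbowR, _J.WristR),
    "hip_l": (_J.SpineBase, _J.HipL),
    "hip_r": (_J.SpineBase, _J.HipR),
    "thigh_l": (_J.HipL, _J.KneeL),
    "thigh_r": (_J.HipR, _J.KneeR),
    "leg_l": (_J.KneeL, _J.AnkleL),
    "leg_r": (_J.KneeR, _J.AnkleR),
    "foot_l": (_J.AnkleL, _J.FootL),
    "foot_r": (_J.AnkleR, _J.FootR),
}


@dataclass(frozen=True)
class AngleSet:
    """The 17 joint angles plus 4 absolute angles of one frame, degrees."""

    mu1: float      # head vs. left shoulder
    mu2: float      # head vs. right shoulder
    xi: float       # head vs. trunk
    tau1: float     # trunk vs. left shoulder
    tau2: float     # trunk vs. right shoulder
    eta1: float     # shoulder vs. arm, left
    eta2: float     # shoulder vs. arm, right
    theta1: float   # arm vs. forearm, left
    theta2: float   # arm vs. forearm, right
    delta1: float   # trunk vs. hip, left
    delta2: float   # trunk vs. hip, right
    gamma1: float   # hip vs. thigh, left
    gamma2: float   # hip vs. thigh, right
    beta1: float    # thigh vs. leg, left
    beta2: float    # thigh vs. leg, right
    alpha1: float   # leg vs. foot, left
    alpha2: float   # leg vs. foot, right
    A_roll: float   # head absolute roll
    A_pitch: float  # head absolute pitch
    B_roll: float   # trunk absolute roll
    B_pitch: float  # trunk absolute pitch

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dataclass_fields(self)}


ANGLE_NAMES: tuple[str, ...] = tuple(f.name for f in dataclass_fields(AngleSet))


def _point(coords: np.ndarray, endpoint) -> np.ndarray:
    """Resolve a joint or midpoint endpoint on coords of shape (..., 17, 3)."""
    if endpoint == "shoulder_mid":
        return 0.5 * (coords[..., _J.ShoulderL, :] + coords[..., _J.ShoulderR, :])
    if endpoint == "hip_mid":
        return 0.5 * (coords[..., _J.HipL, :] + coords[..., _J.HipR, :])
    return coords[..., int(endpoint), :]


def segment_vector(frame: SkeletonFrame | np.ndarray, segment: str) -> np.ndarray:
    """Direction vector of a body segment, proximal to distal.

    ``frame`` may be a :class:`SkeletonFrame` or a coordinate array of shape
    ``(..., 17, 3)``; the result has shape ``(..., 3)``.
    """
    if isinstance(frame, SkeletonFrame):
        if frame.is_sentinel:
            raise SentinelFrameError("cannot take segments of a sentinel frame")
        coords = frame.joints
    else:
        coords = np.asarray(frame, dtype=float)
    try:
        proximal, distal = SEGMENTS[segment]
    except KeyError:
        raise ConfigError(f"unknown segment {segment!r}") from None
    vec = _point(coords, distal) - _point(coords, proximal)
    if np.any(np.linalg.norm(vec, axis=-1) < 1e-12):
        raise DegenerateGeometryError(f"segment {segment!r} has zero length")
    return vec


def joint_angle(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Angle between two segment vectors in degrees, in [0, 180].

    Broadcasts over leading axes; the cosine is clamped to [-1, 1] before
    the arccos to absorb round-off.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    if np.any(nu < 1e-12) or np.any(nv < 1e-12):
        raise DegenerateGeometryError("zero-length vector in joint_angle")
    cos = np.clip(np.sum(u * v, axis=-1) / (nu * nv), -1.0, 1.0)
    return np.degrees(np.arccos(cos))


def body_axes(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Horizontal body-attached axes (right, forward) per frame.

    The right axis is the horizontal projection of the summed left-to-right
    hip and shoulder lines; forward completes a right-handed triad with the
    vertical.  Falls back to the room x axis when the projection degenerates
    (subject axis aligned with the vertical).
    """
    coords = np.asarray(coords, dtype=float)
    right = (
        coords[..., _J.HipR, :]
        - coords[..., _J.HipL, :]
        + coords[..., _J.ShoulderR, :]
        - coords[..., _J.ShoulderL, :]
    )
    right = right.copy()
    right[..., 2] = 0.0
    norm = np.linalg.norm(right, axis=-1, keepdims=True)
    fallback = np.zeros_like(right)
    fallback[..., 0] = 1.0
    right = np.where(norm > 1e-9, right / np.where(norm == 0, 1.0, norm), fallback)
    up = np.zeros_like(right)
    up[..., 2] = 1.0
    forward = np.cross(up, right)
    return right, forward


def absolute_roll_pitch(
    segment: np.ndarray,
    which: str,
    right: np.ndarray | None = None,
    forward: np.ndarray | None = None,
) -> np.ndarray:
    """Signed inclination of a segment out of the horizontal plane, degrees.

    ``pitch`` measures elevation in the sagittal decomposition
    (``atan2(z, |forward component|)``), ``roll`` in the frontal one
    (``atan2(z, |right component|)``); both lie in [-90, 90].  When no body
    axes are given the room ``y``/``x`` axes are used.
    """
    segment = np.asarray(segment, dtype=float)
    if np.any(np.linalg.norm(segment, axis=-1) < 1e-12):
        raise DegenerateGeometryError("zero-length segment in absolute_roll_pitch")
    if which not in ("roll", "pitch"):
        raise ConfigError(f"which must be 'roll' or 'pitch', got {which!r}")
    if right is None or forward is None:
        right = np.broadcast_to(np.array([1.0, 0.0, 0.0]), segment.shape)
        forward = np.broadcast_to(np.array([0.0, 1.0, 0.0]), segment.shape)
    axis = forward if which == "pitch" else right
    horiz = np.abs(np.sum(segment * axis, axis=-1))
    return np.degrees(np.arctan2(segment[..., 2], horiz))


def _angles_arrays(coords: np.ndarray) -> dict[str, np.ndarray]:
    """All 21 angles for coords of shape (..., 17, 3)."""
    seg = {name: segment_vector(coords, name) for name in SEGMENTS}
    right, forward = body_axes(coords)
    out: dict[str, np.ndarray] = {
        "mu1": joint_angle(seg["head"], seg["shoulder_l"]),
        "mu2": joint_angle(seg["head"], seg["shoulder_r"]),
        "xi": joint_angle(seg["head"], seg["trunk"]),
        "tau1": joint_angle(seg["trunk"], seg["shoulder_l"]),
        "tau2": joint_angle(seg["trunk"], seg["shoulder_r"]),
        "eta1": joint_angle(seg["shoulder_l"], seg["arm_l"]),
        "eta2": joint_angle(seg["shoulder_r"], seg["arm_r"]),
        "theta1": joint_angle(seg["arm_l"], seg["forearm_l"]),
        "theta2": joint_angle(seg["arm_r"], seg["forearm_r"]),
        "delta1": joint_angle(seg["trunk"], seg["hip_l"]),
        "delta2": joint_angle(seg["trunk"], seg["hip_r"]),
        "gamma1": joint_angle(seg["hip_l"], seg["thigh_l"]),
        "gamma2": joint_angle(seg["hip_r"], seg["thigh_r"]),
        "beta1": joint_angle(seg["thigh_l"], seg["leg_l"]),
        "beta2": joint_angle(seg["thigh_r"], seg["leg_r"]),
        "alpha1": joint_angle(seg["leg_l"], seg["foot_l"]),
        "alpha2": joint_angle(seg["leg_r"], seg["foot_r"]),
        "A_roll": absolute_roll_pitch(seg["head"], "roll", right, forward),
        "A_pitch": absolute_roll_pitch(seg["head"], "pitch", right, forward),
        "B_roll": absolute_roll_pitch(seg["trunk"], "roll", right, forward),
        "B_pitch": absolute_roll_pitch(seg["trunk"], "pitch", right, forward),
    }
    return out


def compute_angles(frame: SkeletonFrame) -> AngleSet:
    """The full angle set of one frame (degrees)."""
    if frame.is_sentinel:
        raise SentinelFrameError("cannot compute angles of a sentinel frame")
    arrays = _angles_arrays(frame.joints)
    return AngleSet(**{k: float(v) for k, v in arrays.items()})


def _feature_arrays(coords: np.ndarray, subject_height: float) -> np.ndarray:
    """The 10 candidate features for coords (..., 17, 3) -> (..., 10)."""
    angles = _angles_arrays(coords)
    z_head = coords[..., _J.Head, 2]
    z_c7 = 0.5 * (coords[..., _J.ShoulderL, 2] + coords[..., _J.ShoulderR, 2])
    z_hc = 0.5 * (coords[..., _J.HipL, 2] + coords[..., _J.HipR, 2])
    cols = [
        angles["A_pitch"] / 180.0,
        angles["A_roll"] / 180.0,
        angles["B_pitch"] / 180.0,
        angles["B_roll"] / 180.0,
        angles["xi"] / 180.0,
        angles["mu2"] / 180.0,
        angles["delta2"] / 180.0,
        z_head / subject_height,
        z_c7 / subject_height,
        z_hc / subject_height,
    ]
    return np.stack(cols, axis=-1)


def extract_features(
    frame: SkeletonFrame, subject_height: float
) -> tuple[np.ndarray, bool]:
    """The 10 candidate features of one frame.

    Returns ``(values, is_sentinel)``.  Angles are divided by 180; vertical
    coordinates by the subject height.  A sentinel frame yields ten 999s.
    """
    if subject_height <= 0:
        raise ConfigError(f"subject_height must be > 0, got {subject_height}")
    if frame.is_sentinel:
        return np.full(N_FEATURES, SENTINEL), True
    return _feature_arrays(frame.joints, subject_height), False


def feature_table(recording: Recording) -> pd.DataFrame:
    """Per-frame feature table of a recording.

    Columns: ``timestamp``, the 10 features of :data:`FEATURE_NAMES`, and
    ``is_sentinel``.  Sentinel rows carry 999 in every feature column.
    """
    if recording.subject_height <= 0:
        raise ConfigError("subject_height must be > 0")
    n = len(recording)
    values = np.full((n, N_FEATURES), SENTINEL)
    keep = ~recording.is_sentinel
    if keep.any():
        values[keep] = _feature_arrays(recording.coords[keep], recording.subject_height)
    df = pd.DataFrame(values, columns=list(FEATURE_NAMES))
    df.insert(0, "timestamp", recording.timestamps)
    df["is_sentinel"] = recording.is_sentinel
    return df
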