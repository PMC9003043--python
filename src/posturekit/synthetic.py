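"""Posture-scripted synthetic skeleton streams.

Emulates the acquisition protocol the pipeline is designed for: a subject in
a monitored room cycles through an ordered sequence of postures (standing,
sitting, lying, dangerous sitting — the slumped-in-chair alarm posture),
holding each for some seconds and transitioning smoothly between them, while
one or more depth cameras record a 30 Hz 17-joint skeleton stream.  Frames
rendered during a transition between two *different* postures carry the
transition class (5).  Tracking dropouts are emulated as missing-frame
bursts, which become all-999 sentinel frames.

Geometry is template-based: each posture has a 17-joint keyframe expressed
in fractions of subject height, with a small seeded per-subject variation;
transitions interpolate keyframes with a minimum-jerk time profile, giving
transition frames genuinely intermediate feature values — the hard case
that motivates a sequence classifier.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .features import feature_table
from .skeleton import (
    JointName,
    N_JOINTS,
    CameraExtrinsics,
    Recording,
    SENTINEL,
    SkeletonFrame,
    write_extrinsics,
    write_recording,
)

POSTURES = ("standing", "sitting", "lying", "dangerous_sitting")

#: Class labels of the static postures (transition frames are class 5).
POSTURE_CLASS = {"standing": 1, "sitting": 2, "lying": 3, "dangerous_sitting": 4}

_J = JointName

# Keyframe templates, fractions of subject height, subject facing +y,
# room z vertical.  Mirrored joints share magnitudes with opposite x sign.
_TEMPLATES: dict[str, dict[JointName, tuple[float, float, float]]] = {
    "standing": {
        _J.Head: (0.0, 0.01, 0.95),
        _J.Neck: (0.0, 0.0, 0.86),
        _J.ShoulderL: (-0.11, 0.0, 0.83),
        _J.ShoulderR: (0.11, 0.0, 0.83),
        _J.ElbowL: (-0.13, 0.0, 0.65),
        _J.ElbowR: (0.13, 0.0, 0.65),
        _J.WristL: (-0.14, 0.02, 0.47),
        _J.WristR: (0.14, 0.02, 0.47),
        _J.SpineBase: (0.0, 0.0, 0.55),
        _J.HipL: (-0.09, 0.0, 0.52),
        _J.HipR: (0.09, 0.0, 0.52),
        _J.KneeL: (-0.09, 0.01, 0.27),
        _J.KneeR: (0.09, 0.01, 0.27),
        _J.AnkleL: (-0.09, 0.0, 0.04),
        _J.AnkleR: (0.09, 0.0, 0.04),
        _J.FootL: (-0.09, 0.10, 0.01),
        _J.FootR: (0.09, 0.10, 0.01),
    },
    "sitting": {
        _J.Head: (0.0, 0.01, 0.69),
        _J.Neck: (0.0, 0.0, 0.61),
        _J.ShoulderL: (-0.11, 0.0, 0.58),
        _J.ShoulderR: (0.11, 0.0, 0.58),
        _J.ElbowL: (-0.13, 0.02, 0.41),
        _J.ElbowR: (0.13, 0.02, 0.41),
        _J.WristL: (-0.12, 0.12, 0.32),
        _J.WristR: (0.12, 0.12, 0.32),
        _J.SpineBase: (0.0, 0.02, 0.30),
        _J.HipL: (-0.09, 0.02, 0.28),
        _J.HipR: (0.09, 0.02, 0.28),
        _J.KneeL: (-0.09, 0.24, 0.28),
        _J.KneeR: (0.09, 0.24, 0.28),
        _J.AnkleL: (-0.09, 0.26, 0.04),
        _J.AnkleR: (0.09, 0.26, 0.04),
        _J.FootL: (-0.09, 0.36, 0.01),
        _J.FootR: (0.09, 0.36, 0.01),
    },
    "lying": {
        _J.Head: (0.0, 0.93, 0.15),
        _J.Neck: (0.0, 0.85, 0.13),
        _J.ShoulderL: (-0.11, 0.82, 0.12),
        _J.ShoulderR: (0.11, 0.82, 0.12),
        _J.ElbowL: (-0.13, 0.65, 0.11),
        _J.ElbowR: (0.13, 0.65, 0.11),
        _J.WristL: (-0.14, 0.47, 0.11),
        _J.WristR: (0.14, 0.47, 0.11),
        _J.SpineBase: (0.0, 0.55, 0.12),
        _J.HipL: (-0.09, 0.52, 0.12),
        _J.HipR: (0.09, 0.52, 0.12),
        _J.KneeL: (-0.09, 0.27, 0.14),
        _J.KneeR: (0.09, 0.27, 0.14),
        _J.AnkleL: (-0.09, 0.06, 0.12),
        _J.AnkleR: (0.09, 0.06, 0.12),
        _J.FootL: (-0.09, 0.02, 0.15),
        _J.FootR: (0.09, 0.02, 0.15),
    },
    "dangerous_sitting": {
        _J.Head: (0.0, 0.26, 0.50),
        _J.Neck: (0.0, 0.16, 0.53),
        _J.ShoulderL: (-0.11, 0.14, 0.50),
        _J.ShoulderR: (0.11, 0.14, 0.50),
        _J.ElbowL: (-0.12, 0.18, 0.35),
        _J.ElbowR: (0.12, 0.18, 0.35),
        _J.WristL: (-0.10, 0.28, 0.28),
        _J.WristR: (0.10, 0.28, 0.28),
        _J.SpineBase: (0.0, 0.04, 0.30),
        _J.HipL: (-0.09, 0.02, 0.28),
        _J.HipR: (0.09, 0.02, 0.28),
        _J.KneeL: (-0.09, 0.26, 0.28),
        _J.KneeR: (0.09, 0.26, 0.28),
        _J.AnkleL: (-0.09, 0.30, 0.04),
        _J.AnkleR: (0.09, 0.30, 0.04),
        _J.FootL: (-0.09, 0.40, 0.01),
        _J.FootR: (0.09, 0.40, 0.01),
    },
}


@dataclass(frozen=True)
class PostureScript:
    """An ordered sequence of held postures with smooth transitions.

    ``entries`` are ``(posture, hold_seconds)`` pairs; every consecutive pair
    is bridged by a transition of ``transition_s`` seconds, labeled class 5
    when the two postures differ.
    """

    entries: tuple[tuple[str, float], ...]
    transition_s: float = 2.0

    def __post_init__(self) -> None:
        if not self.entries:
            raise ConfigError("script must contain at least one posture")
        for posture, hold in self.entries:
            if posture not in POSTURES:
                raise ConfigError(f"unknown posture {posture!r}")
            if hold <= 0:
                raise ConfigError("hold durations must be > 0")
        if self.transition_s <= 0:
            raise ConfigError("transition duration must be > 0")

    @property
    def total_duration(self) -> float:
        holds = sum(h for _, h in self.entries)
        return holds + self.transition_s * (len(self.entries) - 1)

    @staticmethod
    def default(cycles: int = 2, hold_s: float = 10.0, transition_s: float = 2.0) -> "PostureScript":
        """The acquisition-style script: 10 s holds cycling through the four postures."""
        entries = tuple((p, hold_s) for _ in range(cycles) for p in POSTURES)
        return PostureScript(entries, transition_s)


@dataclass(frozen=True)
class NoiseModel:
    """Additive joint jitter plus missing-frame bursts.

    ``jitter_sd`` is the per-coordinate Gaussian SD in meters.  A missing
    burst starts at any frame with probability ``burst_start_prob`` and has
    geometric length with mean ``burst_mean_frames``; its frames become
    all-999 sentinels, emulating stretches where the tracker loses the
    skeleton.
    """

    jitter_sd: float = 0.01
    burst_start_prob: float = 0.005
    burst_mean_frames: float = 15.0

    def __post_init__(self) -> None:
        if self.jitter_sd < 0:
            raise ConfigError("jitter_sd must be >= 0")
        if not 0.0 <= self.burst_start_prob <= 1.0:
            raise ConfigError("burst_start_prob must be in [0, 1]")
        if self.burst_mean_frames < 1:
            raise ConfigError("burst_mean_frames must be >= 1")

    @staticmethod
    def none() -> "NoiseModel":
        return NoiseModel(jitter_sd=0.0, burst_start_prob=0.0)


def _minimum_jerk(s: np.ndarray) -> np.ndarray:
    """Minimum-jerk time profile on [0, 1]: 10 s^3 - 15 s^4 + 6 s^5."""
    return s**3 * (10.0 - 15.0 * s + 6.0 * s**2)


def keyframe_pose(
    posture: str,
    subject_height: float,
    seed: int | None = None,
    variation_sd: float = 0.005,
) -> SkeletonFrame:
    """Keyframe skeleton of a posture, scaled to the subject's height.

    ``variation_sd`` (fraction of height) adds a seeded per-joint offset that
    individualizes the template; the same seed always yields the same pose.
    """
    coords = _keyframe_coords(posture, subject_height, seed, variation_sd)
    return SkeletonFrame(0.0, "template", coords)


def _keyframe_coords(
    posture: str, subject_height: float, seed: int | None, variation_sd: float
) -> np.ndarray:
    if posture not in _TEMPLATES:
        raise ConfigError(f"unknown posture {posture!r}")
    if subject_height <= 0:
        raise ConfigError("subject_height must be > 0")
    template = _TEMPLATES[posture]
    coords = np.array([template[j] for j in JointName], dtype=float) * subject_height
    if variation_sd > 0:
        rng = np.random.default_rng(seed)
        coords = coords + rng.normal(0.0, variation_sd * subject_height, coords.shape)
    return coords


def generate_recording(
    script: PostureScript,
    subject_id: str = "s00",
    subject_height: float = 1.70,
    noise: NoiseModel | None = None,
    frame_rate: float = 30.0,
    seed: int | None = None,
    camera_id: str = "cam0",
) -> tuple[Recording, np.ndarray]:
    """Render a script into a room-frame recording plus per-frame labels.

    Returns ``(recording, labels)`` where ``labels`` holds the ground-truth
    class per frame (1–4 during holds, 5 during transitions between
    differing postures).  Labels refer to the scripted movement; frames
    knocked out by a missing burst keep their ground-truth label while their
    coordinates become the 999 sentinel.
    """
    if frame_rate <= 0:
        raise ConfigError("frame_rate must be > 0")
    noise = noise if noise is not None else NoiseModel()
    rng = np.random.default_rng(seed)

    # One fixed per-subject keyframe variation so that, with zero jitter,
    # features are constant within a held posture.
    subject_seed = int(rng.integers(0, 2**31))
    keyframes = {
        p: _keyframe_coords(p, subject_height, subject_seed + i, 0.005)
        for i, p in enumerate(POSTURES)
    }

    # Piecewise timeline: (start_s, end_s, kind, payload)
    segments: list[tuple[float, float, str, tuple]] = []
    t = 0.0
    for k, (posture, hold) in enumerate(script.entries):
        segments.append((t, t + hold, "hold", (posture,)))
        t += hold
        if k + 1 < len(script.entries):
            nxt = script.entries[k + 1][0]
            segments.append((t, t + script.transition_s, "transition", (posture, nxt)))
            t += script.transition_s
    total = t

    n_frames = int(round(total * frame_rate))
    if n_frames == 0:
        raise ConfigError("script duration too short for a single frame")
    timestamps = np.arange(n_frames) / frame_rate
    coords = np.empty((n_frames, N_JOINTS, 3))
    labels = np.empty(n_frames, dtype=int)

    seg_idx = 0
    for i, ts in enumerate(timestamps):
        while seg_idx + 1 < len(segments) and ts >= segments[seg_idx][1]:
            seg_idx += 1
        start, end, kind, payload = segments[seg_idx]
        if kind == "hold":
            coords[i] = keyframes[payload[0]]
            labels[i] = POSTURE_CLASS[payload[0]]
        else:
            a, b = payload
            s = _minimum_jerk(np.clip((ts - start) / (end - start), 0.0, 1.0))
            coords[i] = (1.0 - s) * keyframes[a] + s * keyframes[b]
            labels[i] = 5 if a != b else POSTURE_CLASS[a]

    if noise.jitter_sd > 0:
        coords += rng.normal(0.0, noise.jitter_sd, coords.shape)

    is_sentinel = np.zeros(n_frames, dtype=bool)
    if noise.burst_start_prob > 0:
        i = 0
        while i < n_frames:
            if rng.random() < noise.burst_start_prob:
                length = int(rng.geometric(1.0 / noise.burst_mean_frames))
                is_sentinel[i : i + length] = True
                i += length
            else:
                i += 1
        coords[is_sentinel] = SENTINEL

    rec = Recording(
        subject_id=subject_id,
        subject_height=subject_height,
        camera_id=camera_id,
        timestamps=timestamps,
        coords=coords,
        is_sentinel=is_sentinel,
        frame_rate=frame_rate,
    )
    return rec, labels


def labeled_frame_table(
    recording: Recording, labels: np.ndarray, recording_id: str = "rec0"
) -> pd.DataFrame:
    """Feature table of a recording with label and identity columns attached."""
    df = feature_table(recording)
    df["label"] = np.asarray(labels, dtype=int)
    df["subject_id"] = recording.subject_id
    df["recording_id"] = recording_id
    df["frame_index"] = np.arange(len(df))
    return df


def benchmark_frame_table(
    n_subjects: int = 2,
    script: PostureScript | None = None,
    noise: NoiseModel | None = None,
    frame_rate: float = 30.0,
    seed: int | None = None,
    height_range: tuple[float, float] = (1.55, 1.90),
) -> pd.DataFrame:
    """Labeled feature table for a small in-memory benchmark.

    One room-frame recording per subject, heights drawn uniformly from
    ``height_range`` (the study population's span).  This is the fast path
    used by tests and examples; :func:`generate_benchmark` adds the
    multi-camera on-disk variant.
    """
    if n_subjects < 1:
        raise ConfigError("n_subjects must be >= 1")
    script = script if script is not None else PostureScript.default()
    rng = np.random.default_rng(seed)
    tables = []
    for s in range(n_subjects):
        height = float(rng.uniform(*height_range))
        rec, labels = generate_recording(
            script,
            subject_id=f"s{s:02d}",
            subject_height=height,
            noise=noise,
            frame_rate=frame_rate,
            seed=int(rng.integers(0, 2**31)),
        )
        tables.append(labeled_frame_table(rec, labels, recording_id=f"s{s:02d}_cam0"))
    return pd.concat(tables, ignore_index=True)


def generate_benchmark(
    out_dir: str | Path,
    n_subjects: int = 2,
    script: PostureScript | None = None,
    noise: NoiseModel | None = None,
    cameras: dict[str, CameraExtrinsics] | None = None,
    frame_rate: float = 30.0,
    seed: int | None = None,
    height_range: tuple[float, float] = (1.55, 1.90),
) -> dict:
    """Write a multi-camera synthetic database to ``out_dir``.

    Per subject x camera one skeleton CSV is written in *camera-local*
    coordinates (the inverse extrinsic applied to the room-frame movement),
    so that reading it back with the camera's extrinsics reproduces the room
    frame.  A label CSV per recording and a JSON manifest (parameters,
    seeds, per-class counts) accompany the data.  Returns the manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    script = script if script is not None else PostureScript.default()
    noise = noise if noise is not None else NoiseModel()
    if cameras is None:
        cameras = {"cam0": CameraExtrinsics.identity()}
    if len(set(cameras)) != len(cameras):
        raise ConfigError("duplicate camera ids")
    if not cameras:
        raise ConfigError("at least one camera required")

    rng = np.random.default_rng(seed)
    manifest: dict = {
        "seed": seed,
        "n_subjects": n_subjects,
        "frame_rate": frame_rate,
        "noise": {
            "jitter_sd": noise.jitter_sd,
            "burst_start_prob": noise.burst_start_prob,
            "burst_mean_frames": noise.burst_mean_frames,
        },
        "script": {"entries": list(script.entries), "transition_s": script.transition_s},
        "recordings": [],
        "class_counts": {},
    }
    class_counts: dict[int, int] = {}
    for s in range(n_subjects):
        subject_id = f"s{s:02d}"
        height = float(rng.uniform(*height_range))
        rec_seed = int(rng.integers(0, 2**31))
        room_rec, labels = generate_recording(
            script,
            subject_id=subject_id,
            subject_height=height,
            noise=noise,
            frame_rate=frame_rate,
            seed=rec_seed,
        )
        for cam_id, ext in cameras.items():
            inv = ext.inverse()
            coords = room_rec.coords.copy()
            keep = ~room_rec.is_sentinel
            coords[keep] = inv.apply(coords[keep])
            cam_rec = Recording(
                subject_id=subject_id,
                subject_height=height,
                camera_id=cam_id,
                timestamps=room_rec.timestamps,
                coords=coords,
                is_sentinel=room_rec.is_sentinel,
                frame_rate=frame_rate,
            )
            rec_id = f"{subject_id}_{cam_id}"
            write_recording(cam_rec, out_dir / f"{rec_id}.csv")
            pd.DataFrame(
                {
                    "recording_id": rec_id,
                    "frame_index": np.arange(len(labels)),
                    "label": labels,
                }
            ).to_csv(out_dir / f"{rec_id}_labels.csv", index=False)
            manifest["recordings"].append(
                {"recording_id": rec_id, "subject_id": subject_id, "camera_id": cam_id,
                 "subject_height": height, "n_frames": len(labels), "seed": rec_seed}
            )
        for cls, cnt in zip(*np.unique(labels, return_counts=True)):
            class_counts[int(cls)] = class_counts.get(int(cls), 0) + int(cnt) * len(cameras)
    manifest["class_counts"] = {str(k): v for k, v in sorted(class_counts.items())}
    write_extrinsics(cameras, out_dir / "extrinsics.yaml")
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def load_benchmark_frames(data_dir: str | Path) -> pd.DataFrame:
    """Load a :func:`generate_benchmark` directory into a labeled frame table.

    Recordings are read back through their camera extrinsics (restoring the
    room frame), features are extracted, and the label CSVs are joined.
    """
    from .skeleton import load_extrinsics, read_recording

    data_dir = Path(data_dir)
    manifest = json.loads((data_dir / "manifest.json").read_text())
    cameras = load_extrinsics(data_dir / "extrinsics.yaml")
    tables = []
    for entry in manifest["recordings"]:
        rec_id = entry["recording_id"]
        rec = read_recording(
            data_dir / f"{rec_id}.csv", extrinsics=cameras[entry["camera_id"]]
        )
        labels = pd.read_csv(data_dir / f"{rec_id}_labels.csv")["label"].to_numpy()
        tables.append(labeled_frame_table(rec, labels, recording_id=rec_id))
    return pd.concat(tables, ignore_index=True)
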