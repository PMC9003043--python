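"""Posture databases: labeling, sentinel handling, windowing, subject splits.

Two databases are built from the same labeled frame stream:

* the *frame* (MLP) database drops every sentinel frame — a static
  classifier gains nothing from all-999 placeholders;
* the *sequence* (LSTM) database keeps sentinels, relabels each with the
  class of the last preceding non-sentinel frame, windows the stream into
  fixed-length contiguous sequences (default 60 frames = 2 s at 30 Hz), and
  discards only sequences made up entirely of sentinels.

Frame streams are pandas DataFrames with the 10 feature columns of
:data:`posturekit.features.FEATURE_NAMES` plus ``is_sentinel``, ``label``,
``subject_id``, ``recording_id`` and ``frame_index``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import pandas as pd

from .exceptions import ConfigError, OrderingError, PostureKitError
from .features import FEATURE_NAMES

SEQUENCE_LENGTH = 60  # frames; 2 s at 30 Hz


class PostureLabel(IntEnum):
    """The five posture classes."""

    STANDING = 1
    SITTING = 2
    LYING = 3
    DANGEROUS_SITTING = 4
    TRANSITION = 5


ALL_LABELS: tuple[int, ...] = tuple(int(l) for l in PostureLabel)


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint train/test partition of subject ids."""

    train_subjects: tuple[str, ...]
    test_subjects: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.train_subjects) & set(self.test_subjects):
            raise ConfigError("train and test subjects must be disjoint")


def _validate_frames(frames: pd.DataFrame) -> None:
    missing = [c for c in (*FEATURE_NAMES, "is_sentinel", "label") if c not in frames]
    if missing:
        raise PostureKitError(f"frame table is missing columns: {missing}")
    if frames["label"].isna().any():
        raise PostureKitError("frame table contains unlabeled frames")


def class_count_table(frames: pd.DataFrame) -> pd.Series:
    """Frame counts per posture class (always reporting all 5 classes)."""
    counts = frames["label"].value_counts()
    return pd.Series(
        {cls: int(counts.get(cls, 0)) for cls in ALL_LABELS}, name="n_frames"
    )


def build_mlp_dataset(frames: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Frame database for the static classifier: every sentinel removed.

    Returns the filtered table (order preserved) and a bookkeeping report
    with total / removed / retained counts and per-class counts.
    """
    _validate_frames(frames)
    keep = ~frames["is_sentinel"].to_numpy(dtype=bool)
    out = frames.loc[keep].reset_index(drop=True)
    report = {
        "total_frames": int(len(frames)),
        "removed_sentinels": int((~keep).sum()),
        "retained_frames": int(keep.sum()),
        "class_counts": class_count_table(out).to_dict(),
    }
    return out, report


def relabel_sentinels(frames: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Propagate labels onto sentinel frames, per recording.

    Each sentinel frame takes the label of the last preceding non-sentinel
    frame; a leading run with no predecessor takes the first following
    non-sentinel label.  Returns the relabeled copy and the number of
    sentinel frames relabeled.
    """
    _validate_frames(frames)
    out = frames.copy()
    group_key = out["recording_id"] if "recording_id" in out else np.zeros(len(out))
    labels = out["label"].astype(float).to_numpy().copy()
    sent = out["is_sentinel"].to_numpy(dtype=bool)
    labels[sent] = np.nan
    lab = pd.Series(labels)
    filled = lab.groupby(group_key.to_numpy()).transform(
        lambda s: s.ffill().bfill()
    )
    if filled.isna().any():
        raise PostureKitError(
            "a recording consists entirely of sentinel frames; no label to propagate"
        )
    out["label"] = filled.astype(int).to_numpy()
    return out, int(sent.sum())


def make_sequences(
    frames: pd.DataFrame, length: int = SEQUENCE_LENGTH
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame, dict]:
    """Window a frame stream into contiguous, non-overlapping sequences.

    Frames are grouped by ``recording_id`` (which must be index-contiguous
    within each recording); each recording yields ``floor(n / length)``
    sequences, the trailing remainder is dropped and counted in the report.

    Returns ``(X, y, meta, report)`` with ``X`` of shape
    ``(n_seq, length, 10)``, ``y`` of shape ``(n_seq, length)`` and one meta
    row (recording_id, subject_id, start_index) per sequence.
    """
    if length <= 0:
        raise ConfigError(f"sequence length must be > 0, got {length}")
    _validate_frames(frames)
    feats = list(FEATURE_NAMES)
    xs, ys, meta_rows = [], [], []
    dropped = 0
    group_key = "recording_id" if "recording_id" in frames else None
    groups = frames.groupby(group_key, sort=False) if group_key else [(None, frames)]
    for rec_id, grp in groups:
        if "frame_index" in grp:
            idx = grp["frame_index"].to_numpy()
            if len(idx) > 1 and not np.all(np.diff(idx) == 1):
                raise OrderingError(
                    f"recording {rec_id!r}: frame_index is not contiguous"
                )
        n_seq = len(grp) // length
        dropped += len(grp) - n_seq * length
        if n_seq == 0:
            continue
        x = grp[feats].to_numpy(dtype=float)[: n_seq * length]
        y = grp["label"].to_numpy(dtype=int)[: n_seq * length]
        xs.append(x.reshape(n_seq, length, len(feats)))
        ys.append(y.reshape(n_seq, length))
        subject = grp["subject_id"].iloc[0] if "subject_id" in grp else ""
        start0 = int(grp["frame_index"].iloc[0]) if "frame_index" in grp else 0
        for k in range(n_seq):
            meta_rows.append(
                {"recording_id": rec_id, "subject_id": subject,
                 "start_index": start0 + k * length}
            )
    X = np.concatenate(xs) if xs else np.empty((0, length, len(feats)))
    y = np.concatenate(ys) if ys else np.empty((0, length), dtype=int)
    meta = pd.DataFrame(meta_rows, columns=["recording_id", "subject_id", "start_index"])
    report = {"n_sequences": int(len(X)), "dropped_remainder_frames": int(dropped)}
    return X, y, meta, report


def build_lstm_dataset(
    frames: pd.DataFrame, length: int = SEQUENCE_LENGTH
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame, dict]:
    """Sequence database for the recurrent classifier.

    Sentinel frames are relabeled from their predecessor, the stream is
    windowed into ``length``-frame sequences, and sequences consisting
    entirely of sentinel frames are discarded.  The report accounts for
    every frame: retained sentinels, the sentinel fraction of the final
    database, dropped all-sentinel sequences and the windowing remainder.
    """
    relabeled, n_sentinels = relabel_sentinels(frames)
    X, y, meta, win_report = make_sequences(relabeled, length)
    sent_per_seq = np.all(X == 999.0, axis=2)  # frame is sentinel iff all-999
    all_sentinel = sent_per_seq.all(axis=1)
    keep = ~all_sentinel
    X, y, meta = X[keep], y[keep], meta.loc[keep].reset_index(drop=True)
    retained_sentinels = int(sent_per_seq[keep].sum())
    total_retained = int(X.shape[0] * X.shape[1])
    report = {
        "total_frames": int(len(frames)),
        "sentinel_frames": n_sentinels,
        "n_sequences": int(len(X)),
        "dropped_all_sentinel_sequences": int(all_sentinel.sum()),
        "dropped_remainder_frames": win_report["dropped_remainder_frames"],
        "retained_frames": total_retained,
        "retained_sentinels": retained_sentinels,
        "sentinel_fraction": retained_sentinels / total_retained if total_retained else 0.0,
    }
    return X, y, meta, report


def split_by_subject(
    items: pd.DataFrame, split: DatasetSplit
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Partition a frame table (or sequence meta table) by subject id.

    Returns ``(train, test, report)``; the report carries per-class counts
    for each partition when labels are available, mirroring the database
    repartition table of the study protocol.
    """
    if "subject_id" not in items:
        raise PostureKitError("items must carry a subject_id column")
    subjects = set(items["subject_id"].unique())
    unknown = (set(split.train_subjects) | set(split.test_subjects)) - subjects
    if unknown:
        raise ConfigError(f"split names unknown subject ids: {sorted(unknown)}")
    in_test = items["subject_id"].isin(split.test_subjects)
    in_train = (
        items["subject_id"].isin(split.train_subjects)
        if split.train_subjects
        else ~in_test
    )
    train = items.loc[in_train].reset_index(drop=True)
    test = items.loc[in_test].reset_index(drop=True)
    report: dict = {"n_train": int(len(train)), "n_test": int(len(test))}
    if "label" in items:
        report["train_class_counts"] = class_count_table(train).to_dict()
        report["test_class_counts"] = class_count_table(test).to_dict()
    return train, test, report


# ---------------------------------------------------------------------------
# Database bookkeeping arithmetic
# ---------------------------------------------------------------------------

def mlp_database_size(total_frames: int, sentinel_frames: int) -> int:
    """Frames in the static-classifier database: total minus all sentinels."""
    if sentinel_frames > total_frames:
        raise ConfigError("sentinel_frames cannot exceed total_frames")
    return total_frames - sentinel_frames


def lstm_database_size(
    total_frames: int, sentinel_frames: int, retained_sentinels: int
) -> int:
    """Frames in the sequence database.

    Sentinels inside mixed sequences are retained; only those belonging to
    discarded all-sentinel sequences (and remainders) leave the database.
    """
    if retained_sentinels > sentinel_frames:
        raise ConfigError("retained_sentinels cannot exceed sentinel_frames")
    return total_frames - (sentinel_frames - retained_sentinels)


def sentinel_percent(retained_sentinels: int, database_frames: int) -> float:
    """Percentage of the database made of retained sentinel frames."""
    if database_frames <= 0:
        raise ConfigError("database_frames must be > 0")
    return 100.0 * retained_sentinels / database_frames


def partition_total(class_counts: dict) -> int:
    """Total of a per-class frame-count table (the table's bottom row)."""
    return int(sum(class_counts.values()))


def sequence_duration_s(length: int, frame_rate: float) -> float:
    """Wall-clock span of a sequence of ``length`` frames at ``frame_rate`` Hz."""
    if frame_rate <= 0:
        raise ConfigError("frame_rate must be > 0")
    return length / frame_rate
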