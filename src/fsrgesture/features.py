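"""Per-segment features and gesture databases.

For each gesture instance (one held-posture segment) the features are the
mean and sample standard deviation of every FSR channel over the segment,
giving the row (fsr1_mean, fsr2_mean, fsr3_mean, fsr1_sd, fsr2_sd,
fsr3_sd, label).  A full protocol trial (10 repetitions x 8 gestures)
yields an 80-row database; sensor-subset projections keep 4 (pair) or 2
(single sensor) feature columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .labels import GestureLabel, SensorChannel
from .recording import RawRecording
from .segmentation import (
    Segment,
    SegmentationConfig,
    apply_normalization,
    compute_normalization,
    label_segments,
    rest_segments,
    segment,
    select_segmentation_channel,
)
from .synth import Session

FULL_MASK: tuple[int, ...] = (1, 2, 3)

#: All non-empty sensor subsets, singles first.
SENSOR_MASKS: tuple[tuple[int, ...], ...] = (
    (1,), (2,), (3,), (1, 2), (1, 3), (2, 3), (1, 2, 3),
)


def feature_columns(mask: Sequence[int] = FULL_MASK) -> list[str]:
    mask = sorted(mask)
    return [f"fsr{i}_mean" for i in mask] + [f"fsr{i}_sd" for i in mask]


@dataclass
class GestureDatabase:
    """Feature rows (one per gesture instance) for one subject or a cohort.

    ``frame`` holds the masked feature columns plus integer ``label`` codes
    and a per-row ``subject_id``.
    """

    frame: pd.DataFrame
    subject_id: str = ""
    sensor_mask: tuple[int, ...] = FULL_MASK

    def __post_init__(self):
        self.sensor_mask = tuple(sorted(self.sensor_mask))
        missing = set(feature_columns(self.sensor_mask) + ["label"]) - set(
            self.frame.columns
        )
        if missing:
            raise ValueError(f"database frame missing columns: {sorted(missing)}")
        if "subject_id" not in self.frame.columns:
            self.frame = self.frame.assign(subject_id=self.subject_id)

    @property
    def feature_names(self) -> list[str]:
        return feature_columns(self.sensor_mask)

    @property
    def X(self) -> np.ndarray:
        return self.frame[self.feature_names].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame["label"].to_numpy(dtype=int)

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.y)

    def subset(self, indices: Sequence[int]) -> "GestureDatabase":
        return GestureDatabase(
            self.frame.iloc[np.asarray(indices)].reset_index(drop=True),
            self.subject_id,
            self.sensor_mask,
        )


def extract_features(
    rec: RawRecording, segments: Sequence[Segment], subject_id: str = ""
) -> GestureDatabase:
    """One feature row per labeled segment (mean and SD per channel).

    SDs use the sample (n-1) convention; segments of at least two samples
    are required.  Unlabeled segments are rejected.
    """
    rows = []
    for seg in segments:
        if seg.label is None:
            raise ValueError(f"segment [{seg.start_sample}, {seg.end_sample}) is unlabeled")
        window = rec.forces[:, seg.start_sample : seg.end_sample]
        rows.append(
            np.concatenate([window.mean(axis=1), window.std(axis=1, ddof=1)])
        )
    frame = pd.DataFrame(rows, columns=feature_columns())
    frame["label"] = [int(seg.label) for seg in segments]
    return GestureDatabase(frame, subject_id=subject_id)


def median_check(
    rec: RawRecording,
    segments: Sequence[Segment],
    channel: SensorChannel | None = None,
) -> np.ndarray:
    """Percent deviation ``100*|mean - median|/|mean|`` per segment on the
    segmentation channel; NaN where the mean is zero (undefined)."""
    channel = channel or select_segmentation_channel(rec)
    x = rec.forces[channel.array_index]
    out = np.empty(len(segments))
    for i, seg in enumerate(segments):
        window = x[seg.start_sample : seg.end_sample]
        mean = window.mean()
        out[i] = (
            np.nan if mean == 0.0 else 100.0 * abs(mean - np.median(window)) / abs(mean)
        )
    return out


def combine_databases(dbs: Sequence[GestureDatabase]) -> GestureDatabase:
    """Row-concatenate subject databases (provenance kept per row)."""
    if not dbs:
        return GestureDatabase(
            pd.DataFrame(columns=feature_columns() + ["label", "subject_id"]),
            subject_id="combined",
        )
    masks = {db.sensor_mask for db in dbs}
    if len(masks) != 1:
        raise ValueError("cannot combine databases with different sensor masks")
    frame = pd.concat([db.frame for db in dbs], ignore_index=True)
    return GestureDatabase(frame, "combined", dbs[0].sensor_mask)


def project_sensors(
    db: GestureDatabase, mask: Sequence[int]
) -> GestureDatabase:
    """Restrict the database to the mean/SD columns of a sensor subset."""
    mask = tuple(sorted(mask))
    if not mask or not set(mask) <= set(db.sensor_mask):
        raise ValueError(f"mask {mask} not a subset of {db.sensor_mask}")
    cols = feature_columns(mask) + ["label", "subject_id"]
    return GestureDatabase(db.frame[cols].copy(), db.subject_id, mask)


def session_database(
    session: Session,
    cfg: SegmentationConfig | None = None,
) -> GestureDatabase:
    """Run the batch pipeline on a full protocol session.

    Offsets are taken from the rest block (falling back to global minima),
    the normalization scale from the whole session; each gesture block is
    then segmented with its own threshold and labeled from the ground-truth
    timeline.  Rest instances, which cross no threshold, are windowed from
    the rest block's known hold intervals.
    """
    cfg = cfg or SegmentationConfig()
    rest_ref = (
        session.block(GestureLabel.REST)
        if GestureLabel.REST in session.gestures
        else None
    )
    norm = compute_normalization(session.recordings, rest_ref)
    parts = []
    for gesture, rec in zip(session.gestures, session.recordings):
        pre = apply_normalization(rec, norm)
        if gesture is GestureLabel.REST:
            segs = rest_segments(pre)
        else:
            segs = label_segments(segment(pre, cfg), pre.timeline)
            segs = [s for s in segs if s.label is not None]
        parts.append(extract_features(pre, segs, session.subject_id))
    db = combine_databases(parts)
    db.subject_id = session.subject_id
    return db
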