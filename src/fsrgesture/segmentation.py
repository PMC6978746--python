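"""Preprocessing and threshold segmentation of armband recordings.

Preprocessing subtracts each channel's minimum over a rest reference (the
FSR offsets due to the armband fastening pressure) and normalizes all
channels by the single global maximum absolute value, so the preprocessed
recording peaks at exactly 1.

Segmentation picks the channel with the largest variation (peak-to-peak
amplitude) and thresholds it at 40% of that variation above the channel
minimum; maximal supra-threshold runs are the held-posture segments, which
by construction discard the sub-threshold initial and final transients.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateSignalError
from .labels import GestureLabel, SensorChannel
from .recording import RawRecording, TimelineEntry


@dataclass(frozen=True)
class SegmentationConfig:
    """Threshold-segmentation parameters.

    ``threshold_fraction`` is the fraction of the selected channel's
    peak-to-peak amplitude (above its minimum) used as the threshold;
    ``min_segment_duration`` drops spurious short runs and ``merge_gap``
    bridges brief sub-threshold dips, both in seconds.
    """

    threshold_fraction: float = 0.40
    min_segment_duration: float = 0.5
    merge_gap: float = 0.1

    def __post_init__(self):
        if not 0.0 < self.threshold_fraction < 1.0:
            raise ValueError("threshold_fraction must be in (0, 1)")
        if self.min_segment_duration < 0 or self.merge_gap < 0:
            raise ValueError("durations must be non-negative")


@dataclass(frozen=True)
class Segment:
    """Half-open sample interval ``[start_sample, end_sample)`` of one held
    posture; ``label`` is None while unassigned (or unlabeled)."""

    start_sample: int
    end_sample: int
    label: GestureLabel | None = None
    source_channel: SensorChannel | None = None

    def __post_init__(self):
        if not 0 <= self.start_sample < self.end_sample:
            raise ValueError(
                f"invalid segment [{self.start_sample}, {self.end_sample})"
            )

    @property
    def n_samples(self) -> int:
        return self.end_sample - self.start_sample


@dataclass(frozen=True)
class Normalization:
    """Rest offsets (kg, per channel) and the global normalization scale."""

    offsets: tuple[float, float, float]
    scale: float


def _rest_forces(
    rec: RawRecording,
    rest_reference: RawRecording | tuple[int, int] | None,
) -> np.ndarray:
    if rest_reference is None:
        return rec.forces
    if isinstance(rest_reference, RawRecording):
        if rest_reference.n_samples == 0:
            raise ValueError("rest reference is empty")
        return rest_reference.forces
    start, end = rest_reference
    if end <= start:
        raise ValueError("rest reference interval is empty")
    return rec.forces[:, start:end]


def compute_normalization(
    recordings: RawRecording | Sequence[RawRecording],
    rest_reference: RawRecording | tuple[int, int] | None = None,
) -> Normalization:
    """Offsets = per-channel minima over the rest reference (or over the
    recordings themselves, whose inter-burst gaps are at rest); scale = the
    global maximum absolute value across all channels after offset removal."""
    if isinstance(recordings, RawRecording):
        recordings = [recordings]
    if not recordings:
        raise ValueError("no recordings given")
    rest = _rest_forces(recordings[0], rest_reference)
    if rest_reference is None and len(recordings) > 1:
        offsets = np.min(
            [r.forces.min(axis=1) for r in recordings], axis=0
        )
    else:
        offsets = rest.min(axis=1)
    scale = max(
        float(np.abs(r.forces - offsets[:, None]).max()) for r in recordings
    )
    if scale == 0.0:
        raise DegenerateSignalError(
            "recording is identically zero after offset removal"
        )
    return Normalization(tuple(offsets), scale)


def apply_normalization(rec: RawRecording, norm: Normalization) -> RawRecording:
    offsets = np.asarray(norm.offsets)[:, None]
    return rec.with_forces((rec.forces - offsets) / norm.scale)


def preprocess(
    rec: RawRecording,
    rest_reference: RawRecording | tuple[int, int] | None = None,
) -> RawRecording:
    """Offset-subtract and normalize one recording (see module docstring)."""
    return apply_normalization(rec, compute_normalization(rec, rest_reference))


def select_segmentation_channel(rec: RawRecording) -> SensorChannel:
    """Channel with maximum peak-to-peak amplitude; ties -> lowest index."""
    if rec.n_samples == 0:
        raise ValueError("empty recording")
    ptp = rec.forces.max(axis=1) - rec.forces.min(axis=1)
    return SensorChannel(int(np.argmax(ptp)) + 1)


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.astype(np.int8), [0]))))
    return list(zip(edges[0::2], edges[1::2]))


def segment(
    rec: RawRecording, cfg: SegmentationConfig | None = None
) -> list[Segment]:
    """Threshold segmentation on the maximum-variation channel.

    The threshold is ``min + threshold_fraction * (max - min)`` of the
    selected channel; maximal runs at or above it are kept after bridging
    sub-threshold gaps shorter than ``merge_gap`` and dropping runs shorter
    than ``min_segment_duration``.  A flat signal yields no segments.
    """
    cfg = cfg or SegmentationConfig()
    channel = select_segmentation_channel(rec)
    x = rec.forces[channel.array_index]
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return []
    threshold = lo + cfg.threshold_fraction * (hi - lo)
    runs = _runs_above(x >= threshold)
    max_gap = round(cfg.merge_gap * rec.sampling_rate)
    merged: list[list[int]] = []
    for start, end in runs:
        if merged and start - merged[-1][1] < max_gap:
            merged[-1][1] = end
        else:
            merged.append([start, end])
    min_len = round(cfg.min_segment_duration * rec.sampling_rate)
    return [
        Segment(int(s), int(e), source_channel=channel)
        for s, e in merged
        if e - s >= min_len
    ]


def label_segments(
    segments: Sequence[Segment], timeline: Sequence[TimelineEntry]
) -> list[Segment]:
    """Assign each segment the label of the maximally overlapping timeline
    interval; segments overlapping nothing keep ``label=None``."""
    starts = [t.start_sample for t in timeline]
    out = []
    for seg in segments:
        best_label, best_overlap = None, 0
        # only neighbours around the segment can overlap (timeline is sorted)
        first = max(0, bisect.bisect_right(starts, seg.start_sample) - 1)
        for entry in timeline[first:]:
            if entry.start_sample >= seg.end_sample:
                break
            overlap = min(seg.end_sample, entry.end_sample) - max(
                seg.start_sample, entry.start_sample
            )
            if overlap > best_overlap:
                best_label, best_overlap = entry.label, overlap
        out.append(
            Segment(seg.start_sample, seg.end_sample, best_label, seg.source_channel)
        )
    return out


def rest_segments(
    rec: RawRecording, window_length: float | None = None
) -> list[Segment]:
    """Fixed-length rest windows taken from the ground-truth rest intervals.

    Rest produces no threshold crossing, so rest instances are windowed from
    the known rest plateaus instead (window length defaults to the full
    interval), letting rest participate as a class in the database.
    """
    out = []
    for entry in rec.timeline:
        if entry.label is not GestureLabel.REST:
            continue
        end = entry.end_sample
        if window_length is not None:
            end = min(end, entry.start_sample + round(window_length * rec.sampling_rate))
        out.append(Segment(entry.start_sample, end, GestureLabel.REST))
    return out


def timeline_segments(rec: RawRecording) -> list[Segment]:
    """Segments taken directly from the ground-truth (cue-aligned) timeline,
    e.g. for a video-guided mixed-gesture session."""
    return [
        Segment(t.start_sample, t.end_sample, t.label) for t in rec.timeline
    ]
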