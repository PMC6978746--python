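"""Streaming gesture decoder emulating the embedded implementation.

Features (per-channel mean and SD) are computed over consecutive
non-overlapping 100 ms windows and classified at 10 Hz; each decision is
emitted as a single byte equal to the gesture code.  The calibrate-then-
play workflow trains a classifier on a full protocol recording with the
batch pipeline, then streams fresh samples through it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .classifiers import TrainedModel
from .errors import ConfigurationError, MissingClassError
from .features import GestureDatabase, feature_columns, session_database
from .labels import GestureLabel
from .recording import RawRecording
from .segmentation import (
    Normalization,
    SegmentationConfig,
    apply_normalization,
    compute_normalization,
)
from .synth import Session


@dataclass(frozen=True)
class StreamConfig:
    """Windowing of the real-time decoder: non-overlapping windows of
    ``window_length`` seconds emitted at ``output_rate`` Hz (the defaults,
    100 ms at 10 Hz, tile the stream exactly)."""

    window_length: float = 0.1
    output_rate: float = 10.0
    sampling_rate: float = 1000.0

    def __post_init__(self):
        if min(self.window_length, self.output_rate, self.sampling_rate) <= 0:
            raise ConfigurationError("stream parameters must be positive")
        n = self.sampling_rate * self.window_length
        if abs(n - round(n)) > 1e-9 or round(n) < 2:
            raise ConfigurationError(
                "window_length must span an integer number (>= 2) of samples"
            )

    @property
    def window_samples(self) -> int:
        return round(self.sampling_rate * self.window_length)


@dataclass(frozen=True)
class StreamDecision:
    """One classification decision for a completed window."""

    window_index: int
    label: GestureLabel

    @property
    def byte_code(self) -> int:
        return self.label.code


def stream_decode(
    source: RawRecording | np.ndarray,
    model: TrainedModel,
    cfg: StreamConfig | None = None,
    normalization: Normalization | None = None,
) -> list[StreamDecision]:
    """Decode a sample stream into one decision per completed window.

    ``source`` is a recording or a (3, n) force array replayed in
    acquisition order; an incomplete trailing window is dropped.  If the
    model was calibrated on preprocessed signals, pass the calibration's
    ``normalization`` so streamed samples live on the same scale.
    """
    cfg = cfg or StreamConfig()
    forces = source.forces if isinstance(source, RawRecording) else np.asarray(source, float)
    if normalization is not None:
        offsets = np.asarray(normalization.offsets)[:, None]
        forces = (forces - offsets) / normalization.scale
    w = cfg.window_samples
    n_windows = forces.shape[1] // w
    windows = forces[:, : n_windows * w].reshape(forces.shape[0], n_windows, w)
    means = windows.mean(axis=2)
    sds = windows.std(axis=2, ddof=1)
    full = np.vstack([means, sds]).T  # (n_windows, 6) in canonical column order
    columns = feature_columns()
    take = [columns.index(name) for name in model.feature_names]
    codes = model.predict(full[:, take])
    return [
        StreamDecision(i, GestureLabel(int(c))) for i, c in enumerate(codes)
    ]


def calibration_session(
    session: Session,
    trainer,
    cfg: SegmentationConfig | None = None,
) -> tuple[TrainedModel, Normalization, GestureDatabase]:
    """Calibration phase: run the batch pipeline on a full protocol session
    and train the classifier exactly as the offline path would.

    Returns the trained model, the session normalization (needed to stream
    raw samples through the model) and the calibration database.  Raises
    :class:`MissingClassError` if any protocol gesture produced no usable
    instance.
    """
    db = session_database(session, cfg)
    expected = {int(g) for g in session.gestures}
    present = set(int(c) for c in db.classes)
    if present != expected:
        missing = sorted(
            GestureLabel(c).name.lower() for c in expected - present
        )
        raise MissingClassError(f"calibration recording missing classes: {missing}")
    rest_ref = (
        session.block(GestureLabel.REST)
        if GestureLabel.REST in session.gestures
        else None
    )
    norm = compute_normalization(session.recordings, rest_ref)
    return trainer(db), norm, db


def decision_stream_writer(decisions: Sequence[StreamDecision]) -> bytes:
    """Serialize decisions as one byte per window, in order."""
    return bytes(d.byte_code for d in decisions)


def read_decision_stream(data: bytes) -> list[StreamDecision]:
    """Invert :func:`decision_stream_writer`."""
    return [StreamDecision(i, GestureLabel(b)) for i, b in enumerate(data)]


def plateau_majority_labels(
    decisions: Sequence[StreamDecision],
    rec: RawRecording,
    cfg: StreamConfig | None = None,
) -> list[tuple[GestureLabel, GestureLabel]]:
    """(true, decoded) label per ground-truth plateau, where the decoded
    label is the majority vote of the decisions whose windows lie fully
    inside the plateau.  Used to tally per-gesture real-time recognition."""
    cfg = cfg or StreamConfig()
    w = cfg.window_samples
    out = []
    for entry in rec.timeline:
        first = -(-entry.start_sample // w)  # first window fully inside
        last = entry.end_sample // w  # one past the last full window
        codes = [d.label.code for d in decisions[first:last]]
        if not codes:
            continue
        counts = np.bincount(codes)
        out.append((entry.label, GestureLabel(int(np.argmax(counts)))))
    return out
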