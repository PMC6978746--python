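"""In-memory container for multichannel armband force recordings."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .labels import N_CHANNELS, GestureLabel


@dataclass(frozen=True)
class TimelineEntry:
    """Ground-truth plateau interval ``[start_sample, end_sample)``."""

    start_sample: int
    end_sample: int
    label: GestureLabel

    def __post_init__(self):
        if not 0 <= self.start_sample < self.end_sample:
            raise ValueError(
                f"invalid interval [{self.start_sample}, {self.end_sample})"
            )

    @property
    def n_samples(self) -> int:
        return self.end_sample - self.start_sample


@dataclass
class RawRecording:
    """A 3-channel force trace in kilograms at a fixed sampling rate.

    ``forces`` has shape ``(3, n_samples)`` with row ``i`` holding FSR ``i+1``.
    ``timeline`` optionally records the ground-truth held-posture intervals
    (half-open, 0-based sample indices, sorted and non-overlapping).
    """

    forces: np.ndarray
    sampling_rate: float
    timeline: list[TimelineEntry] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self):
        self.forces = np.asarray(self.forces, dtype=float)
        if self.forces.ndim != 2 or self.forces.shape[0] != N_CHANNELS:
            raise ValueError(
                f"forces must have shape (3, n); got {self.forces.shape}"
            )
        if not np.all(np.isfinite(self.forces)):
            raise ValueError("forces contain non-finite samples")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        prev_end = 0
        for entry in self.timeline:
            if entry.start_sample < prev_end:
                raise ValueError("timeline intervals must be sorted and disjoint")
            if entry.end_sample > self.n_samples:
                raise ValueError("timeline interval exceeds recording length")
            prev_end = entry.end_sample

    @property
    def n_samples(self) -> int:
        return self.forces.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    def with_forces(self, forces: np.ndarray) -> "RawRecording":
        """Copy of this recording with a new force array (same timeline)."""
        return replace(self, forces=forces, timeline=list(self.timeline))
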