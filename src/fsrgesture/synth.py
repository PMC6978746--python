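"""Synthetic 3-channel armband recordings.

Each gesture repetition is a trapezoidal force burst (linear rise, held
plateau, linear fall) on top of the armband fastening preload, with
gesture-specific plateau amplitudes per muscle channel, i.i.d. Gaussian
force noise, and per-subject multiplicative scale / additive offset
mimicking armband placement variability.  Forces are clamped at 0 kg
(an FSR cannot report negative force).

The default plateau matrix encodes the functional anatomy of the three
instrumented muscles: flexor carpi ulnaris (FSR1) dominates wrist flexion
and adduction, flexor carpi radialis (FSR2) wrist flexion and abduction,
extensor digitorum (FSR3) wrist extension and fingers abduction; a
clenched fist co-contracts all three.  Plateau columns of distinct
gestures are separated by well over six noise standard deviations, so the
per-subject feature clusters occupy non-overlapping regions of the
(FSR1, FSR2, FSR3) mean-force space.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .acquisition import AcquisitionConfig
from .labels import ACTIVE_GESTURES, N_CHANNELS, PROTOCOL_ORDER, GestureLabel
from .recording import RawRecording, TimelineEntry


@dataclass(frozen=True)
class ActivationProfile:
    """Timing, amplitude and noise model of one subject's gesture bursts.

    ``plateau_force`` is a (3, 8) matrix of held-posture forces in kg,
    channel x gesture code.  Times are in seconds; ``preload`` is the
    armband fastening force common to all channels; ``noise_sd`` the
    per-sample Gaussian force noise; ``subject_scale``/``subject_offset``
    the per-channel placement variability (identity by default).
    """

    plateau_force: np.ndarray
    rise_time: float = 0.1
    hold_time: float = 2.0
    fall_time: float = 0.1
    rest_gap: float = 1.5
    preload: float = 0.1  # kg
    noise_sd: float = 0.02  # kg
    subject_scale: tuple[float, float, float] = (1.0, 1.0, 1.0)
    subject_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        object.__setattr__(
            self, "plateau_force", np.asarray(self.plateau_force, dtype=float)
        )
        if self.plateau_force.shape != (N_CHANNELS, len(GestureLabel)):
            raise ValueError(
                f"plateau_force must be (3, 8); got {self.plateau_force.shape}"
            )
        if np.any(self.plateau_force[:, GestureLabel.REST] != 0.0):
            raise ValueError("rest column of plateau_force must be zero")
        if self.preload < 0 or self.noise_sd < 0:
            raise ValueError("preload and noise_sd must be non-negative")
        if min(self.rise_time, self.hold_time, self.fall_time, self.rest_gap) < 0:
            raise ValueError("timing parameters must be non-negative")

    @property
    def cycle_time(self) -> float:
        """Duration of one repetition cycle (burst plus following rest gap)."""
        return self.rise_time + self.hold_time + self.fall_time + self.rest_gap


def default_activation_profile() -> ActivationProfile:
    """Default cohort conditions: 0.1 kg preload, ~1 kg full-scale plateaus,
    noise SD 2% of the largest plateau, brisk (~100 ms) posture transitions,
    2 s holds separated by 1.5 s rest gaps."""
    plateau = np.zeros((N_CHANNELS, len(GestureLabel)))
    #                         FSR1   FSR2   FSR3
    amplitudes = {            # (FCU,  FCR,  ED) kg
        GestureLabel.WRIST_FLEXION: (0.80, 0.70, 0.10),
        GestureLabel.WRIST_EXTENSION: (0.10, 0.10, 0.90),
        GestureLabel.WRIST_ADDUCTION: (0.90, 0.20, 0.15),
        GestureLabel.WRIST_ABDUCTION: (0.15, 0.85, 0.20),
        GestureLabel.WRIST_ROTATION: (0.45, 0.40, 0.35),
        GestureLabel.FINGERS_ABDUCTION: (0.25, 0.20, 0.70),
        GestureLabel.CLENCHED_FIST: (0.60, 0.55, 1.00),
    }
    for gesture, amps in amplitudes.items():
        plateau[:, gesture] = amps
    return ActivationProfile(plateau_force=plateau)


#: Inter-subject variability model: lognormal per-channel gain (sigma of the
#: underlying normal) and uniform per-channel offset half-range in kg.
SUBJECT_SCALE_SIGMA = 0.25
SUBJECT_OFFSET_RANGE = 0.05


def subject_profile(
    base: ActivationProfile,
    seed: int | np.random.Generator,
    subject_id: str = "",
) -> ActivationProfile:
    """Draw one subject's placement variability around a base profile.

    The per-channel multiplicative scale is lognormal (sigma=0.25) and the
    additive offset uniform on +-0.05 kg, both fixed for the subject.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    scale = tuple(rng.lognormal(0.0, SUBJECT_SCALE_SIGMA, N_CHANNELS))
    offset = tuple(rng.uniform(-SUBJECT_OFFSET_RANGE, SUBJECT_OFFSET_RANGE, N_CHANNELS))
    return replace(base, subject_scale=scale, subject_offset=offset)


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_gesture_sequence(
    profile: ActivationProfile,
    labels: Sequence[GestureLabel],
    acq: AcquisitionConfig | None = None,
    seed: int | np.random.Generator = 0,
    subject_id: str = "",
) -> RawRecording:
    """Generate one burst per element of ``labels`` (in order).

    The trace starts with one rest gap, then for each label a trapezoid
    (rise, hold, fall) followed by a rest gap.  The ground-truth timeline
    records every held plateau interval with its label, including rest
    "bursts" (which have zero amplitude but a defined hold window).
    """
    if len(labels) == 0:
        raise ValueError("labels must be non-empty")
    acq = acq or AcquisitionConfig()
    rng = _as_rng(seed)
    fs = acq.sampling_rate
    n_rise = round(profile.rise_time * fs)
    n_hold = round(profile.hold_time * fs)
    n_fall = round(profile.fall_time * fs)
    n_gap = round(profile.rest_gap * fs)
    n_burst = n_rise + n_hold + n_fall
    total = n_gap + len(labels) * (n_burst + n_gap)

    envelope = np.zeros(total)
    gesture_idx = np.zeros(total, dtype=int)
    timeline: list[TimelineEntry] = []
    pos = n_gap
    for label in labels:
        if n_rise:
            envelope[pos : pos + n_rise] = np.arange(1, n_rise + 1) / n_rise
        envelope[pos + n_rise : pos + n_rise + n_hold] = 1.0
        if n_fall:
            envelope[pos + n_rise + n_hold : pos + n_burst] = (
                1.0 - np.arange(1, n_fall + 1) / n_fall
            )
        gesture_idx[pos : pos + n_burst] = label.code
        timeline.append(TimelineEntry(pos + n_rise, pos + n_rise + n_hold, label))
        pos += n_burst + n_gap

    amplitude = profile.plateau_force[:, gesture_idx] * envelope
    scale = np.asarray(profile.subject_scale)[:, None]
    offset = np.asarray(profile.subject_offset)[:, None]
    noise = rng.normal(0.0, profile.noise_sd, size=(N_CHANNELS, total))
    forces = profile.preload + offset + scale * amplitude + noise
    np.clip(forces, 0.0, None, out=forces)
    return RawRecording(forces, fs, timeline, subject_id=subject_id)


def generate_trial(
    profile: ActivationProfile,
    repetitions: int,
    gestures: Sequence[GestureLabel],
    acq: AcquisitionConfig | None = None,
    seed: int | np.random.Generator = 0,
    subject_id: str = "",
) -> RawRecording:
    """Generate ``repetitions`` consecutive bursts of each gesture in turn.

    Mirrors the acquisition protocol: within a trial each gesture class is
    repeated back-to-back (block structure), every repetition holding the
    posture for ``hold_time`` and resting for ``rest_gap``.  The timeline
    contains exactly ``repetitions * len(gestures)`` plateau intervals.
    """
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    if len(gestures) == 0:
        raise ValueError("gestures must be non-empty")
    labels = [g for g in gestures for _ in range(repetitions)]
    return generate_gesture_sequence(
        profile, labels, acq=acq, seed=seed, subject_id=subject_id
    )


@dataclass
class Session:
    """One subject's full recording session: one block recording per gesture
    class, in protocol order."""

    recordings: list[RawRecording]
    gestures: list[GestureLabel]
    profile: ActivationProfile
    acq: AcquisitionConfig
    repetitions: int
    subject_id: str = ""

    def block(self, gesture: GestureLabel) -> RawRecording:
        return self.recordings[self.gestures.index(gesture)]


def simulate_session(
    profile: ActivationProfile,
    repetitions: int = 10,
    acq: AcquisitionConfig | None = None,
    seed: int | np.random.Generator = 0,
    subject_id: str = "",
    gestures: Sequence[GestureLabel] = PROTOCOL_ORDER,
) -> Session:
    """Simulate the full protocol: for each gesture class (rest first, then
    the seven active gestures) one block of ``repetitions`` repetitions."""
    acq = acq or AcquisitionConfig()
    rng = _as_rng(seed)
    recs = [
        generate_trial(
            profile, repetitions, [g], acq=acq, seed=rng, subject_id=subject_id
        )
        for g in gestures
    ]
    return Session(recs, list(gestures), profile, acq, repetitions, subject_id)


def random_active_sequence(
    n_gestures: int, seed: int | np.random.Generator
) -> list[GestureLabel]:
    """Randomized sequence of active gestures (rest separates bursts by
    construction of the generator), as used in a second-session test."""
    rng = _as_rng(seed)
    codes = rng.integers(0, len(ACTIVE_GESTURES), size=n_gestures)
    return [ACTIVE_GESTURES[c] for c in codes]
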