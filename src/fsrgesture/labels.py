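"""Gesture classes and sensor channels of the three-FSR armband.

The armband carries three force-sensitive resistors (FSRs), each coupled to
one superficial forearm muscle, and the protocol discriminates eight hand
postures (rest plus seven active gestures).  Gesture byte codes 0-7 follow
the acquisition protocol ordering and double as the one-byte codes emitted
by the real-time decoder.
"""

from __future__ import annotations

import enum


class GestureLabel(enum.IntEnum):
    """The eight hand postures, in protocol order. ``int(label)`` is the code."""

    REST = 0
    WRIST_FLEXION = 1
    WRIST_EXTENSION = 2
    WRIST_ADDUCTION = 3
    WRIST_ABDUCTION = 4
    WRIST_ROTATION = 5  # supination
    FINGERS_ABDUCTION = 6
    CLENCHED_FIST = 7

    @property
    def code(self) -> int:
        return int(self)

    @classmethod
    def from_name(cls, name: str) -> "GestureLabel":
        try:
            return cls[name.strip().upper()]
        except KeyError:
            raise ValueError(f"unknown gesture label {name!r}") from None


#: Protocol ordering of the recording session (one block per class).
PROTOCOL_ORDER: tuple[GestureLabel, ...] = tuple(GestureLabel)

#: Active (non-rest) gestures.
ACTIVE_GESTURES: tuple[GestureLabel, ...] = tuple(
    g for g in GestureLabel if g is not GestureLabel.REST
)


class SensorChannel(enum.IntEnum):
    """The three FSR channels; the value is the 1-based channel index."""

    FSR1 = 1  # flexor carpi ulnaris
    FSR2 = 2  # flexor carpi radialis
    FSR3 = 3  # extensor digitorum

    @property
    def muscle(self) -> str:
        return _MUSCLES[self]

    @property
    def array_index(self) -> int:
        """0-based row index into a (3, n_samples) force array."""
        return int(self) - 1


_MUSCLES = {
    SensorChannel.FSR1: "flexor_carpi_ulnaris",
    SensorChannel.FSR2: "flexor_carpi_radialis",
    SensorChannel.FSR3: "extensor_digitorum",
}

N_CHANNELS = 3
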