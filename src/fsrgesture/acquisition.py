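"""Sensor transduction model: FSR conductance -> current mirror -> ADC.

Each FSR is conditioned by a BJT current mirror that replicates the sensor
current through a per-channel gain resistor R_G, so the output voltage is

    V_out = R_G * V_CC * G(F),        G(F) = G0 + s * F,

linear in the applied force F (kg) up to sensor saturation: ``G0`` is the
rest conductance and ``s`` the conductance sensitivity in siemens per kg.
The three gain resistors (850, 790, 960 ohm) are chosen to equalize the
volts-per-kg slope across channels; acquisition is 1 kHz / 12-bit over the
0-5 V supply range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .labels import N_CHANNELS
from .recording import RawRecording


@dataclass(frozen=True)
class AcquisitionConfig:
    """Analog front-end and ADC parameters."""

    sampling_rate: float = 1000.0  # Hz
    adc_bits: int = 12
    v_cc: float = 5.0  # volts
    gain_resistances: tuple[float, ...] = (850.0, 790.0, 960.0)  # ohms

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if self.adc_bits < 1:
            raise ConfigurationError("adc_bits must be >= 1")
        if len(self.gain_resistances) != N_CHANNELS:
            raise ConfigurationError("need one gain resistance per channel")
        if any(r <= 0 for r in self.gain_resistances):
            raise ConfigurationError("gain resistances must be positive")

    @property
    def adc_step(self) -> float:
        """One ADC quantization step in volts."""
        return self.v_cc / 2**self.adc_bits


@dataclass(frozen=True)
class FsrCalibration:
    """Per-channel affine conductance model of the static calibration.

    ``conductance_offset`` (S) is the conductance under the fastening preload
    alone; ``sensitivity`` (S/kg) the slope; ``saturation_force`` (kg) the
    force beyond which the sensor no longer responds.
    """

    conductance_offset: tuple[float, ...]
    sensitivity: tuple[float, ...]
    saturation_force: tuple[float, ...]

    def __post_init__(self):
        n = len(self.conductance_offset)
        if not (len(self.sensitivity) == len(self.saturation_force) == n):
            raise ConfigurationError("calibration field lengths disagree")
        if any(s <= 0 for s in self.sensitivity):
            raise ConfigurationError("sensitivities must be positive")

    @property
    def n_channels(self) -> int:
        return len(self.sensitivity)


def default_calibration(acq: AcquisitionConfig | None = None) -> FsrCalibration:
    """Calibration with channel gains equalized through the gain resistors.

    Sensitivities are proportional to 1/R_G so every channel maps force to
    voltage with the same slope (2 V/kg), and rest conductances give a common
    0.25 V baseline; ~1 kg plateaus then land mid-range on the 12-bit ADC.
    """
    acq = acq or AcquisitionConfig()
    slope_v_per_kg = 2.0
    baseline_v = 0.25
    sens = tuple(slope_v_per_kg / (acq.v_cc * r) for r in acq.gain_resistances)
    offs = tuple(baseline_v / (acq.v_cc * r) for r in acq.gain_resistances)
    sat = tuple(2.0 for _ in acq.gain_resistances)
    return FsrCalibration(offs, sens, sat)


def _check_channels(calib: FsrCalibration, n_channels: int) -> None:
    if calib.n_channels != n_channels:
        raise ConfigurationError(
            f"calibration has {calib.n_channels} channels, recording {n_channels}"
        )


def volts_per_kg(calib: FsrCalibration, acq: AcquisitionConfig) -> np.ndarray:
    """Per-channel transduction slope below saturation (V/kg)."""
    rg = np.asarray(acq.gain_resistances)
    return rg * acq.v_cc * np.asarray(calib.sensitivity)


def transduce(
    rec: RawRecording | np.ndarray,
    calib: FsrCalibration | None = None,
    acq: AcquisitionConfig | None = None,
) -> np.ndarray:
    """Convert a force trace (kg) to the digitized output voltages (V).

    Applies per channel the affine conductance model up to the saturation
    force, clamps the output to [0, V_CC] and quantizes to ``adc_bits``
    levels (round-to-nearest code over the supply range).
    """
    acq = acq or AcquisitionConfig()
    calib = calib or default_calibration(acq)
    forces = rec.forces if isinstance(rec, RawRecording) else np.asarray(rec, float)
    _check_channels(calib, forces.shape[0])
    rg = np.asarray(acq.gain_resistances)[:, None]
    g0 = np.asarray(calib.conductance_offset)[:, None]
    s = np.asarray(calib.sensitivity)[:, None]
    sat = np.asarray(calib.saturation_force)[:, None]
    f = np.minimum(forces, sat)
    v = rg * acq.v_cc * (g0 + s * f)
    v = np.clip(v, 0.0, acq.v_cc)
    step = acq.adc_step
    codes = np.clip(np.round(v / step), 0, 2**acq.adc_bits - 1)
    return codes * step


def saturation_voltage(
    calib: FsrCalibration, acq: AcquisitionConfig
) -> np.ndarray:
    """Per-channel output voltage at the saturation force (clamped to V_CC)."""
    rg = np.asarray(acq.gain_resistances)
    g0 = np.asarray(calib.conductance_offset)
    s = np.asarray(calib.sensitivity)
    sat = np.asarray(calib.saturation_force)
    return np.minimum(rg * acq.v_cc * (g0 + s * sat), acq.v_cc)


def inverse_calibrate(
    voltages: np.ndarray,
    calib: FsrCalibration | None = None,
    acq: AcquisitionConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Invert the transduction back to forces in kg.

    Returns ``(forces, saturated)``: samples at or above the saturation
    voltage (within half an ADC step) are flagged in the boolean mask and
    set to NaN rather than inverted, since the affine model does not hold
    there.  Unsaturated samples round-trip within one ADC step divided by
    the volts-per-kg slope.
    """
    acq = acq or AcquisitionConfig()
    calib = calib or default_calibration(acq)
    v = np.asarray(voltages, dtype=float)
    _check_channels(calib, v.shape[0])
    if np.any(v < -1e-12) or np.any(v > acq.v_cc + 1e-12):
        raise ValueError("voltages outside [0, V_CC]")
    rg = np.asarray(acq.gain_resistances)[:, None]
    g0 = np.asarray(calib.conductance_offset)[:, None]
    s = np.asarray(calib.sensitivity)[:, None]
    sat_v = saturation_voltage(calib, acq)[:, None]
    saturated = v >= sat_v - 0.5 * acq.adc_step
    forces = (v / (rg * acq.v_cc) - g0) / s
    forces = np.where(saturated, np.nan, forces)
    return forces, saturated
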