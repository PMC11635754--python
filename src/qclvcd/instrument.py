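"""Instrument configuration for a pulsed EC-QCL VCD spectrometer.

The instrument model: a pulsed external-cavity quantum cascade laser sweeps
its emission wavenumber linearly in time while a photoelastic modulator (PEM)
in the sample arm modulates the polarization between left- and right-handed
circular states at its resonance frequency.  The laser pulse train is
phase-locked to the PEM cycle (an exact integer number of pulses per
modulation period), and a balanced detector pair (sample minus reference)
suppresses common-mode laser noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "PemSettings",
    "LaserSettings",
    "InstrumentConfig",
    "pem_retardation",
    "narrowband_config",
    "broadband_config",
    "scaled_test_config",
    "pathlength_snr_factor",
]

#: Amide I' window limits (cm^-1) used for fixture validity checks.
AMIDE_I_REGION = (1580.0, 1710.0)


@dataclass(frozen=True)
class PemSettings:
    """Photoelastic modulator drive parameters.

    The PEM imposes a sinusoidal retardation delta(t) = delta0 * sin(2*pi*f*t).
    At fixed mechanical drive the peak retardation delta0 scales linearly with
    wavenumber; it is specified by a setpoint (default: half-wave/2 = pi/2 rad
    at 1555 cm^-1).
    """

    frequency: float = 5.0e4  # Hz
    retardation_setpoint: float = math.pi / 2  # radians
    setpoint_wavenumber: float = 1555.0  # cm^-1

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("PEM frequency must be positive")
        if not (0 < self.retardation_setpoint <= math.pi):
            raise ValueError("retardation_setpoint must be in (0, pi]")
        if self.setpoint_wavenumber <= 0:
            raise ValueError("setpoint_wavenumber must be positive")


@dataclass(frozen=True)
class LaserSettings:
    """Pulsed EC-QCL sweep and emission parameters.

    ``emission_envelope`` is a parametric stand-in for the laser's spectral
    emission profile: a flat-top (fourth-order) super-Gaussian of the given
    center and width riding on a constant floor fraction of the peak.
    """

    pulse_rate: float = 4.0e5  # Hz
    pulse_width: float = 7.0e-7  # s
    sweep_start: float = 1580.0  # cm^-1
    sweep_stop: float = 1710.0  # cm^-1
    sweep_speed: float = 40.0  # cm^-1 / s
    emission_envelope: tuple[float, float, float] = (1560.0, 220.0, 0.3)

    def __post_init__(self) -> None:
        if self.pulse_rate <= 0 or self.pulse_width <= 0:
            raise ValueError("pulse_rate and pulse_width must be positive")
        if self.pulse_width * self.pulse_rate > 1:
            raise ValueError("pulse duty cycle cannot exceed 1")
        if self.sweep_stop <= self.sweep_start:
            raise ValueError("sweep_stop must exceed sweep_start")
        if self.sweep_speed <= 0:
            raise ValueError("sweep_speed must be positive")
        center, width, floor = self.emission_envelope
        if width <= 0 or not (0 <= floor <= 1) or center <= 0:
            raise ValueError("invalid emission envelope parameters")

    @property
    def duty_cycle(self) -> float:
        """Fraction of time the laser is on: pulse_width x pulse_rate."""
        return self.pulse_width * self.pulse_rate

    @property
    def sweep_duration(self) -> float:
        """Duration of one sweep in seconds."""
        return (self.sweep_stop - self.sweep_start) / self.sweep_speed

    def envelope(self, wavenumber: np.ndarray | float) -> np.ndarray | float:
        """Relative laser intensity vs wavenumber (peak = 1)."""
        center, width, floor = self.emission_envelope
        x = (np.asarray(wavenumber, dtype=float) - center) / width
        return floor + (1.0 - floor) * np.exp(-(x**4))


@dataclass(frozen=True)
class InstrumentConfig:
    """Full acquisition configuration: laser, PEM, detection and sampling."""

    laser: LaserSettings = field(default_factory=LaserSettings)
    pem: PemSettings = field(default_factory=PemSettings)
    output_rate: float = 838.0  # Sa/s, decimated lock-in output
    path_length: float = 204.0  # micrometers
    lockin_time_constant: float = 0.010  # s
    balance_gain: float = 1.0  # reference-arm gain in the subtraction
    intensity_floor: float = 1e-6  # of envelope max; below -> total absorption
    max_pulses_per_scan: int = 20_000_000  # memory budget for one sweep

    def __post_init__(self) -> None:
        if self.output_rate <= 0:
            raise ValueError("output_rate must be positive")
        if self.output_rate > self.laser.pulse_rate:
            raise ValueError("output_rate cannot exceed the pulse rate")
        if self.path_length <= 0:
            raise ValueError("path_length must be positive")
        if self.lockin_time_constant <= 0:
            raise ValueError("lockin_time_constant must be positive")
        ratio = self.laser.pulse_rate / self.pem.frequency
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ValueError(
                "pulse_rate must be an exact integer multiple of the PEM "
                f"frequency (got ratio {ratio})"
            )

    @property
    def pulses_per_pem_cycle(self) -> int:
        return round(self.laser.pulse_rate / self.pem.frequency)

    @property
    def path_length_mm(self) -> float:
        return self.path_length / 1000.0

    @property
    def samples_per_wavenumber(self) -> float:
        """Decimated output samples per cm^-1 of sweep."""
        return self.output_rate / self.laser.sweep_speed

    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "InstrumentConfig":
        d = dict(d)
        laser = dict(d.pop("laser"))
        laser["emission_envelope"] = tuple(laser["emission_envelope"])
        return InstrumentConfig(
            laser=LaserSettings(**laser), pem=PemSettings(**d.pop("pem")), **d
        )


def pem_retardation(wavenumber, pem: PemSettings):
    """Peak PEM retardation delta0 (radians) at a given wavenumber.

    At fixed drive voltage the optical path difference of the PEM is constant,
    so the retardation in radians grows linearly with wavenumber:
    delta0(v) = setpoint * v / setpoint_wavenumber.
    """
    wn = np.asarray(wavenumber, dtype=float)
    if np.any(wn <= 0):
        raise ValueError("wavenumber must be positive")
    out = pem.retardation_setpoint * wn / pem.setpoint_wavenumber
    return float(out) if np.isscalar(wavenumber) else out


def narrowband_config(**overrides) -> InstrumentConfig:
    """Amide-I'-only acquisition: 1580-1710 cm^-1 sweep (the fast mode)."""
    laser = LaserSettings(sweep_start=1580.0, sweep_stop=1710.0)
    return InstrumentConfig(laser=laser, **overrides)


def broadband_config(**overrides) -> InstrumentConfig:
    """Broadband acquisition: 1400-1710 cm^-1 sweep."""
    laser = LaserSettings(sweep_start=1400.0, sweep_stop=1710.0)
    return InstrumentConfig(laser=laser, **overrides)


def scaled_test_config(
    sweep_start: float = 1580.0, sweep_stop: float = 1710.0, **overrides
) -> InstrumentConfig:
    """Downscaled configuration for fast tests.

    All frequency ratios of the full instrument are preserved (8 pulses per
    PEM cycle, ~477 pulses per output sample, same sweep speed), with the PEM
    at 5 kHz and the laser at 40 kHz so a sweep costs 10x fewer pulses.
    """
    laser = LaserSettings(
        pulse_rate=4.0e4,
        pulse_width=7.0e-6,
        sweep_start=sweep_start,
        sweep_stop=sweep_stop,
    )
    pem = PemSettings(frequency=5.0e3)
    overrides.setdefault("output_rate", 83.8)
    return InstrumentConfig(laser=laser, pem=pem, **overrides)


def pathlength_snr_factor(path_length: float, reference_path: float) -> float:
    """Signal gain of a longer transmission cell over a reference cell.

    Absorbance (and VCD) signals scale linearly with path length, so at equal
    noise the SNR advantage is simply the path-length ratio (204/23 ~ 9 for
    this instrument vs. a typical FT-IR VCD cell).
    """
    if path_length <= 0 or reference_path <= 0:
        raise ValueError("path lengths must be positive")
    return path_length / reference_path
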