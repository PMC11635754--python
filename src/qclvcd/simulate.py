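"""Pulse-level simulation of balanced-detection PEM-VCD scans.

Each laser pulse is represented by a single energy sample (the lock-in acts
on pulse energies, so sub-pulse structure is irrelevant).  The pulse train is
phase-locked to the PEM: with 8 pulses per modulation period and the default
phase offset theta0 = pi/2, exactly two of every eight pulses land on the
retardation extrema (|sin theta| = 1), i.e. 25% of the laser intensity is
spent at the maximum of the PEM cycle.

Sample-arm pulse energy (first order in dA, adequate at dA ~ 1e-4):

    I_k = env(v_k) * 10^(-A(v_k)) * [1 + ln(10)/2 * dA(v_k) * sin(d0(v_k) sin theta_k)]

times a common-mode noise factor shared with the reference arm, plus
detector-independent white noise and a static interference-fringe term.
The reference arm sees the envelope, the transmission of a matched
solvent-filled reference cell (same path length as the sample cell, so the
two detector intensities stay as equal as possible across the sweep — the
condition for the balanced subtraction to cancel common-mode noise) and the
common-mode factor, but no PEM or analyte terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .instrument import InstrumentConfig, pem_retardation
from .samples import SampleModel

__all__ = [
    "NoiseModel",
    "RawScan",
    "simulate_scan",
    "simulate_reference_offset",
    "pem_phase_offset_default",
]

#: Default pulse-train phase offset relative to the PEM cycle: pulses straddle
#: the retardation extrema (matches the 25%-of-intensity-at-maximum timing).
pem_phase_offset_default = np.pi / 2


@dataclass(frozen=True)
class NoiseModel:
    """Stochastic model of the laser + detection chain.

    pulse_rsd : effective relative SD of per-pulse energy as seen by the
        demodulator (QCL pulse-to-pulse jitter after pulse integration).
    common_mode_fraction : share of the pulse-energy variance common to both
        detectors (what balanced detection can cancel), 0..1.
    drift_amplitude, drift_exponent : multiplicative 1/f^alpha drift envelope
        (relative amplitude at the sweep timescale; alpha typically ~1).
    white_noise_sd : additive detector noise per pulse, relative to the
        envelope peak, independent between the two detectors.
    fringe_amplitude, fringe_period, fringe_phase : static interference
        fringes (wire-grid polarizer etalon) on the sample arm, additive,
        sinusoidal in wavenumber.
    """

    pulse_rsd: float = 0.002
    common_mode_fraction: float = 0.995
    drift_amplitude: float = 1e-3
    drift_exponent: float = 1.0
    white_noise_sd: float = 5e-4
    fringe_amplitude: float = 1e-3
    fringe_period: float = 1.2  # cm^-1
    fringe_phase: float = 0.0

    def __post_init__(self) -> None:
        for name in ("pulse_rsd", "drift_amplitude", "white_noise_sd", "fringe_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.common_mode_fraction <= 1):
            raise ValueError("common_mode_fraction must be in [0, 1]")
        if self.fringe_period <= 0:
            raise ValueError("fringe_period must be positive")

    def scaled_for_average(self, n_sweeps: int) -> "NoiseModel":
        """Noise model of the mean of ``n_sweeps`` phase-locked sweeps.

        Every stochastic term is Gaussian and independent between sweeps, and
        the demodulation chain is linear, so the sweep average is exactly
        distributed as a single sweep with the random amplitudes scaled by
        1/sqrt(n); static terms (fringes) are unchanged.  Drift realizations
        are treated as independent between sweeps (no cross-sweep 1/f
        correlation is modeled).
        """
        if n_sweeps < 1:
            raise ValueError("n_sweeps must be >= 1")
        s = 1.0 / np.sqrt(n_sweeps)
        return NoiseModel(
            pulse_rsd=self.pulse_rsd * s,
            common_mode_fraction=self.common_mode_fraction,
            drift_amplitude=self.drift_amplitude * s,
            drift_exponent=self.drift_exponent,
            white_noise_sd=self.white_noise_sd * s,
            fringe_amplitude=self.fringe_amplitude,
            fringe_period=self.fringe_period,
            fringe_phase=self.fringe_phase,
        )

    @staticmethod
    def noiseless() -> "NoiseModel":
        return NoiseModel(
            pulse_rsd=0.0,
            drift_amplitude=0.0,
            white_noise_sd=0.0,
            fringe_amplitude=0.0,
        )


@dataclass
class RawScan:
    """Per-pulse detector record for one sweep.

    The balanced stream is sample - balance_gain * reference by construction.
    """

    pulse_times: np.ndarray  # s, strictly increasing at 1/pulse_rate
    sample_amplitudes: np.ndarray
    reference_amplitudes: np.ndarray
    balanced_amplitudes: np.ndarray
    sweep_start: float
    sweep_stop: float
    sweep_speed: float
    sweep_direction: int = +1  # low -> high wavenumber
    pulse_rate: float = 4.0e5
    balance_gain: float = 1.0
    seed: int | None = None

    def __len__(self) -> int:
        return self.pulse_times.size

    @property
    def wavenumbers(self) -> np.ndarray:
        return self.sweep_start + self.sweep_direction * self.sweep_speed * self.pulse_times


def _drift_realization(n: int, dt: float, noise: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative 1/f^alpha drift factor over the sweep.

    Generated spectrally on a coarse grid (the drift is slow) and linearly
    interpolated to the pulse grid.
    """
    if noise.drift_amplitude == 0.0:
        return np.ones(n)
    m = 4096
    freqs = np.fft.rfftfreq(m, d=n * dt / m)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-noise.drift_exponent / 2.0)
    phases = rng.uniform(0, 2 * np.pi, size=freqs.size)
    coarse = np.fft.irfft(amp * np.exp(1j * phases), n=m)
    coarse *= noise.drift_amplitude / max(np.std(coarse), 1e-30)
    x = np.linspace(0.0, 1.0, m)
    return 1.0 + np.interp(np.linspace(0.0, 1.0, n), x, coarse)


def simulate_scan(
    config: InstrumentConfig,
    sample: SampleModel,
    noise: NoiseModel | None = None,
    seed: int = 0,
    phase_offset: float = pem_phase_offset_default,
) -> RawScan:
    """Simulate one full sweep of per-pulse detector amplitudes.

    Deterministic: identical inputs (including seed) give a bit-identical
    RawScan.
    """
    noise = noise or NoiseModel()
    laser = config.laser
    n = int(np.floor(laser.sweep_duration * laser.pulse_rate))
    if n > config.max_pulses_per_scan:
        raise MemoryError(
            f"sweep of {n} pulses exceeds the configured budget of "
            f"{config.max_pulses_per_scan}; simulate and demodulate "
            "sweep-by-sweep (streaming) instead of in one call"
        )
    rng = np.random.default_rng(seed)
    dt = 1.0 / laser.pulse_rate
    k = np.arange(n)
    t = k * dt
    wn = laser.sweep_start + laser.sweep_speed * t

    # PEM phase of each pulse; exact integer pulses per period => the multiset
    # of phases repeats identically every cycle (phase lock).
    theta = 2.0 * np.pi * config.pem.frequency * t + phase_offset
    delta0 = pem_retardation(wn, config.pem)

    env = laser.envelope(wn)
    a_tot = sample.absorbance(wn, config.path_length_mm)
    da = sample.vcd(wn, config.path_length_mm)
    transmission = 10.0 ** (-a_tot)
    # Matched reference cell: solvent transmission at the same path length.
    if hasattr(sample, "solvent_absorbance"):
        ref_transmission = 10.0 ** (-sample.solvent_absorbance(wn, config.path_length_mm))
    else:
        ref_transmission = 1.0
    pem_term = 1.0 + 0.5 * np.log(10.0) * da * np.sin(delta0 * np.sin(theta))

    # Common-mode vs independent split of the per-pulse energy jitter.
    cmf = noise.common_mode_fraction
    if noise.pulse_rsd > 0:
        z_shared = rng.standard_normal(n)
        z_s = rng.standard_normal(n)
        z_r = rng.standard_normal(n)
        common = np.sqrt(cmf) * z_shared
        f_sample = 1.0 + noise.pulse_rsd * (common + np.sqrt(1 - cmf) * z_s)
        f_ref = 1.0 + noise.pulse_rsd * (common + np.sqrt(1 - cmf) * z_r)
    else:
        f_sample = f_ref = np.ones(n)

    drift = _drift_realization(n, dt, noise, rng)
    f_sample = f_sample * drift
    f_ref = f_ref * drift

    fringe = noise.fringe_amplitude * np.sin(
        2.0 * np.pi * wn / noise.fringe_period + noise.fringe_phase
    )

    white_s = noise.white_noise_sd * rng.standard_normal(n) if noise.white_noise_sd else 0.0
    white_r = noise.white_noise_sd * rng.standard_normal(n) if noise.white_noise_sd else 0.0

    sample_amp = env * transmission * pem_term * f_sample + white_s + fringe
    ref_amp = env * ref_transmission * f_ref + white_r
    balanced = sample_amp - config.balance_gain * ref_amp

    return RawScan(
        pulse_times=t,
        sample_amplitudes=sample_amp,
        reference_amplitudes=ref_amp,
        balanced_amplitudes=balanced,
        sweep_start=laser.sweep_start,
        sweep_stop=laser.sweep_stop,
        sweep_speed=laser.sweep_speed,
        sweep_direction=+1,
        pulse_rate=laser.pulse_rate,
        balance_gain=config.balance_gain,
        seed=seed,
    )


def simulate_reference_offset(
    config: InstrumentConfig,
    noise: NoiseModel | None = None,
    seed: int = 0,
    sample: SampleModel | None = None,
):
    """Reference-detector DC record vs wavenumber (the balanced-signal offset).

    Recorded once (before the measurement, on a blank) by demodulating the
    reference-arm stream at the pulse-rate harmonic; it is added back to the
    balanced DC trace downstream to restore the sample-arm intensity level.
    ``sample`` sets the blank configuration (default: solvent only); it must
    use the same solvent as the later measurements so the reference-cell
    transmission matches.  Returns a Spectrum of kind "intensity".
    """
    from .lockin import digital_lockin, time_to_wavenumber
    from .samples import solvent_only

    if sample is None:
        sample = solvent_only()
    scan = simulate_scan(config, sample, noise=noise or NoiseModel.noiseless(), seed=seed)
    trace = digital_lockin(
        scan.pulse_times,
        scan.reference_amplitudes,
        frequency=config.laser.pulse_rate,
        phase=0.0,
        time_constant=config.lockin_time_constant,
        output_rate=config.output_rate,
        source_rate=config.laser.pulse_rate,
    )
    spec = time_to_wavenumber(trace, scan)
    spec.meta["role"] = "reference_offset"
    return spec
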