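"""High-level measurement workflows: simulate, demodulate, reduce, classify.

These functions chain the instrument simulator, the digital lock-in and the
spectral pipeline the way a measurement session would: record the reference
offset once, then per sweep demodulate the balanced stream at the PEM
fundamental (VCD channel) and at the pulse-rate harmonic (intensity channel),
map to wavenumber, reconstruct dA and the restored DC level, and finally
baseline-correct / average / smooth / background-correct the scan ensemble.
"""

from __future__ import annotations

import numpy as np

from .bands import SignatureRules, classify_signature, find_vcd_bands
from .instrument import InstrumentConfig
from .lockin import (
    compute_absorbance,
    compute_vcd,
    default_vcd_gain,
    digital_lockin,
    time_to_wavenumber,
)
from .pipeline import ScanSet, default_anchor_regions, process_scans, spline_smooth
from .samples import SampleModel, solvent_only
from .simulate import NoiseModel, RawScan, simulate_reference_offset, simulate_scan
from .spectra import Spectrum

__all__ = [
    "demodulate_sweep",
    "acquire",
    "protein_measurement",
    "estimate_noise_rms",
    "classify_spectrum",
    "scan_seeds",
]

#: Prominence threshold for band detection, in units of measured noise RMS.
PROMINENCE_SIGMA = 5.0
#: Relative prominence floor (of the strongest amplitude) guarding against
#: smoothing ripple when the measured noise is essentially zero.
RIPPLE_FLOOR = 0.08
#: Band-search region for classification, inset from the sweep edges.
CLASSIFY_REGION = (1595.0, 1700.0)


def scan_seeds(seed: int, n: int) -> list[int]:
    """Deterministic child seeds (< 2^31) for an n-scan acquisition."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s) & 0x7FFFFFFF for s in state]


def demodulate_sweep(
    scan: RawScan,
    config: InstrumentConfig,
    ref_offset: Spectrum,
    gain: float | None = None,
) -> tuple[Spectrum, Spectrum]:
    """One sweep -> (vcd, restored sample DC) spectra.

    The VCD channel is demodulated at the PEM fundamental at matched phase
    (the pulse train straddles the retardation extrema, so the modulation is
    a cosine in lab time); the intensity channel at the pulse-rate harmonic.
    """
    tc = config.lockin_time_constant
    rate = config.output_rate
    s1f = time_to_wavenumber(
        digital_lockin(scan, frequency=config.pem.frequency, phase=0.0,
                       time_constant=tc, output_rate=rate), scan)
    s8f = time_to_wavenumber(
        digital_lockin(scan, frequency=config.laser.pulse_rate, phase=0.0,
                       time_constant=tc, output_rate=rate), scan)
    vcd = compute_vcd(s1f, s8f, ref_offset, config.pem, gain=gain,
                      intensity_floor=config.intensity_floor)
    dc = Spectrum(axis=s8f.axis.copy(), values=s8f.values + ref_offset.values,
                  kind="intensity", resolution=s8f.resolution,
                  meta={"role": "restored_sample_dc"})
    return vcd, dc


def acquire(
    config: InstrumentConfig,
    sample: SampleModel,
    noise: NoiseModel,
    n_scans: int,
    seed: int,
    sweeps_per_scan: int = 1,
    ref_offset: Spectrum | None = None,
    gain: float | None = None,
) -> dict:
    """Simulate an n-scan acquisition; each scan averages sweeps_per_scan sweeps.

    The sweep average inside a scan is simulated directly: demodulation is
    linear and the noise terms are Gaussian and sweep-independent, so the
    mean of m phase-locked sweeps is exactly one sweep with noise amplitudes
    scaled by 1/sqrt(m) (NoiseModel.scaled_for_average).  Returns
    {"vcd": ScanSet, "dc": ScanSet, "ref_offset": Spectrum}.  Deterministic
    in (config, sample, noise, seed).
    """
    if ref_offset is None:
        ref_offset = simulate_reference_offset(config, seed=0)
    if gain is None:
        gain = default_vcd_gain(config.pem, config.pulses_per_pem_cycle)
    seeds = scan_seeds(seed, n_scans)
    scan_noise = noise.scaled_for_average(sweeps_per_scan)
    vcd_scans, dc_scans = [], []
    for i in range(n_scans):
        scan = simulate_scan(config, sample, scan_noise, seed=seeds[i])
        vcd, dc = demodulate_sweep(scan, config, ref_offset, gain=gain)
        vcd_scans.append(Spectrum(vcd.axis, vcd.values, kind="vcd",
                                  resolution=vcd.resolution, meta={"sample": sample.name}))
        dc_scans.append(Spectrum(dc.axis, dc.values, kind="intensity",
                                 resolution=dc.resolution, meta={"sample": sample.name}))
    t_scan = sweeps_per_scan * config.laser.sweep_duration
    return {
        "vcd": ScanSet(vcd_scans, acquisition_time_per_scan=t_scan),
        "dc": ScanSet(dc_scans, acquisition_time_per_scan=t_scan),
        "ref_offset": ref_offset,
    }


def protein_measurement(
    sample: SampleModel,
    config: InstrumentConfig,
    noise: NoiseModel | None = None,
    n_scans: int = 1,
    seed: int = 0,
    sweeps_per_scan: int = 1,
    target_resolution: float = 8.0,
    anchor_regions=None,
) -> dict:
    """Full measurement of a sample against a solvent background.

    Runs sample and background acquisitions, reduces the VCD ensemble
    (baseline -> average -> smooth -> background), computes the
    background-ratioed absorbance, and returns both processed spectra plus
    the stage log.
    """
    noise = noise or NoiseModel()
    ref_offset = simulate_reference_offset(config, seed=0)
    gain = default_vcd_gain(config.pem, config.pulses_per_pem_cycle)
    meas = acquire(config, sample, noise, n_scans, seed,
                   sweeps_per_scan=sweeps_per_scan, ref_offset=ref_offset, gain=gain)
    blank = acquire(config, solvent_only(), noise, n_scans, seed + 1,
                    sweeps_per_scan=sweeps_per_scan, ref_offset=ref_offset, gain=gain)

    vcd_bg, _ = process_scans(blank["vcd"], anchor_regions=anchor_regions,
                              target_resolution=target_resolution)
    vcd, log = process_scans(meas["vcd"], anchor_regions=anchor_regions,
                             target_resolution=target_resolution, background=vcd_bg)

    from .pipeline import average_scans

    sample_dc = average_scans(meas["dc"])
    background_dc = average_scans(blank["dc"])
    absorbance = spline_smooth(compute_absorbance(sample_dc, background_dc),
                               target_resolution)
    return {
        "vcd": vcd,
        "absorbance": absorbance,
        "log": log,
        "ref_offset": ref_offset,
        "acquisition_time": n_scans * sweeps_per_scan * config.laser.sweep_duration,
    }


def estimate_noise_rms(spectrum: Spectrum, regions=None) -> float:
    """Pooled RMS in band-free anchor regions (mean removed per region)."""
    if regions is None:
        regions = default_anchor_regions(spectrum.axis)
    residuals = []
    for lo, hi in regions:
        mask = (spectrum.axis >= lo) & (spectrum.axis <= hi)
        if mask.sum() >= 2:
            r = spectrum.values[mask]
            residuals.append(r - r.mean())
    if not residuals:
        return 0.0
    pooled = np.concatenate(residuals)
    return float(np.sqrt(np.mean(pooled**2)))


def classify_spectrum(
    vcd: Spectrum,
    region: tuple[float, float] = CLASSIFY_REGION,
    rules: SignatureRules | None = None,
    noise_rms: float | None = None,
) -> dict:
    """Detect amide I' VCD bands and classify the secondary structure.

    The prominence threshold is PROMINENCE_SIGMA times the measured noise
    RMS, floored at a small fraction of the strongest amplitude to reject
    smoothing ripple in nearly noiseless spectra.
    """
    if noise_rms is None:
        noise_rms = estimate_noise_rms(vcd)
    sub = vcd.restrict(*region)
    floor = RIPPLE_FLOOR * float(np.max(np.abs(sub.values))) if len(sub) else 0.0
    min_prominence = max(PROMINENCE_SIGMA * noise_rms, floor)
    features = find_vcd_bands(vcd, region=region, min_prominence=min_prominence)
    signature = classify_signature(features, rules)
    return {
        "features": features,
        "signature": signature,
        "noise_rms": noise_rms,
        "min_prominence": min_prominence,
    }
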