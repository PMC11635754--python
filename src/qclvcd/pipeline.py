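"""Per-scan conditioning and ensemble reduction.

Enforced stage order: baseline correction (per scan, before averaging, to
compensate slow drifts) -> scan averaging -> least-squares spline smoothing
to the working resolution (native 0.5 cm^-1 -> 8 cm^-1 by default) ->
solvent-background subtraction.  All four stages are linear operators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import Polynomial
from scipy.interpolate import make_lsq_spline

from .spectra import Spectrum, same_axis

__all__ = [
    "ScanSet",
    "baseline_correct",
    "average_scans",
    "spline_smooth",
    "subtract_background",
    "process_scans",
    "default_anchor_regions",
]

#: Band-free margins used for baseline fitting, by acquisition mode.
BROADBAND_ANCHORS = ((1405.0, 1420.0), (1695.0, 1705.0))
NARROWBAND_ANCHORS = ((1585.0, 1595.0), (1700.0, 1710.0))


@dataclass
class ScanSet:
    """An ensemble of repeat scans on a common axis."""

    scans: list[Spectrum]
    acquisition_time_per_scan: float  # s

    def __post_init__(self) -> None:
        if len(self.scans) < 1:
            raise ValueError("ScanSet needs at least one scan")
        if not same_axis(*self.scans):
            raise ValueError("all scans must share one axis")
        kinds = {s.kind for s in self.scans}
        if len(kinds) != 1:
            raise ValueError("all scans must have the same kind")

    def __len__(self) -> int:
        return len(self.scans)


def default_anchor_regions(axis: np.ndarray) -> tuple[tuple[float, float], ...]:
    """Band-free anchor intervals appropriate for the axis coverage."""
    return BROADBAND_ANCHORS if axis.min() < 1500.0 else NARROWBAND_ANCHORS


def _anchor_mask(axis: np.ndarray, regions) -> np.ndarray:
    mask = np.zeros(axis.shape, dtype=bool)
    for lo, hi in regions:
        mask |= (axis >= lo) & (axis <= hi)
    return mask


def baseline_correct(
    spectrum: Spectrum,
    anchor_regions=None,
    degree: int = 1,
) -> Spectrum:
    """Subtract a low-order polynomial fitted over band-free anchor regions.

    The fit sees only the anchors, so band amplitudes outside them are
    untouched up to the removed trend.
    """
    if anchor_regions is None:
        anchor_regions = default_anchor_regions(spectrum.axis)
    if not anchor_regions:
        raise ValueError("anchor_regions is empty")
    mask = _anchor_mask(spectrum.axis, anchor_regions)
    if mask.sum() <= degree:
        raise ValueError("anchor regions fall outside the spectrum axis")
    poly = Polynomial.fit(spectrum.axis[mask], spectrum.values[mask], deg=degree)
    out = spectrum.copy_with(values=spectrum.values - poly(spectrum.axis))
    out.meta["baseline"] = {"degree": degree, "anchors": list(map(tuple, anchor_regions))}
    return out


def average_scans(scan_set: ScanSet, n: int | None = None) -> Spectrum:
    """Pointwise mean of the first n scans."""
    if n is None:
        n = len(scan_set)
    if not (1 <= n <= len(scan_set)):
        raise ValueError(f"n must be in [1, {len(scan_set)}]")
    stack = np.stack([s.values for s in scan_set.scans[:n]])
    first = scan_set.scans[0]
    out = first.copy_with(values=stack.mean(axis=0))
    out.meta["n_scans"] = n
    out.meta["total_time"] = n * scan_set.acquisition_time_per_scan
    return out


def spline_smooth(spectrum: Spectrum, target_resolution: float = 8.0) -> Spectrum:
    """Least-squares cubic spline with knots spaced ``target_resolution`` apart.

    This is the resolution-matching step: the swept-laser data come out at
    ~0.5 cm^-1 native resolution and are fitted down to the conventional
    8 cm^-1 of FT-IR VCD.  A linear operator (projection onto the spline
    space), so it commutes with averaging.
    """
    x, y = spectrum.axis, spectrum.values
    if spectrum.resolution and target_resolution <= spectrum.resolution:
        raise ValueError("target_resolution must exceed the native resolution")
    span = x[-1] - x[0]
    if span < 2 * target_resolution:
        raise ValueError("axis shorter than two knot intervals")
    if not np.all(np.isfinite(y)):
        raise ValueError("cannot smooth a spectrum with masked (NaN) points")
    interior = np.arange(x[0] + target_resolution, x[-1] - 1e-9, target_resolution)
    knots = np.r_[[x[0]] * 4, interior, [x[-1]] * 4]
    spline = make_lsq_spline(x, y, knots, k=3)
    out = spectrum.copy_with(values=spline(x), resolution=float(target_resolution))
    out.meta["smoothing"] = {"type": "lsq_cubic_spline", "knot_spacing": target_resolution}
    return out


def subtract_background(spectrum: Spectrum, background: Spectrum) -> Spectrum:
    """Pointwise solvent-background subtraction (absorbance or vcd kinds)."""
    if spectrum.kind != background.kind:
        raise ValueError("spectrum and background kinds differ")
    if not same_axis(spectrum, background):
        raise ValueError("spectrum and background axes differ")
    out = spectrum.copy_with(values=spectrum.values - background.values)
    out.meta["background_subtracted"] = True
    return out


def process_scans(
    scan_set: ScanSet,
    n: int | None = None,
    anchor_regions=None,
    baseline_degree: int = 1,
    target_resolution: float = 8.0,
    background: Spectrum | None = None,
) -> tuple[Spectrum, list[str]]:
    """Run the full conditioning chain in its canonical order.

    Returns the processed spectrum and a stage log.
    """
    log = []
    corrected = [baseline_correct(s, anchor_regions, baseline_degree) for s in scan_set.scans]
    log.append(f"baseline_correct(degree={baseline_degree})")
    averaged = average_scans(
        ScanSet(corrected, scan_set.acquisition_time_per_scan), n
    )
    log.append(f"average_scans(n={averaged.meta['n_scans']})")
    smoothed = spline_smooth(averaged, target_resolution)
    log.append(f"spline_smooth(target_resolution={target_resolution})")
    if background is not None:
        smoothed = subtract_background(smoothed, background)
        log.append("subtract_background")
    smoothed.meta["pipeline"] = list(log)
    return smoothed, log
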