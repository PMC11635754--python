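"""Split-half RMS noise versus measurement time.

The scan ensemble is split into a background block (first half) and a sample
block (second half).  For m = 1..n/2 the m-scan averages of the two blocks
are differenced; the RMS of that difference over a wavenumber region, after
mean removal within the region, is the noise estimate at measurement time
m * acquisition_time_per_scan.  The mean removal makes the statistic a noise
measure rather than an offset measure; the 1/sqrt(2) of differencing two
equal-variance averages is deliberately not divided out (the curve is used
relatively, against itself and between instruments).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pipeline import ScanSet, average_scans

__all__ = ["NoiseCurve", "split_half_rms"]


@dataclass
class NoiseCurve:
    """RMS noise vs measurement time over a fixed spectral region."""

    times: np.ndarray  # minutes
    rms: np.ndarray  # dAU (or AU)
    region: tuple[float, float]
    n_pairs: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.rms = np.asarray(self.rms, dtype=float)
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.rms < 0):
            raise ValueError("rms must be non-negative")

    def loglog_slope(self) -> float:
        """Least-squares slope of log10(rms) vs log10(time)."""
        return float(np.polyfit(np.log10(self.times), np.log10(self.rms), 1)[0])

    def to_dict(self) -> dict:
        return {
            "times_min": self.times.tolist(),
            "rms": self.rms.tolist(),
            "region": list(self.region),
            "n_pairs": self.n_pairs,
        }


def split_half_rms(scan_set: ScanSet, region: tuple[float, float]) -> NoiseCurve:
    """Noise-vs-averaging curve from an even ensemble of repeat scans."""
    n = len(scan_set)
    if n < 2 or n % 2 != 0:
        raise ValueError("split_half_rms needs an even number of scans >= 2")
    axis = scan_set.scans[0].axis
    lo, hi = region
    mask = (axis >= lo) & (axis <= hi)
    if not mask.any():
        raise ValueError(f"region [{lo}, {hi}] outside the scan axis")

    half = n // 2
    background = ScanSet(scan_set.scans[:half], scan_set.acquisition_time_per_scan)
    sample = ScanSet(scan_set.scans[half:], scan_set.acquisition_time_per_scan)

    times, rms = [], []
    for m in range(1, half + 1):
        diff = average_scans(sample, m).values - average_scans(background, m).values
        r = diff[mask]
        r = r - r.mean()
        rms.append(float(np.sqrt(np.mean(r**2))))
        times.append(m * scan_set.acquisition_time_per_scan / 60.0)
    return NoiseCurve(times=np.array(times), rms=np.array(rms),
                      region=(lo, hi), n_pairs=half)
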