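"""Calibration / limit-of-detection analysis and amide I' VCD band shapes.

The VCD (or absorbance) response of a dilution series is linear in
concentration; an ordinary least-squares line through (concentration,
response) gives the sensitivity, and the limit of detection at SNR = 3 is
LOD = 3 * noise_sd / |slope|.

Band-shape classification encodes the standard amide I' VCD signatures:
a dominant couplet (adjacent +/- pair from exciton coupling) indicates
alpha-helix; a strong negative band below ~1630 cm^-1 under a +/- pair
(-, +, - from high to low wavenumber) indicates beta-sheet; a double
negative ("w" shape) indicates mixed secondary structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import linregress

from .spectra import Spectrum

__all__ = [
    "CalibrationResult",
    "BandFeature",
    "SignatureClass",
    "SignatureRules",
    "fit_calibration",
    "peak_response",
    "find_vcd_bands",
    "classify_signature",
]

AMIDE_I_WINDOW = (1580.0, 1710.0)
#: Default response window for VCD calibration curves.
VCD_RESPONSE_WINDOW = (1610.0, 1675.0)


@dataclass(frozen=True)
class CalibrationResult:
    """Linear calibration with a 3-sigma limit of detection."""

    slope: float  # dAU per (mg/mL)
    intercept: float  # dAU
    r_squared: float
    noise_sd: float  # dAU
    lod: float  # mg/mL

    def __post_init__(self) -> None:
        if not (0 <= self.r_squared <= 1 + 1e-12):
            raise ValueError("r_squared must be in [0, 1]")


@dataclass(frozen=True)
class BandFeature:
    """A signed local extremum of a smoothed spectrum."""

    position: float  # cm^-1
    amplitude: float  # signed dAU
    prominence: float  # dAU
    width: float  # cm^-1

    @property
    def sign(self) -> int:
        return 1 if self.amplitude > 0 else -1


@dataclass(frozen=True)
class SignatureClass:
    """Secondary-structure call with the rules that produced it."""

    label: str  # alpha_helix | beta_sheet | mixed | indeterminate
    evidence: tuple[str, ...] = ()


@dataclass(frozen=True)
class SignatureRules:
    """Tunable thresholds of the signature rule table.

    Fixed once against the three reference protein band patterns; every
    threshold is in physically meaningful units (cm^-1 or amplitude ratios),
    and classification is invariant to an overall amplitude rescale.
    """

    couplet_max_separation: float = 25.0  # cm^-1
    couplet_ratio_bounds: tuple[float, float] = (1.0 / 3.0, 3.0)
    beta_sheet_cutoff: float = 1630.0  # cm^-1
    sideband_fraction: float = 0.5  # of couplet magnitude
    mixed_min_separation: float = 15.0  # cm^-1
    mixed_positive_fraction: float = 0.5


def fit_calibration(concentrations, responses, noise_sd: float) -> CalibrationResult:
    """OLS calibration line and 3-sigma LOD.

    ``noise_sd`` is the measured spectral noise (same units as the responses)
    at the acquisition time of the series.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if c.size < 3 or c.size != y.size:
        raise ValueError("need at least 3 (concentration, response) points")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    fit = linregress(c, y)
    if fit.slope == 0:
        raise ValueError("zero calibration slope; LOD undefined")
    return CalibrationResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        noise_sd=float(noise_sd),
        lod=3.0 * noise_sd / abs(fit.slope),
    )


def peak_response(spectrum: Spectrum, window: tuple[float, float] = VCD_RESPONSE_WINDOW) -> float:
    """Signed extremum of largest magnitude within a wavenumber window."""
    sub = spectrum.restrict(*window)
    idx = int(np.nanargmax(np.abs(sub.values)))
    return float(sub.values[idx])


def _peaks_one_sign(axis, values, min_prominence):
    # prominence=0 still makes find_peaks report prominences for every peak
    peaks, props = find_peaks(values, prominence=float(max(min_prominence, 0.0)))
    out = []
    for i, p in enumerate(peaks):
        if values[p] <= 0:
            continue  # an undulation below zero is not a band of this sign
        left = props["left_bases"][i]
        right = props["right_bases"][i]
        out.append(
            BandFeature(
                position=float(axis[p]),
                amplitude=float(values[p]),
                prominence=float(props["prominences"][i]),
                width=float(axis[right] - axis[left]),
            )
        )
    return out


def find_vcd_bands(
    spectrum: Spectrum,
    region: tuple[float, float] = AMIDE_I_WINDOW,
    min_prominence: float = 0.0,
) -> list[BandFeature]:
    """Signed band features: positive maxima and negative minima.

    Intended for spectra smoothed to >= 4 cm^-1 resolution.  Features are
    returned sorted by |amplitude| descending.  A local maximum that never
    rises above zero (or a minimum that never dips below) is not a band.
    """
    sub = spectrum.restrict(*region)
    pos = _peaks_one_sign(sub.axis, sub.values, min_prominence)
    neg = [
        BandFeature(f.position, -f.amplitude, f.prominence, f.width)
        for f in _peaks_one_sign(sub.axis, -sub.values, min_prominence)
    ]
    return sorted(pos + neg, key=lambda f: abs(f.amplitude), reverse=True)


def _couplets(features: list[BandFeature], rules: SignatureRules):
    """All opposite-sign pairs within the couplet separation and ratio bounds."""
    lo, hi = rules.couplet_ratio_bounds
    out = []
    for i, a in enumerate(features):
        for b in features[i + 1:]:
            if a.sign == b.sign:
                continue
            if abs(a.position - b.position) > rules.couplet_max_separation:
                continue
            ratio = abs(a.amplitude) / abs(b.amplitude)
            if lo <= ratio <= hi:
                out.append((a, b))
    return out


def dominant_couplet(
    features: list[BandFeature], rules: SignatureRules | None = None
) -> tuple[BandFeature, BandFeature] | None:
    """The couplet containing the strongest feature, lobes sorted by position.

    Returns None when no couplet (opposite-sign adjacent pair) involves the
    strongest feature.
    """
    rules = rules or SignatureRules()
    if not features:
        return None
    feats = sorted(features, key=lambda f: abs(f.amplitude), reverse=True)
    strongest = feats[0]
    for pair in _couplets(feats, rules):
        if strongest in pair:
            lo, hi = sorted(pair, key=lambda f: f.position)
            return lo, hi
    return None


def classify_signature(
    features: list[BandFeature],
    rules: SignatureRules | None = None,
) -> SignatureClass:
    """Map amide I' VCD band features to a secondary-structure signature.

    Rule table (checked in order):
      (a) couplet: two opposite-sign features within 25 cm^-1, magnitude
          ratio within [1/3, 3];
      (b) alpha_helix: a couplet exists, the strongest feature belongs to
          one, and no negative feature at/below 1630 cm^-1 reaches half the
          couplet magnitude;
      (c) beta_sheet: strongest feature is negative at <= 1630 cm^-1, with a
          positive feature above it and a further negative above that
          (-, +, - running from high to low wavenumber);
      (d) mixed: two negative features >= 15 cm^-1 apart with no positive
          feature of half their magnitude between them;
      (e) otherwise indeterminate.
    """
    rules = rules or SignatureRules()
    if not features:
        return SignatureClass("indeterminate", ("no features",))
    feats = sorted(features, key=lambda f: abs(f.amplitude), reverse=True)
    strongest = feats[0]
    evidence: list[str] = []

    couplets = _couplets(feats, rules)
    if couplets:
        evidence.append(
            "couplet: " + "; ".join(
                f"({a.position:.0f}{'+' if a.sign > 0 else '-'}, "
                f"{b.position:.0f}{'+' if b.sign > 0 else '-'})"
                for a, b in couplets
            )
        )

    # (b) alpha helix: dominant couplet, no strong low-wavenumber negative.
    strongest_couplets = [c for c in couplets if strongest in c]
    if strongest_couplets:
        pair = strongest_couplets[0]
        magnitude = max(abs(pair[0].amplitude), abs(pair[1].amplitude))
        low_neg = [
            f for f in feats
            if f.sign < 0
            and f.position <= rules.beta_sheet_cutoff
            and abs(f.amplitude) > rules.sideband_fraction * magnitude
        ]
        if not low_neg:
            evidence.append("dominant couplet with no strong negative "
                            f"band below {rules.beta_sheet_cutoff:.0f}")
            return SignatureClass("alpha_helix", tuple(evidence))

    # (c) beta sheet: strong low negative under a -,+ pair above it.
    if strongest.sign < 0 and strongest.position <= rules.beta_sheet_cutoff:
        above_pos = [f for f in feats if f.sign > 0 and f.position > strongest.position]
        if above_pos:
            top_pos = max(above_pos, key=lambda f: abs(f.amplitude))
            above_neg = [f for f in feats if f.sign < 0 and f.position > top_pos.position]
            if above_neg:
                evidence.append(
                    f"-,+,- pattern from high to low wavenumber ending at "
                    f"{strongest.position:.0f}"
                )
                return SignatureClass("beta_sheet", tuple(evidence))

    # (d) mixed: well-separated double negative ("w" shape).
    negs = [f for f in feats if f.sign < 0]
    for i, a in enumerate(negs):
        for b in negs[i + 1:]:
            lo_f, hi_f = sorted((a, b), key=lambda f: f.position)
            if hi_f.position - lo_f.position < rules.mixed_min_separation:
                continue
            magnitude = min(abs(a.amplitude), abs(b.amplitude))
            blocking = [
                f for f in feats
                if f.sign > 0
                and lo_f.position < f.position < hi_f.position
                and abs(f.amplitude) > rules.mixed_positive_fraction * magnitude
            ]
            if not blocking:
                evidence.append(
                    f"double negative at {lo_f.position:.0f} and {hi_f.position:.0f}"
                )
                return SignatureClass("mixed", tuple(evidence))

    evidence.append("no rule matched")
    return SignatureClass("indeterminate", tuple(evidence))
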