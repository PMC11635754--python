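"""Ground-truth sample models: protein amide I' bands in D2O.

A sample is a set of Gaussian bands.  Each band contributes a Beer-Lambert
absorbance A(v) = c * eps * L * g(v) (g is a unit-peak Gaussian) and a
circular-dichroism term dA(v) = anisotropy * A(v), where the anisotropy is
the signed ratio dA/A at the band center.  Protein VCD signals are roughly
1e-4 of the parent absorbance band, so fixture anisotropies are normalized
to give max|dA| / max(A_protein) = 1e-4 over the amide I' window.

The three bundled fixtures encode the published amide I' signatures of
bovine serum albumin (alpha-helical: a strong couplet at 1662/1648 cm^-1
with a deuteration sideband at 1628 cm^-1), hen egg-white lysozyme (mixed
structure: two negative peaks at 1660 and 1635 cm^-1, a "w" shape) and
beta-lactoglobulin (beta-sheet: small negative 1660, positive 1638, strong
negative 1621 cm^-1).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .instrument import InstrumentConfig
from .spectra import Spectrum

__all__ = [
    "BandSpec",
    "SampleModel",
    "protein_fixture",
    "solvent_only",
    "true_spectra",
    "PROTEIN_FIXTURES",
]

DEFAULT_ANISOTROPY_MAGNITUDE = 1e-4

#: mg/mL absorptivity of the amide I' band chosen so that 14 mg/mL in a
#: 204 um cell peaks at ~0.78 AU (the top of the published dilution series).
_AMIDE_EPS = 0.78 / (14.0 * 0.204)  # AU per (mg/mL) per mm

#: VCD carrier bands get a small absorptivity (3% of the main band) so the
#: VCD band shape can differ from the absorbance shape without distorting it.
_CARRIER_EPS = 0.03 * _AMIDE_EPS


def gaussian(wavenumber, center: float, fwhm: float):
    """Unit-peak Gaussian line shape."""
    x = (np.asarray(wavenumber, dtype=float) - center) / fwhm
    return np.exp(-4.0 * np.log(2.0) * x * x)


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian band: position, width, strength and chirality.

    ``absorptivity`` is in AU per (mg/mL) per mm for protein bands; solvent
    bands re-use the field as AU per mm (concentration-independent).
    ``anisotropy`` is the signed dA/A ratio at band center.
    """

    center: float  # cm^-1
    fwhm: float  # cm^-1
    absorptivity: float
    anisotropy: float = 0.0

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if abs(self.anisotropy) >= 1e-2:
            raise ValueError("|anisotropy| must be < 1e-2")


@dataclass(frozen=True)
class SampleModel:
    """A named analyte (bands scaling with concentration) plus solvent."""

    name: str
    concentration: float  # mg/mL
    bands: tuple[BandSpec, ...] = ()
    solvent_bands: tuple[BandSpec, ...] = ()
    validity_window: tuple[float, float] = (1400.0, 1710.0)

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")
        lo, hi = self.validity_window
        for b in self.bands:
            if not (lo <= b.center <= hi):
                raise ValueError(f"band at {b.center} outside validity window")
        for b in self.solvent_bands:
            if b.anisotropy != 0.0:
                raise ValueError("solvent bands must be achiral (anisotropy 0)")

    def with_concentration(self, concentration: float) -> "SampleModel":
        return replace(self, concentration=concentration)

    def absorbance(self, wavenumber, path_length_mm: float) -> np.ndarray:
        """Total decadic absorbance A(v), protein + solvent."""
        wn = np.asarray(wavenumber, dtype=float)
        a = np.zeros_like(wn)
        for b in self.bands:
            a += self.concentration * b.absorptivity * path_length_mm * gaussian(
                wn, b.center, b.fwhm
            )
        for b in self.solvent_bands:
            a += b.absorptivity * path_length_mm * gaussian(wn, b.center, b.fwhm)
        return a

    def protein_absorbance(self, wavenumber, path_length_mm: float) -> np.ndarray:
        wn = np.asarray(wavenumber, dtype=float)
        a = np.zeros_like(wn)
        for b in self.bands:
            a += self.concentration * b.absorptivity * path_length_mm * gaussian(
                wn, b.center, b.fwhm
            )
        return a

    def solvent_absorbance(self, wavenumber, path_length_mm: float) -> np.ndarray:
        """Solvent-only absorbance (what the matched reference cell sees)."""
        wn = np.asarray(wavenumber, dtype=float)
        a = np.zeros_like(wn)
        for b in self.solvent_bands:
            a += b.absorptivity * path_length_mm * gaussian(wn, b.center, b.fwhm)
        return a

    def vcd(self, wavenumber, path_length_mm: float) -> np.ndarray:
        """Ground-truth dA(v) = sum of anisotropy-weighted band terms."""
        wn = np.asarray(wavenumber, dtype=float)
        da = np.zeros_like(wn)
        for b in self.bands:
            if b.anisotropy != 0.0:
                da += (
                    b.anisotropy
                    * self.concentration
                    * b.absorptivity
                    * path_length_mm
                    * gaussian(wn, b.center, b.fwhm)
                )
        return da


#: D2O background: the weak absorption feature near 1550 cm^-1 plus a broad
#: low-frequency tail (DOH bending region).  Absorptivities are AU per mm.
_D2O_BANDS = (
    BandSpec(center=1555.0, fwhm=120.0, absorptivity=0.25 / 0.204),
    BandSpec(center=1450.0, fwhm=160.0, absorptivity=0.20 / 0.204),
)

# Fixture tables: (absorbance bands) and (VCD extremum, relative signed
# amplitude) lists.  VCD carriers are narrow (12 cm^-1) as protein VCD bands
# are sharper than their parent absorbance bands.
_VCD_FWHM = 12.0

_FIXTURE_TABLES: dict[str, dict] = {
    "bsa": {
        "absorbance": [(1649.0, 34.0, 1.0)],
        "vcd": [(1662.0, -1.0), (1648.0, +1.0), (1628.0, -0.30)],
    },
    "lysozyme": {
        "absorbance": [(1649.0, 36.0, 1.0)],
        "vcd": [(1660.0, -1.0), (1635.0, -0.85)],
    },
    "beta_lactoglobulin": {
        "absorbance": [(1636.0, 30.0, 1.0), (1655.0, 18.0, 0.25)],
        "vcd": [(1660.0, -0.40), (1638.0, +0.65), (1621.0, -1.0)],
    },
}

PROTEIN_FIXTURES = tuple(_FIXTURE_TABLES)

_ALIASES = {
    "bsa": "bsa",
    "bovine_serum_albumin": "bsa",
    "lysozyme": "lysozyme",
    "beta_lactoglobulin": "beta_lactoglobulin",
    "blg": "beta_lactoglobulin",
    "b-lactoglobulin": "beta_lactoglobulin",
}


def _extrema_positions(axis: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Positions of all interior local extrema of y (sign-agnostic)."""
    d = np.diff(y)
    idx = np.where(np.sign(d[1:]) != np.sign(d[:-1]))[0] + 1
    return axis[idx]


def _refine_centers(
    bands: list[BandSpec],
    adjustable: list[int],
    targets: list[float],
    value_fn,
    n_iter: int = 4,
) -> list[BandSpec]:
    """Nudge band centers so the summed spectrum's extrema land on targets.

    Overlapping Gaussians pull each other's extrema; a few fixed-point
    iterations (shift each adjustable center by the residual of its nearest
    extremum) remove the bias to well below 0.01 cm^-1.
    """
    axis = np.arange(1560.0, 1730.0, 0.01)
    for _ in range(n_iter):
        y = value_fn(bands, axis)
        found = _extrema_positions(axis, y)
        if found.size == 0:
            break
        new = list(bands)
        for i, target in zip(adjustable, targets):
            nearest = found[np.argmin(np.abs(found - target))]
            new[i] = replace(new[i], center=new[i].center + (target - nearest))
        bands = new
    return bands


def protein_fixture(
    name: str,
    concentration: float = 10.0,
    anisotropy_magnitude: float = DEFAULT_ANISOTROPY_MAGNITUDE,
    couplet_positive_low: bool = True,
) -> SampleModel:
    """Build one of the bundled protein samples in D2O.

    Parameters
    ----------
    name : ``"bsa"``, ``"lysozyme"`` or ``"beta_lactoglobulin"`` (aliases
        accepted, case-insensitive).
    concentration : analyte concentration in mg/mL.
    anisotropy_magnitude : peak |dA|/peak(A) of the fixture (default 1e-4,
        the typical protein VCD-to-absorbance ratio).
    couplet_positive_low : sign order of the BSA couplet; by default the
        lower-wavenumber lobe (1648 cm^-1) is positive (positive-couplet
        convention).  Ignored for the other fixtures.
    """
    key = _ALIASES.get(name.strip().lower().replace(" ", "_").replace("-", "_"))
    if key is None:
        raise ValueError(
            f"unknown protein fixture {name!r}; valid fixtures: "
            + ", ".join(sorted(PROTEIN_FIXTURES))
        )
    table = _FIXTURE_TABLES[key]

    abs_bands = [
        BandSpec(center=c, fwhm=w, absorptivity=rel * _AMIDE_EPS)
        for c, w, rel in table["absorbance"]
    ]
    sign_flip = -1.0 if (key == "bsa" and not couplet_positive_low) else 1.0
    vcd_bands = [
        BandSpec(
            center=c,
            fwhm=_VCD_FWHM,
            absorptivity=_CARRIER_EPS * abs(rel),
            anisotropy=sign_flip * np.sign(rel) * 3e-3,
        )
        for c, rel in table["vcd"]
    ]

    # Pin the ground-truth absorbance maximum: only the main band is moved
    # (the shoulder stays put, it is a target of its own description).
    def abs_sum(bands, axis):
        out = np.zeros_like(axis)
        for b in bands:
            out += b.absorptivity * gaussian(axis, b.center, b.fwhm)
        return out

    main_target = table["absorbance"][0][0]
    abs_bands = _refine_centers(abs_bands, [0], [main_target], abs_sum)

    # Pin the VCD extrema: amplitude-weighted overlapping lobes shift each
    # other, so refine every carrier center against its printed position.
    rel_amps = [rel for _, rel in table["vcd"]]

    def vcd_sum(bands, axis):
        out = np.zeros_like(axis)
        for b, rel in zip(bands, rel_amps):
            out += rel * gaussian(axis, b.center, b.fwhm)
        return out

    targets = [c for c, _ in table["vcd"]]
    vcd_bands = _refine_centers(vcd_bands, list(range(len(vcd_bands))), targets, vcd_sum)

    sample = SampleModel(
        name=key,
        concentration=concentration,
        bands=tuple(abs_bands + vcd_bands),
        solvent_bands=_D2O_BANDS,
    )
    if concentration <= 0:
        return sample

    # Normalize the fixture chirality: max|dA| / max(A_protein) over the
    # validity window equals anisotropy_magnitude (concentration-invariant).
    axis = np.arange(sample.validity_window[0], sample.validity_window[1], 0.02)
    ratio = np.max(np.abs(sample.vcd(axis, 0.204))) / np.max(
        sample.protein_absorbance(axis, 0.204)
    )
    scale = anisotropy_magnitude / ratio
    scaled = [
        replace(b, anisotropy=b.anisotropy * scale) if b.anisotropy != 0 else b
        for b in sample.bands
    ]
    return replace(sample, bands=tuple(scaled))


def solvent_only(name: str = "d2o") -> SampleModel:
    """A blank: D2O background only (used for background scans)."""
    return SampleModel(name=name, concentration=0.0, solvent_bands=_D2O_BANDS)


def true_spectra(
    sample: SampleModel, config: InstrumentConfig, axis: np.ndarray
) -> tuple[Spectrum, Spectrum]:
    """Ground-truth (absorbance, vcd) spectra on a wavenumber axis.

    Both are exactly linear in concentration and path length (Beer-Lambert).
    """
    axis = np.asarray(axis, dtype=float)
    if axis.size == 0:
        raise ValueError("axis is empty")
    if axis.min() < config.laser.sweep_start - 1e-9 or axis.max() > config.laser.sweep_stop + 1e-9:
        raise ValueError("axis extends beyond the configured sweep range")
    path = config.path_length_mm
    res = float(np.median(np.diff(axis))) if axis.size > 1 else 0.0
    meta = {"sample": sample.name, "concentration": sample.concentration}
    a = Spectrum(axis, sample.absorbance(axis, path), kind="absorbance",
                 resolution=res, meta=dict(meta))
    v = Spectrum(axis, sample.vcd(axis, path), kind="vcd",
                 resolution=res, meta=dict(meta))
    return a, v
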