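"""Wavenumber-indexed spectrum container shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Spectrum", "SpectrumKind"]

#: Allowed spectrum kinds and their units: raw detector intensity,
#: decadic absorbance (AU), and circular-dichroism absorbance difference (dAU).
SpectrumKind = ("intensity", "absorbance", "vcd")


@dataclass
class Spectrum:
    """A spectrum on a strictly increasing wavenumber axis.

    Attributes
    ----------
    axis : array of wavenumbers in cm^-1, strictly increasing.
    values : array of the same length; units depend on ``kind``.
    kind : one of ``"intensity"``, ``"absorbance"``, ``"vcd"``.
    resolution : effective spectral resolution in cm^-1 (native grid spacing
        until smoothing widens it).
    meta : free-form provenance (n_scans averaged, config hash, stage log...).
    """

    axis: np.ndarray
    values: np.ndarray
    kind: str = "intensity"
    resolution: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.axis.ndim != 1 or self.axis.shape != self.values.shape:
            raise ValueError("axis and values must be 1-D and equally long")
        if self.axis.size >= 2 and not np.all(np.diff(self.axis) > 0):
            raise ValueError("axis must be strictly increasing")
        if self.kind not in SpectrumKind:
            raise ValueError(f"kind must be one of {SpectrumKind}")

    def __len__(self) -> int:
        return self.axis.size

    def copy_with(self, **changes) -> "Spectrum":
        out = replace(self, **changes)
        out.meta = dict(self.meta, **changes.get("meta", {}))
        return out

    def restrict(self, lo: float, hi: float) -> "Spectrum":
        """Slice to the closed wavenumber interval [lo, hi]."""
        mask = (self.axis >= lo) & (self.axis <= hi)
        if not mask.any():
            raise ValueError(f"interval [{lo}, {hi}] outside spectrum axis")
        return self.copy_with(axis=self.axis[mask], values=self.values[mask])

    def interp_to(self, axis: np.ndarray) -> "Spectrum":
        """Linear re-interpolation onto a new axis (within the current span)."""
        axis = np.asarray(axis, dtype=float)
        if axis.min() < self.axis.min() - 1e-9 or axis.max() > self.axis.max() + 1e-9:
            raise ValueError("target axis extends beyond spectrum span")
        return self.copy_with(axis=axis, values=np.interp(axis, self.axis, self.values))


def same_axis(*spectra: Spectrum, atol: float = 1e-9) -> bool:
    axes = [s.axis for s in spectra]
    return all(a.shape == axes[0].shape and np.allclose(a, axes[0], atol=atol) for a in axes)
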