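"""Readers and writers: CSV and JCAMP-DX spectra, raw pulse tables, configs.

JCAMP-DX support is a minimal uncompressed-AFFN implementation (XYDATA in
(X++(Y..Y)) form and XYPOINTS in (XY..XY) form) — enough to round-trip this
package's spectra and to ingest plainly exported instrument files.
Compressed forms (SQZ/DIF/DUP) are not supported.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .instrument import InstrumentConfig
from .simulate import NoiseModel, RawScan
from .spectra import Spectrum

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_raw_scan",
    "write_raw_scan",
    "RunConfig",
    "config_hash",
]

_KIND_TO_YUNITS = {"absorbance": "ABSORBANCE", "vcd": "DELTA ABSORBANCE",
                   "intensity": "ARBITRARY UNITS"}
_YUNITS_TO_KIND = {v: k for k, v in _KIND_TO_YUNITS.items()}


class SpectrumFormatError(ValueError):
    """Raised for malformed spectrum files, naming the offending record."""


def _ensure_increasing(axis: np.ndarray, values: np.ndarray):
    order = np.argsort(axis)
    axis, values = axis[order], values[order]
    if np.any(np.diff(axis) <= 0):
        raise SpectrumFormatError("axis contains duplicated wavenumber values")
    return axis, values


# ---------------------------------------------------------------- CSV

def _read_csv(path: Path) -> Spectrum:
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    if len(cols) < 2 or cols[0] != "wavenumber" or cols[1] != "value":
        raise SpectrumFormatError(
            f"{path}: expected header 'wavenumber,value', got {list(df.columns)!r}"
        )
    axis, values = _ensure_increasing(
        df.iloc[:, 0].to_numpy(dtype=float), df.iloc[:, 1].to_numpy(dtype=float)
    )
    return Spectrum(axis=axis, values=values, meta={"source": str(path)})


def _write_csv(spectrum: Spectrum, path: Path) -> None:
    pd.DataFrame({"wavenumber": spectrum.axis, "value": spectrum.values}).to_csv(
        path, index=False, float_format="%.17g"
    )


# ---------------------------------------------------------------- JCAMP-DX

def _write_jcamp(spectrum: Spectrum, path: Path, title: str = "qclvcd spectrum") -> None:
    a, v = spectrum.axis, spectrum.values
    lines = [
        f"##TITLE={title}",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=INFRARED SPECTRUM",
        "##XUNITS=1/CM",
        f"##YUNITS={_KIND_TO_YUNITS.get(spectrum.kind, 'ARBITRARY UNITS')}",
        f"##RESOLUTION={spectrum.resolution:.17g}",
        "##XFACTOR=1.0",
        "##YFACTOR=1.0",
        f"##FIRSTX={a[0]:.17g}",
        f"##LASTX={a[-1]:.17g}",
        f"##NPOINTS={a.size}",
        f"##FIRSTY={v[0]:.17g}",
        "##XYPOINTS=(XY..XY)",
    ]
    lines += [f"{x:.17g}, {y:.17g}" for x, y in zip(a, v)]
    lines.append("##END=")
    path.write_text("\n".join(lines) + "\n")


def _parse_affn_row(line: str, lineno: int, path: Path) -> list[float]:
    try:
        return [float(tok) for tok in line.replace(",", " ").split()]
    except ValueError as exc:
        raise SpectrumFormatError(f"{path}:{lineno}: unparseable AFFN data: {line!r}") from exc


def _read_jcamp(path: Path) -> Spectrum:
    ldrs: dict[str, str] = {}
    mode = None  # "xydata" | "xypoints"
    block_mode = None  # mode of the (single supported) data block
    xy_rows: list[tuple[int, str]] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("$$")[0].strip()
        if not line:
            continue
        if line.startswith("##"):
            if "=" not in line:
                raise SpectrumFormatError(f"{path}:{lineno}: malformed label {line!r}")
            key, _, val = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            val = val.strip()
            if key == "XYDATA":
                if "X++" not in val.replace(" ", ""):
                    raise SpectrumFormatError(
                        f"{path}:{lineno}: unsupported XYDATA form {val!r}")
                mode = block_mode = "xydata"
            elif key == "XYPOINTS":
                mode = block_mode = "xypoints"
            elif key == "END":
                mode = None
            else:
                ldrs[key] = val
                mode = None
        elif mode is not None:
            xy_rows.append((lineno, line))
        # other free text outside data blocks is ignored
    if not xy_rows:
        raise SpectrumFormatError(f"{path}: no XYDATA/XYPOINTS records found")

    xfactor = float(ldrs.get("XFACTOR", 1.0))
    yfactor = float(ldrs.get("YFACTOR", 1.0))
    xs: list[float] = []
    ys: list[float] = []
    for lineno, line in xy_rows:
        nums = _parse_affn_row(line, lineno, path)
        if block_mode == "xypoints":
            if len(nums) % 2 != 0:
                raise SpectrumFormatError(
                    f"{path}:{lineno}: odd number of values in XY pair record")
            xs.extend(nums[0::2])
            ys.extend(nums[1::2])
        else:  # (X++(Y..Y)): first number is X of the first Y in the row
            if len(nums) < 2:
                raise SpectrumFormatError(
                    f"{path}:{lineno}: XYDATA row needs an X and at least one Y")
            x0 = nums[0]
            yrow = nums[1:]
            # per-row X spacing from FIRSTX/LASTX/NPOINTS
            try:
                first = float(ldrs["FIRSTX"])
                last = float(ldrs["LASTX"])
                npts = int(float(ldrs["NPOINTS"]))
            except KeyError as exc:
                raise SpectrumFormatError(
                    f"{path}: XYDATA requires FIRSTX/LASTX/NPOINTS") from exc
            dx = (last - first) / (npts - 1) if npts > 1 else 0.0
            xs.extend(x0 + dx * np.arange(len(yrow)))
            ys.extend(yrow)

    axis = np.asarray(xs, dtype=float) * xfactor
    values = np.asarray(ys, dtype=float) * yfactor
    if "NPOINTS" in ldrs and int(float(ldrs["NPOINTS"])) != axis.size:
        raise SpectrumFormatError(
            f"{path}: NPOINTS={ldrs['NPOINTS']} but {axis.size} points parsed")
    axis, values = _ensure_increasing(axis, values)
    kind = _YUNITS_TO_KIND.get(ldrs.get("YUNITS", ""), "intensity")
    return Spectrum(axis=axis, values=values, kind=kind,
                    resolution=float(ldrs.get("RESOLUTION", 0.0)),
                    meta={"source": str(path), "title": ldrs.get("TITLE", "")})


# ---------------------------------------------------------------- dispatch

def read_spectrum(path, format: str | None = None, kind: str | None = None) -> Spectrum:
    """Read a spectrum from CSV (wavenumber,value header) or JCAMP-DX.

    The format is inferred from the extension unless given.  The axis is
    re-sorted to ascending order; duplicated axis values are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "jcamp" if path.suffix.lower() in (".jdx", ".dx", ".jcm") else "csv"
    spec = _read_jcamp(path) if format == "jcamp" else _read_csv(path)
    if kind is not None:
        spec.kind = kind
    return spec


def write_spectrum(spectrum: Spectrum, path, format: str | None = None) -> Path:
    """Write a spectrum as CSV or JCAMP-DX (inferred from extension)."""
    path = Path(path)
    if format is None:
        format = "jcamp" if path.suffix.lower() in (".jdx", ".dx", ".jcm") else "csv"
    if format == "jcamp":
        _write_jcamp(spectrum, path)
    else:
        _write_csv(spectrum, path)
    return path


# ---------------------------------------------------------------- raw scans

def write_raw_scan(scan: RawScan, path, sidecar: bool = True) -> Path:
    """Persist a raw scan as a one-row-per-pulse CSV plus a JSON sidecar."""
    path = Path(path)
    pd.DataFrame({
        "pulse_time": scan.pulse_times,
        "sample": scan.sample_amplitudes,
        "reference": scan.reference_amplitudes,
        "balanced": scan.balanced_amplitudes,
    }).to_csv(path, index=False, float_format="%.17g")
    if sidecar:
        meta = {
            "sweep_start": scan.sweep_start,
            "sweep_stop": scan.sweep_stop,
            "sweep_speed": scan.sweep_speed,
            "sweep_direction": scan.sweep_direction,
            "pulse_rate": scan.pulse_rate,
            "balance_gain": scan.balance_gain,
            "seed": scan.seed,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))
    return path


def read_raw_scan(path) -> RawScan:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return RawScan(
        pulse_times=df["pulse_time"].to_numpy(),
        sample_amplitudes=df["sample"].to_numpy(),
        reference_amplitudes=df["reference"].to_numpy(),
        balanced_amplitudes=df["balanced"].to_numpy(),
        **meta,
    )


# ---------------------------------------------------------------- run config

@dataclass
class RunConfig:
    """Serializable bundle of everything a pipeline run depends on."""

    instrument: InstrumentConfig = field(default_factory=InstrumentConfig)
    noise: NoiseModel = field(default_factory=NoiseModel)
    sample: str = "bsa"
    concentration: float = 10.0
    n_scans: int = 1
    sweeps_per_scan: int = 1
    target_resolution: float = 8.0
    anchor_regions: list | None = None
    classify_region: tuple[float, float] = (1595.0, 1700.0)
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["instrument"] = self.instrument.to_dict()
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)

    @staticmethod
    def from_dict(d: dict) -> "RunConfig":
        d = dict(d)
        d["instrument"] = InstrumentConfig.from_dict(d["instrument"])
        d["noise"] = NoiseModel(**d["noise"])
        d["classify_region"] = tuple(d["classify_region"])
        if d.get("anchor_regions"):
            d["anchor_regions"] = [tuple(r) for r in d["anchor_regions"]]
        return RunConfig(**d)

    @staticmethod
    def from_json(text: str) -> "RunConfig":
        return RunConfig.from_dict(json.loads(text))


def config_hash(config: RunConfig) -> str:
    return hashlib.sha256(config.to_json().encode()).hexdigest()[:16]
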