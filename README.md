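# qclvcd

Simulation and analysis of **vibrational circular dichroism (VCD)
spectroscopy with a swept external-cavity quantum cascade laser (EC-QCL)**,
for protein secondary-structure analysis in D₂O.

VCD measures the difference in absorbance of left- versus right-circularly
polarized infrared light, ΔA = A_L − A_R. For proteins the amide I′ band
(1700–1600 cm⁻¹ in deuterated solvent) carries a sign pattern that encodes
secondary structure — a positive couplet for α-helix, a strong negative band
near 1620 cm⁻¹ under a ± pair for β-sheet, a double-negative "w" shape for
mixed folds — but the signal is only ~10⁻⁴ of the parent absorbance. A
high-brilliance pulsed QCL phase-locked to a 50 kHz photoelastic modulator
(PEM), with balanced detection against a matched reference arm, makes this
measurable at a 204 μm path length and protein concentrations of a few
mg/mL.

This package provides, as tested library code:

- **`qclvcd.instrument` / `qclvcd.samples` / `qclvcd.simulate`** — a
  pulse-level synthetic-data generator: laser sweep (40 cm⁻¹/s, 400 kHz
  pulses of 700 ns), PEM retardation δ₀(ν̃) = (π/2)·ν̃/1555 cm⁻¹, protein
  band models for BSA, lysozyme and β-lactoglobulin, and a noise model
  (pulse jitter with common-mode correlation, 1/f drift, detector white
  noise, polarizer fringes).
- **`qclvcd.lockin`** — a digital lock-in (multiply / single-pole low-pass /
  block-average decimate) and the VCD reconstruction

  ΔA(ν̃) = g · S_1f(ν̃) / [ J₁(δ₀(ν̃)) · (S_8f(ν̃) + S_offset(ν̃)) ]

  where S_1f and S_8f are the balanced-detector signals demodulated at the
  PEM fundamental and its eighth harmonic, S_offset is the reference-detector
  record that restores the sample-arm DC level, J₁ is the first-order Bessel
  function, and g is a single gain constant fixed by a noiseless round-trip
  calibration at δ₀ = π/2.
- **`qclvcd.pipeline`** — per-scan baseline correction over band-free
  anchors, scan averaging, least-squares cubic-spline smoothing from the
  native 0.5 cm⁻¹ to the conventional 8 cm⁻¹ resolution, background
  subtraction.
- **`qclvcd.noise_metrics`** — split-half RMS noise versus measurement time.
- **`qclvcd.bands`** — linear calibration with LOD = 3·σ_noise/|slope|,
  band-feature extraction, and a configurable rule table mapping amide I′
  VCD band patterns to {alpha_helix, beta_sheet, mixed, indeterminate}.
- **`qclvcd.io` / `qclvcd.cli`** — CSV and JCAMP-DX spectra, raw pulse
  tables, JSON results, and a `qclvcd` command-line driver
  (`simulate`, `demod`, `process`, `noise`, `calibrate`, `classify`).

## Worked example

Simulate a 1-hour measurement (12 scans × 5 min) of 10 mg/mL
β-lactoglobulin in D₂O at the fast-test instrument scale, reduce it, and
classify the band shape:

```python
import numpy as np
import qclvcd as q
from qclvcd.simulate import NoiseModel
from qclvcd.workflow import classify_spectrum

config = q.scaled_test_config()          # narrowband amide I' sweep
sample = q.protein_fixture("beta_lactoglobulin", concentration=10.0)
result = q.protein_measurement(sample, config, NoiseModel(),
                               n_scans=12, sweeps_per_scan=92, seed=1)
report = classify_spectrum(result["vcd"])

ab = result["absorbance"].restrict(1600, 1690)
print(f"amide I' absorbance max: {ab.values.max():.3f} AU "
      f"at {ab.axis[np.argmax(ab.values)]:.1f} cm-1")
for f in report["features"]:
    print(f"  VCD band at {f.position:7.1f} cm-1   dA = {f.amplitude:+.2e}")
print("signature:", report["signature"].label)
```

prints

```
amide I' absorbance max: 0.573 AU at 1636.6 cm-1
  VCD band at  1621.3 cm-1   dA = -5.77e-05
  VCD band at  1637.6 cm-1   dA = +3.86e-05
  VCD band at  1660.5 cm-1   dA = -2.19e-05
signature: beta_sheet
```

The absorbance maximum sits at the β-sheet-dominated amide I′ position
(~1636 cm⁻¹), the VCD shows the characteristic small-negative / positive /
strong-negative triplet (1660 / 1638 / 1621 cm⁻¹) at ~10⁻⁴ of the
absorbance, and the rule table reads the −,+,− pattern as β-sheet content.

The same flow from a shell:

```sh
qclvcd simulate --sample bsa --conc 10 --mode narrowband --scans 2 --seed 3 --out run/
qclvcd demod   --run run/
qclvcd process --run run/ --resolution 8
qclvcd classify --run run/     # -> signature: alpha_helix
```

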