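# Methods

## Instrument model

The simulated instrument is a swept-wavelength mid-IR VCD spectrometer:

- A pulsed EC-QCL sweeps its emission wavenumber linearly in time,
  ν̃(t) = ν̃_start + r·t, at r = 40 cm⁻¹/s over either 1400–1710 cm⁻¹
  (broadband) or 1580–1710 cm⁻¹ (amide I′ only). Pulses arrive at 400 kHz
  with 700 ns width (28% duty cycle). The emission envelope is modelled as a
  flat-top (fourth-order) super-Gaussian on a constant floor; its exact
  shape is immaterial to the reconstructed spectra because both the VCD and
  the absorbance are intensity ratios in which the envelope cancels.
- A photoelastic modulator in the sample arm imposes the retardation
  δ(t) = δ₀(ν̃)·sin(2πf_PEM·t) at f_PEM = 50 kHz. At fixed mechanical drive
  the optical path difference is constant, so δ₀ scales linearly with
  wavenumber; the setpoint is π/2 at 1555 cm⁻¹.
- The pulse train is phase-locked to the PEM with exactly 8 pulses per
  modulation period and phase offset θ₀ = π/2, so two pulses of every eight
  sit on the retardation extrema — 25% of the laser intensity is spent at
  the maximum of the PEM cycle, and the multiset of sampled phases is
  identical in every period.
- Each pulse is represented by one energy sample (the lock-in integrates
  over the pulse, so sub-pulse structure carries no information). The
  sample-arm pulse energy is, to first order in ΔA (adequate at ΔA ~ 10⁻⁴):

      I_k = env(ν̃_k) · 10^(−A(ν̃_k)) · [1 + (ln10/2)·ΔA(ν̃_k)·sin(δ₀ sin θ_k)]

  times a common-mode noise factor, plus detector white noise and a static
  fringe term. The reference arm sees the envelope, the transmission of a
  solvent-filled reference cell at the same path length, and the same
  common-mode factor — the matched arms are what lets the balanced
  subtraction (sample − gain·reference) cancel correlated laser noise.

## Demodulation and VCD reconstruction

The digital lock-in multiplies the pulse stream by a unit reference
2·cos(2πft+φ), low-pass filters with a single-pole exponential (time
constant τ = 10 ms by default) and decimates to the output rate (838 Sa/s at
full scale, ≈20 samples per cm⁻¹). Amplitude convention: a pure cosine of
peak amplitude A at matched frequency and phase returns A.

Two channels are demodulated from the balanced stream: S_1f at the PEM
fundamental (the circular-dichroism channel) and S_8f at the eighth harmonic
= the pulse rate (the intensity channel; on a phase-locked pulse comb this
harmonic aliases to the pulse-energy mean). A reference-detector record
S_offset, taken once on a blank, restores the sample-arm DC level of the
balanced trace. The VCD spectrum is

    ΔA(ν̃) = g · S_1f(ν̃) / [ J₁(δ₀(ν̃)) · (S_8f(ν̃) + S_offset(ν̃)) ]

and the absorbance is A = −log₁₀(DC_sample/DC_background) from the restored
DC traces of sample and solvent runs.

**Gain calibration.** With 8 pulses per PEM period the demodulated
first-harmonic content of sin(δ₀ sin θ) is the discrete 8-point coefficient
H₁(δ₀) = (2/8)·Σ_k sin(δ₀ sin θ_k)·sin θ_k, not the continuous 2·J₁(δ₀);
the two differ at the 10⁻⁴ level near δ₀ = π/2 (folded harmonics above the
comb Nyquist). The scalar g therefore absorbs ln(10), the demodulation
convention and the H₁/2J₁ ratio; it is fixed once by a noiseless round-trip
calibration at δ₀ = π/2 (`lockin.calibrate_vcd_gain`), which agrees with the
closed form g = 4·J₁(π/2)/(ln10·H₁(π/2)) ≈ 0.8686. Because δ₀ varies by
only ~8% across the amide sweep and the H₁/2J₁ ratio is flat to ~10⁻⁴
there, a single constant suffices for the 0.5% round-trip accuracy the
pipeline is tested to.

## Numerical choices

- **Decimation by block averaging.** The single-pole filter leaves coherent
  ripple at the demodulation frequency; naive subsampling aliases it into
  the output as spurious spectral structure (~10⁻⁴ ΔAU). The decimator
  therefore averages each block of ~477 filtered samples, which is what the
  output sampler of a hardware lock-in does.
- **Settling and group delay.** The first 5τ of every demodulated trace are
  trimmed (filter transient), and the known group delay of the single-pole
  filter (= τ at DC) is subtracted in the time→wavenumber mapping so band
  positions are not dragged along the sweep (+0.4 cm⁻¹ otherwise).
- **Intensity floor.** Points where the restored DC intensity falls below
  10⁻⁶ of its maximum are masked as total absorption.
- **Spline smoothing.** "Resolution matching" from the native 0.5 cm⁻¹ to
  8 cm⁻¹ is a least-squares cubic spline with uniform knots spaced at the
  target resolution — a linear projection, so it commutes with averaging
  and is testable operator-by-operator.
- **Baseline.** Degree-1 polynomial fitted only over band-free anchor
  intervals (1405–1420 / 1695–1705 cm⁻¹ broadband, 1585–1595 / 1700–1710
  narrowband), applied per scan before averaging; the degree and anchors
  are configuration, not auto-detected, to keep the operator deterministic.
- **Band detection.** Signed local extrema with a prominence threshold of
  5× the measured noise RMS (estimated in the anchor regions), floored at
  8% of the strongest amplitude to reject smoothing ripple in nearly
  noiseless spectra. Bands are searched in 1595–1700 cm⁻¹, inset from the
  sweep edges where the spline has inflated variance. A local maximum that
  never rises above zero (the saddle between two negative lobes) is not a
  band.

## Protein fixtures

Samples are sums of Gaussian bands; each band contributes Beer–Lambert
absorbance A = c·ε·L·g(ν̃) and VCD ΔA = anisotropy·A, with the anisotropy
the signed ΔA/A at band center. Absorbance band positions: BSA and lysozyme
peak at 1649 cm⁻¹; β-lactoglobulin at 1636 cm⁻¹ with a weak shoulder near
1652 cm⁻¹. VCD patterns (12 cm⁻¹ FWHM carriers with small absorptivity so
the VCD shape can differ from the absorbance shape): BSA −1662/+1648 couplet
with a −1628 deuteration sideband; lysozyme −1660/−1635 double negative;
β-lactoglobulin −1660/+1638/−1621. Overlapping lobes pull each other's
extrema, so fixture construction runs a short fixed-point refinement that
pins the ground-truth extrema to these positions to <0.01 cm⁻¹. Anisotropies
are normalized so max|ΔA|/max(A_protein) = 10⁻⁴, the canonical protein VCD
magnitude; the main-band absorptivity is set so 14 mg/mL in the 204 μm cell
peaks at 0.78 AU, making the 2–14 mg/mL series span ~0.08–0.78 AU. The sign
order of the BSA couplet (positive lobe at the lower wavenumber, the
positive-couplet convention for α-helix) is a fixture parameter; all
position checks are sign-agnostic.

## Noise model and its calibration

Defaults (per pulse, relative to the envelope peak):

| parameter            | default | meaning |
|----------------------|---------|---------|
| pulse_rsd            | 0.002   | effective pulse-energy jitter seen by the demodulator |
| common_mode_fraction | 0.995   | variance share correlated between the two detectors |
| white_noise_sd       | 5·10⁻⁴  | additive detector noise, independent per detector |
| drift_amplitude      | 10⁻³    | multiplicative 1/f^α envelope over a sweep (α = 1) |
| fringe_amplitude     | 10⁻³    | static polarizer-etalon fringes, period 1.2 cm⁻¹ |

These were set by a forward noise budget, not by fitting outputs: the
uncancelled part of the pulse jitter scales with the arm mismatch
|I_s − I_r| (near zero on solvent, up to ~0.5·env inside a strong protein
band), and propagating jitter + white noise through the lock-in
(σ_out ≈ σ_in·√(dt/τ)), the ΔA conversion (÷ J₁·DC) and the spline gives a
solvent-region noise density that lands at the few ×10⁻⁷ ΔAU scale for a
one-hour average at 8 cm⁻¹ resolution — the performance class of the
physical instrument this models. The split-half statistic
(`noise_metrics.split_half_rms`) evaluates exactly this from simulated scan
sets; the mean is removed within the evaluation region before the RMS (so
the statistic measures noise, not offset) and the √2 of differencing two
averages is deliberately not divided out, since the curve is used
relatively.

**Scan averaging.** A 5-minute scan is 92 narrowband sweeps. Because the
demodulation chain is linear and every noise term is Gaussian and
independent between sweeps, the average of m phase-locked sweeps is exactly
distributed as a single sweep with the random amplitudes scaled by 1/√m
(`NoiseModel.scaled_for_average`); static terms (fringes) are unchanged.
Multi-sweep scans are simulated this way at single-sweep cost. Drift
realizations are treated as independent between sweeps; cross-sweep 1/f
correlation is not modelled, which is exactly the regime the per-scan
baseline correction is there to absorb.

## Signature rules

From the detected amide I′ features (order of evaluation):
(a) a *couplet* is two opposite-sign features within 25 cm⁻¹ with magnitude
ratio in [1/3, 3]; (b) *alpha_helix*: the strongest feature belongs to a
couplet and no negative feature at ≤1630 cm⁻¹ (couplet lobes included)
reaches half the couplet magnitude; (c) *beta_sheet*: the strongest feature
is negative at ≤1630 cm⁻¹ with a positive feature above it and a further
negative above that (−,+,− from high to low wavenumber); (d) *mixed*: two
negative features ≥15 cm⁻¹ apart with no positive feature of half their
magnitude between them; (e) otherwise *indeterminate*. The thresholds live
in a `SignatureRules` table; classification is invariant under amplitude
rescaling. Including the couplet's own low-wavenumber lobe in rule (b)'s
negative check is essential: it is what routes the β-lactoglobulin pattern
past the α-helix rule to (c).

## Problem sizes used in the tests

Fixture-recovery checks run one noiseless sweep at the full instrument
scale (1.3 M pulses, 1580–1710 cm⁻¹). Statistical tests use the scaled
configuration (PEM 5 kHz, pulses 40 kHz, output 83.8 Sa/s — all ratios
preserved, 130 k pulses per sweep); classification robustness uses 12
five-minute scans (92 sweeps each, via the exact averaging identity above)
at 10 mg/mL over 20 seeds per protein. Split-half and averaging-law checks
use 24 synthetic white-noise scans on ≥260-point axes.

## What the generator does and does not emulate

Emulated: sweep/pulse/PEM timing and phase lock, Beer–Lambert protein and
D₂O band structure, the ~10⁻⁴ VCD-to-absorbance ratio, common-mode pulse
noise with imperfect balancing, 1/f drift within a sweep, detector white
noise, static polarizer fringes, and reference-arm solvent matching.

Not emulated: full polarization optics (Mueller/Jones propagation, linear
dichroism and birefringence artifacts), detector nonlinearity, wavenumber
calibration error or sweep nonlinearity, H₂O solvent, deuteration kinetics,
cross-sweep drift correlation, and the measured (as opposed to parametric)
laser emission profile. Passing tests therefore demonstrate correctness of
the signal chain and statistical behaviour under this model, not immunity
to optical artifacts a physical instrument may add; on real data the
phase-autoset routine and the configurable baseline/rule tables are the
intended adjustment points.

## Known limitations

- The single-pole lock-in filter is first order; steeper hardware filters
  would relax the block-averaging decimator's role.
- The LOD analysis takes the noise SD as an input measured elsewhere (e.g.
  from the split-half floor) rather than propagating a full error model
  through the calibration fit.
- Band positions are reported at grid extrema of the smoothed spectrum
  (±½ grid step ≈ 0.25 cm⁻¹ at full scale); no sub-grid peak interpolation
  is applied in the pipeline.
- JCAMP-DX support covers uncompressed AFFN XYDATA/XYPOINTS only.
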