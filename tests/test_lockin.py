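import numpy as np
import pytest
from scipy.special import j1

import qclvcd as q
from qclvcd.lockin import (
    autoset_phase,
    calibrate_vcd_gain,
    compute_absorbance,
    compute_vcd,
    default_vcd_gain,
    digital_lockin,
    discrete_first_harmonic,
    time_to_wavenumber,
    _FlatChiralSample,
)
from qclvcd.simulate import simulate_reference_offset, simulate_scan
from qclvcd.spectra import Spectrum

RATE = 4.0e4
TC = 0.01


def settled(trace):
    # trim 8 time constants: the residual transient is then < 0.04%
    return trace.amplitudes[trace.times > 8 * TC]


class TestLockinConvention:
    def test_matched_cosine_returns_peak_amplitude(self):
        """The amplitude convention anchor: A*cos at matched phase -> A."""
        t = np.arange(int(RATE)) / RATE  # 1 s
        amp, f, phi = 0.7, 5e3, 0.3
        sig = amp * np.cos(2 * np.pi * f * t + phi)
        trace = digital_lockin(t, sig, frequency=f, phase=phi,
                               time_constant=TC, output_rate=83.8, source_rate=RATE)
        np.testing.assert_allclose(settled(trace), amp, rtol=1e-3)

    def test_orthogonal_harmonic_rejected(self):
        t = np.arange(int(RATE)) / RATE
        sig = np.cos(2 * np.pi * 5e3 * t)
        trace = digital_lockin(t, sig, frequency=4e4, phase=0.0,
                               time_constant=TC, output_rate=83.8, source_rate=RATE)
        # the out-of-band tone leaks only through the filter skirt + boxcar
        assert np.max(np.abs(settled(trace))) < 1e-4

    def test_unresolvable_frequency_rejected(self):
        t = np.arange(1000) / RATE
        with pytest.raises(ValueError, match="not resolvable"):
            digital_lockin(t, np.ones(1000), frequency=3.1e4, phase=0.0,
                           time_constant=TC, output_rate=83.8, source_rate=RATE)

    def test_short_time_constant_rejected(self):
        t = np.arange(1000) / RATE
        with pytest.raises(ValueError, match="time_constant"):
            digital_lockin(t, np.ones(1000), frequency=5e3, phase=0.0,
                           time_constant=1e-5, output_rate=83.8, source_rate=RATE)

    def test_autoset_phase_recovers_signal_phase(self):
        t = np.arange(int(RATE)) / RATE
        phi = 1.1
        sig = 0.5 * np.cos(2 * np.pi * 5e3 * t + phi)

        from qclvcd.simulate import RawScan
        scan = RawScan(pulse_times=t, sample_amplitudes=sig,
                       reference_amplitudes=np.zeros_like(sig),
                       balanced_amplitudes=sig, sweep_start=1580, sweep_stop=1710,
                       sweep_speed=40, pulse_rate=RATE)
        est = autoset_phase(scan, frequency=5e3, time_constant=TC, output_rate=83.8)
        assert est == pytest.approx(phi, abs=1e-3)


class TestDiscreteHarmonicOracle:
    def test_pem_stream_demodulates_to_discrete_coefficient(self):
        """S_1f/S_dc equals the brute-force 8-point harmonic, not 2*J1.

        Run at delta0 = 2.5 rad and a large modulation index so the H1-vs-2J1
        gap (folded odd harmonics of the 8-pulse comb) clears the residual
        ripple of the filter/decimator chain.
        """
        delta0 = 2.5
        beta = 0.5
        t = np.arange(4 * int(RATE)) / RATE
        theta = 2 * np.pi * 5e3 * t + np.pi / 2
        stream = 1.0 + beta * np.sin(delta0 * np.sin(theta))
        s1f = settled(digital_lockin(t, stream, frequency=5e3, phase=0.0,
                                     time_constant=TC, output_rate=83.8, source_rate=RATE))
        sdc = settled(digital_lockin(t, stream, frequency=RATE, phase=0.0,
                                     time_constant=TC, output_rate=83.8, source_rate=RATE))
        measured = np.mean(s1f) / np.mean(sdc)

        # independent oracle: direct 8-point first-harmonic sum
        th = np.pi / 2 + 2 * np.pi * np.arange(8) / 8
        h1_brute = (2.0 / 8.0) * np.sum(np.sin(delta0 * np.sin(th)) * np.sin(th))
        assert discrete_first_harmonic(delta0) == pytest.approx(h1_brute, rel=1e-12)
        assert measured == pytest.approx(beta * h1_brute / 2.0, rel=5e-4)
        # ... and the continuous-lockin coefficient 2*J1 is measurably different
        assert abs(h1_brute / (2 * j1(delta0)) - 1.0) > 1e-3
        assert abs(measured / (beta * j1(delta0)) - 1.0) > 1e-3

    def test_calibrated_gain_matches_closed_form(self):
        """Round-trip calibration reproduces 4*J1/(ln10*H1) to < 0.1%."""
        assert calibrate_vcd_gain() == pytest.approx(default_vcd_gain(), rel=1e-3)


class TestAxisMapping:
    def test_sweep_endpoints(self):
        """t = 0 maps to 1400 and t = 7.75 s to 1710 for the broadband sweep."""
        from qclvcd.lockin import DemodTrace

        trace = DemodTrace(times=np.linspace(0.0, 7.75, 10000),
                           amplitudes=np.ones(10000), demod_frequency=5e4,
                           phase=0.0, time_constant=1e-9, decimated_rate=838.0)

        class Sweep:
            sweep_start, sweep_stop, sweep_speed, sweep_direction = 1400.0, 1710.0, 40.0, +1

        spec = time_to_wavenumber(trace, Sweep)
        assert spec.axis[0] == pytest.approx(1400.0, abs=0.1)
        assert spec.axis[-1] == pytest.approx(1710.0, abs=0.1)

    def test_settling_transient_trimmed(self):
        """First 5 time constants are dropped (minus the group-delay shift)."""
        from qclvcd.lockin import DemodTrace

        trace = DemodTrace(times=np.linspace(0.0, 3.0, 300), amplitudes=np.ones(300),
                           demod_frequency=5e4, phase=0.0, time_constant=0.01,
                           decimated_rate=100.0)

        class Sweep:
            sweep_start, sweep_stop, sweep_speed, sweep_direction = 1580.0, 1710.0, 40.0, +1

        spec = time_to_wavenumber(trace, Sweep)
        assert spec.axis[0] >= 1580.0 + 40.0 * 4 * 0.01 - 1e-9

    def test_times_beyond_sweep_rejected(self):
        from qclvcd.lockin import DemodTrace

        trace = DemodTrace(times=np.linspace(0.0, 10.0, 50), amplitudes=np.ones(50),
                           demod_frequency=5e4, phase=0.0, time_constant=0.01,
                           decimated_rate=5.0)

        class Sweep:
            sweep_start, sweep_stop, sweep_speed, sweep_direction = 1580.0, 1710.0, 40.0, +1

        with pytest.raises(ValueError, match="sweep duration"):
            time_to_wavenumber(trace, Sweep)


def make_spec(values, kind="intensity"):
    axis = np.linspace(1600.0, 1700.0, len(values))
    return Spectrum(axis=axis, values=np.asarray(values, dtype=float), kind=kind)


class TestComputeVcd:
    def setup_method(self):
        self.pem = q.PemSettings()
        self.dc = make_spec(np.full(50, 0.5))
        self.off = make_spec(np.full(50, 0.5))

    def test_zero_s1f_gives_zero_vcd(self):
        out = compute_vcd(make_spec(np.zeros(50)), self.dc, self.off, self.pem)
        np.testing.assert_array_equal(out.values, 0.0)

    def test_antisymmetry_in_s1f(self):
        s1f = make_spec(np.sin(np.linspace(0, 3, 50)) * 1e-4)
        neg = make_spec(-s1f.values)
        a = compute_vcd(s1f, self.dc, self.off, self.pem)
        b = compute_vcd(neg, self.dc, self.off, self.pem)
        np.testing.assert_allclose(b.values, -a.values, rtol=1e-12)

    def test_homogeneity(self):
        """1-homogeneous in s1f; invariant under common DC rescale."""
        s1f = make_spec(np.linspace(1e-5, 5e-5, 50))
        a = compute_vcd(s1f, self.dc, self.off, self.pem)
        b = compute_vcd(make_spec(3 * s1f.values), self.dc, self.off, self.pem)
        np.testing.assert_allclose(b.values, 3 * a.values, rtol=1e-12)
        c = compute_vcd(make_spec(2 * s1f.values), make_spec(2 * self.dc.values),
                        make_spec(2 * self.off.values), self.pem)
        np.testing.assert_allclose(c.values, a.values, rtol=1e-12)

    def test_axis_mismatch_rejected(self):
        other = Spectrum(axis=np.linspace(0, 1, 50), values=np.zeros(50))
        with pytest.raises(ValueError, match="axis"):
            compute_vcd(other, self.dc, self.off, self.pem)

    def test_total_absorption_masked(self):
        dc = make_spec(np.r_[np.full(25, 0.5), np.full(25, 1e-12)])
        off = make_spec(np.zeros(50))
        out = compute_vcd(make_spec(np.full(50, 1e-5)), dc, off, self.pem)
        assert np.all(np.isfinite(out.values[:25]))
        assert np.all(np.isnan(out.values[25:]))
        assert out.meta["masked_points"] == 25


class TestComputeAbsorbance:
    def test_equal_intensities_give_zero(self):
        dc = make_spec(np.full(20, 0.4))
        out = compute_absorbance(dc, make_spec(np.full(20, 0.4)))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-15)

    def test_decade_ratio_gives_unit_absorbance(self):
        out = compute_absorbance(make_spec(np.full(20, 0.05)), make_spec(np.full(20, 0.5)))
        np.testing.assert_allclose(out.values, 1.0, rtol=1e-12)

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            compute_absorbance(make_spec(np.zeros(20)), make_spec(np.ones(20)))


class TestRoundTrip:
    def test_flat_vcd_recovered_within_half_percent(self, scaled_cfg, noiseless):
        """Simulate -> demodulate -> reconstruct recovers a flat dA = 5e-4."""
        from qclvcd.samples import SampleModel
        from qclvcd.workflow import demodulate_sweep

        scan = simulate_scan(scaled_cfg, _FlatChiralSample(5e-4), noiseless, seed=0)
        offset = simulate_reference_offset(
            scaled_cfg, seed=0, sample=SampleModel(name="blank", concentration=0.0))
        vcd, _ = demodulate_sweep(scan, scaled_cfg, offset)
        assert np.max(np.abs(vcd.values / 5e-4 - 1.0)) <= 0.005

    def test_bsa_absorbance_max_within_one_percent(self, scaled_cfg, noiseless):
        """Unsmoothed reconstructed absorbance matches the Beer-Lambert truth."""
        from qclvcd.pipeline import average_scans
        from qclvcd.samples import solvent_only
        from qclvcd.workflow import acquire

        sample = q.protein_fixture("bsa", 14.0)
        meas = acquire(scaled_cfg, sample, noiseless, 1, seed=0)
        blank = acquire(scaled_cfg, solvent_only(), noiseless, 1, seed=1)
        ab = compute_absorbance(average_scans(meas["dc"]), average_scans(blank["dc"]))
        window = ab.restrict(1600.0, 1690.0)
        solvent = solvent_only().absorbance(window.axis, scaled_cfg.path_length_mm)
        truth = (sample.absorbance(window.axis, scaled_cfg.path_length_mm) - solvent).max()
        assert window.values.max() == pytest.approx(truth, rel=0.01)
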