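import numpy as np
import pytest
from hypothesis import given, strategies as st

from qclvcd.bands import (
    BandFeature,
    SignatureRules,
    classify_signature,
    find_vcd_bands,
    fit_calibration,
    peak_response,
)
from qclvcd.pipeline import spline_smooth
from qclvcd.samples import gaussian
from qclvcd.spectra import Spectrum

AXIS = np.arange(1580.0, 1710.0, 0.5)


def spec(values, resolution=8.0):
    return Spectrum(axis=AXIS, values=np.asarray(values, dtype=float),
                    kind="vcd", resolution=resolution)


def feature(pos, amp):
    return BandFeature(position=pos, amplitude=amp, prominence=abs(amp), width=12.0)


class TestFitCalibration:
    def test_exact_line_and_lod_formula(self):
        c = [1.0, 2.0, 3.0, 4.0]
        out = fit_calibration(c, [2.0 * x for x in c], noise_sd=6.0)
        assert out.slope == pytest.approx(2.0)
        assert out.intercept == pytest.approx(0.0, abs=1e-12)
        assert out.r_squared == pytest.approx(1.0)
        assert out.lod == pytest.approx(9.0)

    def test_lod_consistent_with_published_noise_floor(self):
        """noise 5.93e-7 dAU with the matching slope gives LOD 0.32 mg/mL."""
        noise = 5.93e-7
        slope = 3.0 * noise / 0.32
        concs = np.array([2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0])
        out = fit_calibration(concs, slope * concs, noise_sd=noise)
        assert out.lod == pytest.approx(0.32, rel=1e-12)

    def test_lod_halves_when_noise_halves(self):
        c = np.arange(1.0, 8.0)
        a = fit_calibration(c, 2.0 * c, noise_sd=4.0)
        b = fit_calibration(c, 2.0 * c, noise_sd=2.0)
        assert b.lod == pytest.approx(a.lod / 2.0)

    @given(scale=st.floats(min_value=0.01, max_value=100.0))
    def test_lod_invariant_under_common_rescale(self, scale):
        c = np.arange(1.0, 8.0)
        y = 3.0 * c + 0.5
        a = fit_calibration(c, y, noise_sd=1.2)
        b = fit_calibration(c, scale * y, noise_sd=scale * 1.2)
        assert b.lod == pytest.approx(a.lod, rel=1e-9)

    def test_noisy_series_recovers_slope_within_ci(self):
        rng = np.random.default_rng(9)
        c = np.array([2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0])
        true_slope = 5.6e-6
        y = true_slope * c + rng.normal(0.0, 2e-6, size=c.size)
        from scipy.stats import linregress
        fit = linregress(c, y)
        out = fit_calibration(c, y, noise_sd=2e-6)
        assert abs(out.slope - true_slope) <= 2.0 * fit.stderr

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_calibration([1.0, 2.0], [1.0, 2.0], noise_sd=1.0)
        with pytest.raises(ValueError):
            fit_calibration([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], noise_sd=0.0)
        with pytest.raises(ValueError, match="slope"):
            fit_calibration([1.0, 2.0, 3.0], [5.0, 5.0, 5.0], noise_sd=1.0)


class TestPeakResponse:
    def test_zero_spectrum(self):
        assert peak_response(spec(np.zeros_like(AXIS))) == 0.0

    @given(scale=st.floats(min_value=0.1, max_value=10.0))
    def test_homogeneity(self, scale):
        v = gaussian(AXIS, 1640.0, 15.0) - 0.4 * gaussian(AXIS, 1665.0, 15.0)
        assert peak_response(spec(scale * v)) == pytest.approx(
            scale * peak_response(spec(v)), rel=1e-12)

    def test_returns_signed_extremum(self):
        v = 0.5 * gaussian(AXIS, 1640.0, 15.0) - 1.0 * gaussian(AXIS, 1621.0, 12.0)
        window = (AXIS >= 1610.0) & (AXIS <= 1630.0)
        assert peak_response(spec(v), (1610.0, 1630.0)) == v[window].min()
        assert peak_response(spec(v), (1610.0, 1630.0)) == pytest.approx(-1.0, abs=0.01)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            peak_response(spec(np.zeros_like(AXIS)), (1800.0, 1900.0))


class TestFindVcdBands:
    def test_single_positive_gaussian(self):
        v = 1e-4 * gaussian(AXIS, 1650.0, 14.0)
        feats = find_vcd_bands(spec(v), min_prominence=1e-5)
        assert len(feats) == 1
        assert feats[0].position == pytest.approx(1650.0, abs=0.5)
        assert feats[0].sign > 0

    def test_three_lobe_pattern_found_with_signs(self):
        v = (-0.4 * gaussian(AXIS, 1660.0, 12.0)
             + 0.65 * gaussian(AXIS, 1638.0, 12.0)
             - 1.0 * gaussian(AXIS, 1621.0, 12.0))
        feats = find_vcd_bands(spec(v), min_prominence=0.05)
        assert [round(f.position) for f in feats] == [1621, 1638, 1660]
        assert [f.sign for f in feats] == [-1, +1, -1]

    def test_submerged_undulation_is_not_a_band(self):
        """A local max that stays below zero is not a positive feature."""
        v = -(gaussian(AXIS, 1635.0, 12.0) + gaussian(AXIS, 1660.0, 12.0))
        feats = find_vcd_bands(spec(v), min_prominence=0.01)
        assert all(f.sign < 0 for f in feats)
        assert len(feats) == 2

    def test_noise_only_rarely_yields_features_at_5_sigma(self):
        """False-positive rate of the 5-sigma prominence threshold <= 5%.

        Searched in the inset band region the pipeline uses (the spline has
        inflated variance at the sweep edges, which are excluded there).
        """
        rng = np.random.default_rng(0)
        n_with_features = 0
        for _ in range(100):
            smoothed = spline_smooth(spec(rng.standard_normal(AXIS.size),
                                          resolution=0.5), 8.0)
            sigma = float(np.std(smoothed.values))
            if find_vcd_bands(smoothed, region=(1595.0, 1700.0),
                              min_prominence=5.0 * sigma):
                n_with_features += 1
        assert n_with_features <= 5

    def test_region_outside_axis_rejected(self):
        with pytest.raises(ValueError):
            find_vcd_bands(spec(np.zeros_like(AXIS)), region=(1800.0, 1900.0))


class TestClassifySignature:
    def bsa_like(self, scale=1.0):
        return [feature(1662.0, -1.0 * scale), feature(1648.0, +0.95 * scale),
                feature(1628.0, -0.3 * scale)]

    def blg_like(self, scale=1.0):
        return [feature(1660.0, -0.4 * scale), feature(1638.0, +0.65 * scale),
                feature(1621.0, -1.0 * scale)]

    def lysozyme_like(self, scale=1.0):
        return [feature(1660.0, -1.0 * scale), feature(1635.0, -0.85 * scale)]

    def test_strong_couplet_is_alpha_helix(self):
        out = classify_signature(self.bsa_like())
        assert out.label == "alpha_helix"
        assert any("couplet" in e for e in out.evidence)

    def test_low_negative_under_couplet_is_beta_sheet(self):
        assert classify_signature(self.blg_like()).label == "beta_sheet"

    def test_double_negative_is_mixed(self):
        assert classify_signature(self.lysozyme_like()).label == "mixed"

    def test_empty_features_indeterminate(self):
        assert classify_signature([]).label == "indeterminate"

    def test_lone_band_indeterminate(self):
        assert classify_signature([feature(1650.0, 1.0)]).label == "indeterminate"

    @given(scale=st.floats(min_value=1e-6, max_value=1e3))
    def test_scale_invariance(self, scale):
        for feats in (self.bsa_like, self.blg_like, self.lysozyme_like):
            assert (classify_signature(feats(scale)).label
                    == classify_signature(feats(1.0)).label)

    def test_rules_are_configurable(self):
        tight = SignatureRules(couplet_max_separation=5.0)
        out = classify_signature(self.bsa_like(), tight)
        assert out.label != "alpha_helix"  # 1662/1648 no longer a couplet
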