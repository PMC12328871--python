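"""Spectral quantification: FFT conventions, baselines, AUC, ROI ratios."""

import numpy as np
import pytest

from hypercsi.core import AcquisitionProtocol, CsiTensor
from hypercsi.phantom import (GuideImage, acquire_csi, downsample_guide,
                              make_brain_phantom, make_guide,
                              synthesize_spectral_cube)
from hypercsi.phantom import _spatial_ifft
from hypercsi.quant import (QuantConfig, baseline_correct, integrate_peak,
                            make_roi_mask, metabolite_auc_maps, quantify,
                            roi_mask_from_phantom, to_frequency)


def _lr_spatial_time(phantom, protocol):
    cube = synthesize_spectral_cube(phantom, protocol)
    ksp = acquire_csi(cube, protocol)
    return ksp.with_data(_spatial_ifft(ksp.data), spatial_domain="spatial")


class TestToFrequency:
    def test_delta_fid_gives_flat_spectrum(self, protocol):
        fid = np.zeros((1, 1, 128), complex)
        fid[0, 0, 0] = 1.0
        spec = to_frequency(CsiTensor(fid, protocol=protocol))
        np.testing.assert_allclose(np.abs(spec.data[0, 0]),
                                   np.abs(spec.data[0, 0, 0]), rtol=1e-12)

    def test_bin_spacing_is_bandwidth_over_points(self, protocol):
        fid = np.zeros((1, 1, 128), complex)
        spec = to_frequency(CsiTensor(fid, protocol=protocol))
        dppm = np.diff(spec.ppm_axis)
        np.testing.assert_allclose(dppm, 15.625 / protocol.hz_per_ppm)

    def test_damped_exponential_gives_lorentzian_fwhm(self, protocol):
        """FWHM of the absorption line equals 1/(pi * T2*)."""
        t2s = 0.02  # s -> expected FWHM 15.92 Hz
        t = protocol.time_axis_s()
        fid = np.exp(-t / t2s)[None, None, :].astype(complex)
        spec = to_frequency(CsiTensor(fid, protocol=protocol), zero_fill=16,
                            first_point_half=True)
        absorption = spec.data[0, 0].real
        f = protocol.freq_axis_hz(128 * 16)
        half = absorption.max() / 2
        above = f[absorption >= half]
        fwhm = above.max() - above.min()
        assert fwhm == pytest.approx(1 / (np.pi * t2s), rel=0.05)

    def test_parseval_without_processing(self, protocol, rng):
        fid = rng.standard_normal((4, 4, 128)) + 1j * rng.standard_normal(
            (4, 4, 128))
        spec = to_frequency(CsiTensor(fid, protocol=protocol))
        assert spec.energy() == pytest.approx(np.sum(np.abs(fid) ** 2),
                                              rel=1e-12)

    def test_wrong_domain_rejected(self, protocol):
        spec = to_frequency(CsiTensor(np.zeros((1, 1, 128), complex),
                                      protocol=protocol))
        with pytest.raises(ValueError, match="time-domain"):
            to_frequency(spec)


class TestBaselineCorrect:
    ppm = np.linspace(0.0, 40.0, 801)

    def test_flat_offset_removed_exactly(self):
        spec = np.full(self.ppm.size, 3.0)
        out = baseline_correct(spec, self.ppm, [(18.0, 22.0)], [20.0],
                               order=0, scope="global")
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_ramp_plus_lorentzian_auc_within_1pct(self):
        # wide axis so the far Lorentzian tails barely touch the fit points
        ppm = np.linspace(0.0, 400.0, 8001)
        gamma = 0.5
        lor = 1.0 / (1.0 + ((ppm - 200.0) / gamma) ** 2)
        spec = lor + 0.2 + 0.01 * ppm  # positive ramp background
        out = baseline_correct(spec, ppm, [(195.0, 205.0)], [200.0],
                               order=1, scope="global", exclusion_ppm=50.0)
        auc = integrate_peak(out, ppm, (195.0, 205.0))
        closed_form = 2 * gamma * np.arctan(5.0 / gamma)
        assert auc == pytest.approx(closed_form, rel=0.01)

    def test_local_scope_tracks_curved_background(self):
        # 1/x-type tail from a remote peak: local fit beats the global line
        tail = 10.0 / (self.ppm + 20.0)
        gamma = 0.4
        lor = 1.0 / (1.0 + ((self.ppm - 25.0) / gamma) ** 2)
        spec = tail + lor
        closed_form = 2 * gamma * np.arctan(3.0 / gamma)
        kw = dict(order=1, exclusion_ppm=3.5, flank_ppm=3.0)
        out_local = baseline_correct(spec, self.ppm, [(22.0, 28.0)], [25.0],
                                     scope="local", **kw)
        out_global = baseline_correct(spec, self.ppm, [(22.0, 28.0)], [25.0],
                                      scope="global", **kw)
        auc_local = integrate_peak(out_local, self.ppm, (22.0, 28.0))
        auc_global = integrate_peak(out_global, self.ppm, (22.0, 28.0))
        # the local flank fit follows the curved tail; the global line cannot
        assert auc_local == pytest.approx(closed_form, rel=0.07)
        assert abs(auc_local - closed_form) < abs(auc_global - closed_form)

    def test_no_baseline_points_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            baseline_correct(np.ones(self.ppm.size), self.ppm,
                             [(0.0, 40.0)], [20.0])


class TestIntegratePeak:
    ppm = np.linspace(-50.0, 50.0, 4001)

    def test_zero_spectrum_integrates_to_zero(self):
        assert integrate_peak(np.zeros(self.ppm.size), self.ppm,
                              (-10, 10)) == 0.0

    def test_linearity_in_amplitude(self):
        gamma = 1.0
        lor = 1.0 / (1.0 + (self.ppm / gamma) ** 2)
        a1 = integrate_peak(lor, self.ppm, (-10, 10))
        a2 = integrate_peak(2 * lor, self.ppm, (-10, 10))
        assert a2 == pytest.approx(2 * a1, rel=1e-12)

    def test_unit_lorentzian_window_fraction_matches_arctan_oracle(self):
        """Window of +/-10 half-widths captures (2/pi) atan(10) of the area."""
        gamma = 1.0
        lor = 1.0 / (1.0 + (self.ppm / gamma) ** 2)
        auc = integrate_peak(lor, self.ppm, (-10 * gamma, 10 * gamma))
        total = np.pi * gamma
        assert auc / total == pytest.approx(2 / np.pi * np.arctan(10.0),
                                            rel=1e-3)
        assert auc / total == pytest.approx(0.937, abs=0.01)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            integrate_peak(np.ones(self.ppm.size), self.ppm, (60.0, 70.0))


@pytest.fixture(scope="module")
def lr_setup():
    proto = AcquisitionProtocol()
    ph = make_brain_phantom(11, 64, {"Lac/Pyr": 0.256, "Bic/Pyr": 0.138})
    img = _lr_spatial_time(ph, proto)
    mask = roi_mask_from_phantom(ph, grid=16)
    return ph, img, mask


class TestQuantify:
    def test_noiseless_ratios_within_2pct(self, lr_setup):
        ph, img, mask = lr_setup
        res = quantify(img, ph.peaks, mask)
        assert res.whole_roi_ratios["lactate/pyruvate"] == pytest.approx(
            0.256, rel=0.02)
        assert res.whole_roi_ratios["bicarbonate/pyruvate"] == pytest.approx(
            0.138, rel=0.02)
        assert res.whole_roi_ratios["lactate/bicarbonate"] == pytest.approx(
            0.256 / 0.138, rel=0.02)

    def test_global_rescaling_invariance(self, lr_setup):
        ph, img, mask = lr_setup
        r1 = quantify(img, ph.peaks, mask).whole_roi_ratios
        r2 = quantify(img.with_data(img.data * 1000.0), ph.peaks,
                      mask).whole_roi_ratios
        for k in r1:
            assert r2[k] == pytest.approx(r1[k], rel=1e-10)

    def test_global_phase_invariance(self, lr_setup):
        ph, img, mask = lr_setup
        r1 = quantify(img, ph.peaks, mask).whole_roi_ratios
        r2 = quantify(img.with_data(img.data * np.exp(1j * 1.1)), ph.peaks,
                      mask).whole_roi_ratios
        for k in r1:
            assert r2[k] == pytest.approx(r1[k], rel=1e-10)

    def test_zero_lactate_gives_zero_ratios(self):
        proto = AcquisitionProtocol()
        ph = make_brain_phantom(3, 64, {"Lac/Pyr": 0.3, "Bic/Pyr": 0.1})
        ph.amplitude_maps["lactate"][:] = 0.0
        img = _lr_spatial_time(ph, proto)
        mask = roi_mask_from_phantom(ph, grid=16)
        res = quantify(img, ph.peaks, mask)
        # residual neighbour-tail leakage stays below 2% of pyruvate
        assert res.whole_roi_ratios["lactate/pyruvate"] == pytest.approx(
            0.0, abs=0.02)

    def test_ratio_maps_respect_denominator_floor(self, lr_setup):
        ph, img, mask = lr_setup
        res = quantify(img, ph.peaks, mask)
        rm = res.ratio_maps["lactate/pyruvate"]
        assert np.isnan(rm.values[~mask.mask]).all()
        assert np.isfinite(rm.whole_roi_ratio)

    def test_mask_grid_mismatch_rejected(self, lr_setup):
        ph, img, _ = lr_setup
        bad = roi_mask_from_phantom(ph, grid=32)
        with pytest.raises(ValueError, match="grid"):
            quantify(img, ph.peaks, bad)


class TestRoiMask:
    def test_bright_ellipse_recovers_truth(self, phantom64):
        guide = downsample_guide(make_guide(phantom64))
        mask = make_roi_mask(guide)
        from hypercsi.phantom import box_downsample
        truth = box_downsample(phantom64.brain_mask.astype(float), 1) > 0.5
        dice = 2 * (mask.mask & truth).sum() / (mask.mask.sum() + truth.sum())
        assert dice >= 0.95

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            make_roi_mask(GuideImage(np.ones((64, 64)), 64))

    def test_phantom_truth_mask_is_exact(self, phantom64):
        mask = roi_mask_from_phantom(phantom64)
        np.testing.assert_array_equal(mask.mask, phantom64.brain_mask)
        assert mask.source == "phantom_truth"
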