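"""Phantom generator: ground-truth bookkeeping, signal synthesis, encoding."""

import numpy as np
import pytest

from hypercsi.core import AcquisitionProtocol, CsiTensor, Dynamics, PeakModel
from hypercsi.phantom import (GuideImage, PhantomSpec, acquire_csi,
                              add_complex_noise, box_downsample, centric_order,
                              downsample_guide, ground_truth_ratios,
                              make_brain_phantom, make_guide, noise_sd_for_snr,
                              synthesize_spectral_cube)
from hypercsi.phantom import _spatial_ifft


class TestBrainPhantom:
    def test_identity_ratios_give_equal_mask_means(self):
        ph = make_brain_phantom(1, 64, {"Lac/Pyr": 1.0, "Bic/Pyr": 1.0})
        assert ph.mask_mean("lactate") == pytest.approx(ph.mask_mean("pyruvate"))
        assert ph.mask_mean("bicarbonate") == pytest.approx(
            ph.mask_mean("pyruvate"))

    def test_same_seed_is_bit_identical(self):
        a = make_brain_phantom(1, 64)
        b = make_brain_phantom(1, 64)
        for m in a.amplitude_maps:
            np.testing.assert_array_equal(a.amplitude_maps[m],
                                          b.amplitude_maps[m])

    def test_pretreatment_targets_recovered_to_machine_precision(self):
        targets = {"Lac/Pyr": 0.256, "Bic/Pyr": 0.138}
        ph = make_brain_phantom(7, 64, targets)
        truth = ground_truth_ratios(ph)
        assert truth["lactate/pyruvate"] == pytest.approx(0.256, rel=1e-10)
        assert truth["bicarbonate/pyruvate"] == pytest.approx(0.138, rel=1e-10)

    def test_chained_ratio_targets(self):
        ph = make_brain_phantom(3, 64, {"Lac/Pyr": 0.406, "Lac/Bic": 3.40})
        truth = ground_truth_ratios(ph)
        assert truth["lactate/bicarbonate"] == pytest.approx(3.40, rel=1e-10)

    def test_unknown_metabolite_rejected(self):
        with pytest.raises(ValueError, match="unknown metabolite"):
            make_brain_phantom(1, 64, {"glucose/pyruvate": 1.0})

    def test_mask_occupancy_and_zero_outside(self):
        ph = make_brain_phantom(5, 64)
        assert 0.30 <= ph.brain_mask.mean() <= 0.60
        for m, amp in ph.amplitude_maps.items():
            assert np.all(amp[~ph.brain_mask] == 0)
            assert np.all(amp >= 0)

    def test_heterogeneity_is_bounded(self):
        ph = make_brain_phantom(2, 64, heterogeneity=0.2)
        amp = ph.amplitude_maps["pyruvate"][ph.brain_mask]
        assert amp.max() / amp.mean() < 1.35
        assert amp.min() / amp.mean() > 0.65


def _single_voxel_phantom(amplitude, fwhm=8.0, shift=183.2, grid=16):
    mask = np.zeros((grid, grid), bool)
    mask[grid // 2, grid // 2] = True
    amp = np.zeros((grid, grid))
    amp[mask] = amplitude
    return PhantomSpec(grid=grid, brain_mask=mask,
                       amplitude_maps={"lactate": amp},
                       peaks=[PeakModel("lactate", shift, fwhm_hz=fwhm)])


class TestSpectralSynthesis:
    def test_peak_auc_is_linear_in_amplitude(self, protocol):
        spectra = []
        for a in (1.0, 2.0):
            cube = synthesize_spectral_cube(_single_voxel_phantom(a), protocol)
            spec = np.fft.fft(cube.data[8, 8], norm="ortho")
            spectra.append(np.abs(spec).sum())
        assert spectra[1] == pytest.approx(2 * spectra[0], rel=1e-12)

    def test_zero_amplitudes_give_zero_cube(self, protocol):
        cube = synthesize_spectral_cube(_single_voxel_phantom(0.0), protocol)
        assert np.all(cube.data == 0)

    def test_well_separated_peaks_match_isolated_aucs(self, protocol):
        """Peaks well beyond 3 FWHM apart integrate like isolated lines."""
        from hypercsi.quant import QuantConfig, metabolite_auc_maps

        grid = 16
        mask = np.zeros((grid, grid), bool)
        mask[8, 8] = True
        amp = np.zeros((grid, grid))
        amp[8, 8] = 1.0
        fwhm = 8.0
        fw_ppm = fwhm / protocol.hz_per_ppm
        sep_ppm = 5 * fw_ppm  # 40 Hz
        peaks = [PeakModel("pyruvate", 171.0, fwhm),
                 PeakModel("lactate", 171.0 + sep_ppm, fwhm)]
        # windows scaled to the linewidth so they stay disjoint
        cfg = QuantConfig(window_ppm=1.0 * fw_ppm, exclusion_ppm=1.1 * fw_ppm,
                          flank_ppm=0.8 * fw_ppm, line_broaden_hz=2.0)
        both = PhantomSpec(grid=grid, brain_mask=mask,
                           amplitude_maps={"pyruvate": amp,
                                           "lactate": 0.5 * amp},
                           peaks=peaks)
        maps_both = metabolite_auc_maps(
            synthesize_spectral_cube(both, protocol), peaks, cfg)
        for met, peak, a in [("pyruvate", peaks[0], amp),
                             ("lactate", peaks[1], 0.5 * amp)]:
            alone = PhantomSpec(grid=grid, brain_mask=mask,
                                amplitude_maps={met: a}, peaks=[peak])
            maps_alone = metabolite_auc_maps(
                synthesize_spectral_cube(alone, protocol), [peak], cfg)
            assert maps_both[met][8, 8] == pytest.approx(
                maps_alone[met][8, 8], rel=0.01)

    def test_peak_outside_window_rejected(self, protocol):
        ph = _single_voxel_phantom(1.0, shift=171.0 + 70.0)  # ~1.14 kHz off
        with pytest.raises(ValueError, match="outside"):
            synthesize_spectral_cube(ph, protocol)


class TestCentricOrder:
    def test_brute_force_4x4(self):
        order = centric_order(4, 4)
        # origin (floor(N/2)) is visited first
        assert tuple(order[0]) == (2, 2)
        d2 = (order[:, 0] - 2) ** 2 + (order[:, 1] - 2) ** 2
        assert np.all(np.diff(d2) >= 0)
        # brute-force check: the multiset of distances matches a full sort
        ky, kx = np.meshgrid(np.arange(4) - 2, np.arange(4) - 2, indexing="ij")
        np.testing.assert_array_equal(np.sort(d2),
                                      np.sort((ky**2 + kx**2).ravel()))

    def test_every_encode_visited_once(self):
        order = centric_order(16, 16)
        assert len(np.unique(order[:, 0] * 16 + order[:, 1])) == 256


class TestAcquisition:
    def test_round_trip_without_dynamics(self, phantom64, protocol):
        cube = synthesize_spectral_cube(phantom64, protocol)
        ksp = acquire_csi(cube, protocol)
        lowres = box_downsample(cube.data, 4)
        np.testing.assert_allclose(_spatial_ifft(ksp.data), lowres, atol=1e-12)

    def test_encoding_is_unitary(self, phantom64, protocol):
        cube = synthesize_spectral_cube(phantom64, protocol)
        ksp = acquire_csi(cube, protocol)
        lowres = box_downsample(cube.data, 4)
        assert ksp.energy() == pytest.approx(np.sum(np.abs(lowres) ** 2),
                                             rel=1e-12)

    def test_last_shot_scale_matches_closed_form(self, protocol):
        """FA=10 deg, 256 shots, T1=30 s, TR=75 ms."""
        dyn = Dynamics(consume_rf=True, t1_s=30.0)
        fa = np.deg2rad(10.0)
        expected = np.sin(fa) * np.cos(fa) ** 255 * np.exp(-19.2 / 30.0)
        assert dyn.shot_scale(256, protocol, 30.0) == pytest.approx(
            expected, rel=1e-12)

    def test_shot_scales_strictly_decrease(self, protocol):
        dyn = Dynamics(consume_rf=True, t1_s=30.0)
        scales = dyn.shot_scale(np.arange(1, 257), protocol, 30.0)
        assert np.all(np.diff(scales) < 0)

    def test_per_metabolite_dynamics_requires_components(self, phantom64,
                                                         protocol):
        cube = synthesize_spectral_cube(phantom64, protocol)
        with pytest.raises(ValueError, match="sub-cubes"):
            acquire_csi(cube, protocol, Dynamics(consume_rf=True))

    def test_non_divisible_grid_rejected(self, protocol):
        bad = CsiTensor(np.zeros((24, 24, 128), complex))
        with pytest.raises(ValueError, match="divisible"):
            acquire_csi(bad, protocol)


class TestNoise:
    def test_zero_sd_is_identity(self, phantom64, protocol):
        cube = synthesize_spectral_cube(phantom64, protocol)
        ksp = acquire_csi(cube, protocol)
        out = add_complex_noise(ksp, 0.0, seed=3)
        np.testing.assert_array_equal(out.data, ksp.data)

    def test_real_part_variance_is_half_sd_squared(self):
        z = CsiTensor(np.zeros((16, 16, 128), complex))
        out = add_complex_noise(z, 1.0, seed=0)
        assert out.data.real.var() == pytest.approx(0.5, rel=0.05)

    def test_seeded_reproducibility(self):
        z = CsiTensor(np.zeros((8, 8, 32), complex))
        a = add_complex_noise(z, 1.0, seed=11)
        b = add_complex_noise(z, 1.0, seed=11)
        np.testing.assert_array_equal(a.data, b.data)

    def test_negative_sd_rejected(self):
        z = CsiTensor(np.zeros((8, 8, 32), complex))
        with pytest.raises(ValueError):
            add_complex_noise(z, -1.0, seed=0)

    def test_snr_definition(self, phantom64, protocol):
        cube = synthesize_spectral_cube(phantom64, protocol)
        ksp = acquire_csi(cube, protocol)
        sd = noise_sd_for_snr(ksp, 20.0)
        img = _spatial_ifft(ksp.data)
        spec = np.fft.fftshift(np.fft.fft(img, axis=2, norm="ortho"), axes=2)
        assert np.abs(spec).max() / sd == pytest.approx(20.0, rel=1e-12)


class TestGuide:
    def test_constant_guide_downsample(self):
        g = GuideImage(np.full((128, 128), 3.5), 128)
        out = downsample_guide(g)
        assert out.grid == 64
        np.testing.assert_allclose(out.pixels, 3.5)

    def test_checkerboard_downsamples_to_half(self):
        cb = np.indices((128, 128)).sum(axis=0) % 2
        out = downsample_guide(GuideImage(cb.astype(float), 128))
        np.testing.assert_allclose(out.pixels, 0.5)

    def test_default_guide_grids(self, phantom64):
        guide = make_guide(phantom64)
        assert guide.grid == 128
        assert downsample_guide(guide).grid == 64

    def test_guide_edges_colocalise_with_mask(self, phantom64):
        """Bright guide foreground overlaps the brain mask almost exactly."""
        guide = downsample_guide(make_guide(phantom64))
        fg = guide.pixels > 0.5 * guide.pixels.max()
        truth = box_downsample(phantom64.brain_mask.astype(float), 1) > 0.5
        dice = 2 * (fg & truth).sum() / (fg.sum() + truth.sum())
        assert dice > 0.9

    def test_odd_grid_rejected(self, phantom64):
        with pytest.raises(ValueError):
            make_guide(phantom64, native_grid=127)
        g = GuideImage(np.ones((64, 64)), 64)
        with pytest.raises(ValueError):
            downsample_guide(g, factor=3)
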