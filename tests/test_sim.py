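"""Simulator: rendering, scaling law, PSF blur, Poisson acquisition."""

import numpy as np
import pytest
from scipy import optimize, stats

import sted_restore as sr


class TestRenderPhantom:
    def test_empty_phantom_renders_all_zero(self):
        ph = sr.Phantom("puncta", (32, 32), 20.0, structures=[], seed=0)
        assert not sr.render_phantom(ph).any()

    def test_point_source_is_single_pixel_before_blur(self):
        ph = sr.Phantom("puncta", (32, 32), 20.0, structures=[
            {"type": "punctum", "center": np.array([10.0, 20.0]),
             "amplitude": 3.5}], seed=0)
        grid = sr.render_phantom(ph)
        assert np.count_nonzero(grid) == 1
        assert grid[10, 20] == pytest.approx(3.5)

    def test_rendering_is_deterministic(self, filament_phantom):
        a = sr.render_phantom(filament_phantom)
        b = sr.render_phantom(filament_phantom)
        assert np.array_equal(a, b)

    def test_non_negative_for_all_kinds(self):
        for kind in ("filaments", "puncta", "hollow_tubes"):
            ph = sr.make_phantom(kind, (64, 64), 20.0, 5, seed=2)
            grid = sr.render_phantom(ph)
            assert grid.min() >= 0
            assert grid.any()

    def test_structure_outside_grid_rejected(self):
        ph = sr.Phantom("puncta", (16, 16), 20.0, structures=[
            {"type": "punctum", "center": np.array([20.0, 5.0]),
             "amplitude": 1.0}], seed=0)
        with pytest.raises(ValueError, match="outside the grid"):
            sr.render_phantom(ph)

    def test_3d_filaments_render(self):
        ph = sr.make_phantom("filaments", (16, 48, 48), 20.0, 4, seed=1)
        grid = sr.render_phantom(ph)
        assert grid.shape == (16, 48, 48)
        assert grid.any()


class TestScalingLaw:
    def test_no_depletion_returns_confocal_fwhm(self):
        optics = sr.OpticsModel(240.0, 0.0, 1.0)
        assert sr.effective_fwhm(optics) == pytest.approx(240.0)

    def test_saturation_power_gives_sqrt_two_gain(self):
        optics = sr.OpticsModel(240.0, 1.0, 1.0)
        assert sr.effective_fwhm(optics) == pytest.approx(240.0 / np.sqrt(2))

    def test_fifteen_fold_saturation_gives_60nm(self, optics):
        assert sr.effective_fwhm(optics) == pytest.approx(60.0)

    def test_strictly_decreasing_in_power(self):
        fwhms = [sr.effective_fwhm(sr.OpticsModel(240.0, p, 1.0))
                 for p in np.linspace(0, 30, 16)]
        assert np.all(np.diff(fwhms) < 0)

    def test_negative_power_rejected(self):
        with pytest.raises(ValueError):
            sr.OpticsModel(240.0, -1.0, 1.0)


class TestBlur:
    def test_total_intensity_conserved_for_interior_structure(self, optics):
        grid = np.zeros((64, 64))
        grid[32, 32] = 7.0
        out = sr.blur(grid, optics, 20.0)
        assert out.sum() == pytest.approx(7.0, rel=1e-6)

    def test_blurred_delta_fwhm_matches_scaling_law(self, optics):
        grid = np.zeros((128, 128))
        grid[64, 64] = 1.0
        out = sr.blur(grid, optics, 20.0)
        x = np.arange(128)

        def gauss(x, a, c, s):
            return a * np.exp(-0.5 * ((x - c) / s) ** 2)

        popt, _ = optimize.curve_fit(gauss, x, out[64], p0=[out.max(), 64, 2])
        fwhm = 2 * np.sqrt(2 * np.log(2)) * abs(popt[2]) * 20.0
        assert fwhm == pytest.approx(sr.effective_fwhm(optics), rel=0.02)

    def test_uniform_input_stays_uniform_in_interior(self, optics):
        out = sr.blur(np.ones((64, 64)), optics, 20.0)
        interior = out[16:-16, 16:-16]
        assert np.allclose(interior, 1.0, atol=1e-9)

    def test_subpixel_fwhm_warns_and_clamps(self, optics):
        with pytest.warns(UserWarning, match="clamping"):
            sr.blur(np.ones((16, 16)), optics, pixel_size=120.0)


class TestAcquire:
    def test_zero_dwell_gives_zero_counts(self, noiseless_scene):
        acq = sr.AcquisitionModel(dwell_time=0.0, seed=0)
        assert not sr.acquire(noiseless_scene, acq).any()

    def test_poisson_moments(self):
        # 10,000 draws at expectation 5: mean within 5 +- 0.07 (3 sigma),
        # variance/mean within 1 +- 0.05
        grid = np.full((100, 100), 5.0)
        acq = sr.AcquisitionModel(dwell_time=1.0, brightness=1.0,
                                  background=0.0, seed=123)
        counts = sr.acquire(grid, acq)
        assert counts.mean() == pytest.approx(5.0, abs=0.07)
        assert counts.var() / counts.mean() == pytest.approx(1.0, abs=0.05)

    def test_poisson_dispersion_chi2(self):
        # index of dispersion test at n = 10^4, alpha = 0.01
        n = 10_000
        grid = np.full((n,), 5.0).reshape(100, 100)
        counts = sr.acquire(grid, sr.AcquisitionModel(1.0, 1.0, 0.0, seed=7))
        disp = (n - 1) * counts.var(ddof=1) / counts.mean()
        lo, hi = stats.chi2.ppf([0.005, 0.995], df=n - 1)
        assert lo < disp < hi

    def test_mean_scales_linearly_with_dwell(self, noiseless_scene):
        means = []
        for dwell in (0.5, 1.0, 2.0):
            acc = 0.0
            for s in range(20):
                acq = sr.AcquisitionModel(dwell, 60.0, 0.0, seed=s)
                acc += sr.acquire(noiseless_scene, acq).mean()
            means.append(acc / 20)
        assert means[1] / means[0] == pytest.approx(2.0, rel=0.02)
        assert means[2] / means[1] == pytest.approx(2.0, rel=0.02)

    def test_deterministic_under_seed(self, noiseless_scene):
        acq = sr.AcquisitionModel(1.0, 60.0, 0.1, seed=9)
        assert np.array_equal(sr.acquire(noiseless_scene, acq),
                              sr.acquire(noiseless_scene, acq))


class TestSimulatePair:
    def test_exposure_contrast_exceeds_32_fold(self, training_pair):
        # dwell 2.3 vs 0.072 µs reproduces the >32x count contrast
        ratio = training_pair.gt.mean() / training_pair.noisy.mean()
        assert ratio > 32

    def test_identical_seed_identical_pair(self, filament_phantom, optics):
        a = sr.simulate_pair(filament_phantom, optics, seed=2)
        b = sr.simulate_pair(filament_phantom, optics, seed=2)
        assert np.array_equal(a.noisy, b.noisy)
        assert np.array_equal(a.gt, b.gt)

    def test_fast_member_has_lower_psnr(self, training_pair):
        p_fast = sr.psnr(training_pair.expected_fast, training_pair.noisy)
        p_slow = sr.psnr(training_pair.expected_slow, training_pair.gt)
        assert p_fast < p_slow

    def test_requires_fast_below_slow(self, filament_phantom, optics):
        with pytest.raises(ValueError):
            sr.simulate_pair(filament_phantom, optics, dwell_fast=2.3,
                             dwell_slow=0.072)


class TestTimelapse:
    def test_no_bleaching_is_stationary(self, filament_phantom, optics):
        acq = sr.AcquisitionModel(2.3, 60.0, 0.1, seed=3)
        stack = sr.simulate_timelapse(filament_phantom, optics, acq, 12, 0.0)
        means = stack.mean(axis=(1, 2))
        assert means.std() / means.mean() < 0.05

    def test_half_life_matches_closed_form(self, filament_phantom, optics):
        rate, dwell = 0.05, 2.3
        acq = sr.AcquisitionModel(dwell, 60.0, 0.0, seed=4)
        stack = sr.simulate_timelapse(filament_phantom, optics, acq, 30, rate)
        means = stack.mean(axis=(1, 2))
        half = np.interp(0.5, means[::-1] / means[0],
                         np.arange(len(means))[::-1])
        assert half == pytest.approx(np.log(2) / (rate * dwell), rel=0.1)

    def test_fast_dwell_bleaches_slower_per_frame(self, filament_phantom,
                                                  optics):
        rate = 0.05
        slow = sr.simulate_timelapse(
            filament_phantom, optics,
            sr.AcquisitionModel(2.3, 60.0, 0.0, seed=5), 20, rate)
        fast = sr.simulate_timelapse(
            filament_phantom, optics,
            sr.AcquisitionModel(0.072, 60.0, 0.0, seed=6), 20, rate)
        decay_slow = slow.mean(axis=(1, 2))[-1] / slow.mean(axis=(1, 2))[0]
        decay_fast = fast.mean(axis=(1, 2))[-1] / fast.mean(axis=(1, 2))[0]
        assert decay_fast > decay_slow
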