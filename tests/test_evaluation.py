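"""Fidelity metrics, resolution estimators and photobleaching curves."""

import numpy as np
import pytest

import sted_restore as sr

SIGMA_TO_FWHM = 2 * np.sqrt(2 * np.log(2))


class TestPSNR:
    def test_identical_images_capped_sentinel(self, rng):
        img = rng.random((32, 32))
        assert sr.psnr(img, img) >= 100.0

    def test_constant_offset_closed_form(self):
        ref = np.zeros((16, 16))
        ref[0, 0] = 1.0  # data range 1
        test = ref + 0.1
        assert sr.psnr(ref, test, data_range=1.0) == pytest.approx(20.0)

    def test_decreases_with_shorter_dwell(self, noiseless_scene):
        values = []
        for dwell in (2.3, 0.5, 0.072):
            acq = sr.AcquisitionModel(dwell, 60.0, 0.1, seed=2)
            noisy = sr.acquire(noiseless_scene, acq)
            expected = dwell * (60.0 * noiseless_scene + 0.1)
            values.append(sr.psnr(expected, noisy))
        assert values[0] > values[1] > values[2]

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sr.psnr(np.zeros((4, 4)), np.zeros((5, 4)))


class TestNMSE:
    def test_identical_is_zero(self, rng):
        img = rng.random((16, 16))
        assert sr.nmse(img, img) == 0.0

    def test_zero_prediction_is_one(self, rng):
        ref = rng.random((16, 16))
        assert sr.nmse(ref, np.zeros_like(ref)) == pytest.approx(1.0)

    def test_doubled_prediction_is_one(self, rng):
        ref = rng.random((16, 16))
        assert sr.nmse(ref, 2 * ref) == pytest.approx(1.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            sr.nmse(np.zeros((4, 4)), np.ones((4, 4)))


class TestMSSSIM:
    def test_identical_images_score_one(self, rng):
        img = rng.random((192, 192))
        assert sr.ms_ssim(img, img) == pytest.approx(1.0)

    def test_symmetric(self, rng):
        a, b = rng.random((192, 192)), rng.random((192, 192))
        assert sr.ms_ssim(a, b) == pytest.approx(sr.ms_ssim(b, a))

    def test_shared_structure_beats_independent_noise(self, noiseless_scene):
        scene = np.pad(noiseless_scene, 32)  # 192x192
        a = sr.acquire(scene, sr.AcquisitionModel(2.3, 60.0, 0.1, seed=5))
        b = sr.acquire(scene, sr.AcquisitionModel(2.3, 60.0, 0.1, seed=6))
        indep = np.random.default_rng(7).poisson(
            a.mean(), a.shape).astype(float)
        assert sr.ms_ssim(a, b) > sr.ms_ssim(a, indep)

    def test_degrades_with_noise_magnitude(self, noiseless_scene):
        scene = np.pad(noiseless_scene, 32)
        ref = 2.3 * (60.0 * scene + 0.1)
        scores = []
        for dwell in (2.3, 0.2):
            noisy = sr.acquire(scene, sr.AcquisitionModel(dwell, 60.0, 0.1,
                                                          seed=8))
            scores.append(sr.ms_ssim(ref, noisy * 2.3 / dwell))
        assert scores[0] > scores[1]

    def test_too_small_image_rejected_with_minimum(self):
        with pytest.raises(ValueError, match="176"):
            sr.ms_ssim(np.zeros((64, 64)), np.zeros((64, 64)))


class TestFWHM:
    def test_sigma_two_ridge_94nm(self):
        y = np.arange(64)[:, None] * np.ones((1, 64))
        ridge = np.exp(-0.5 * ((y - 32) / 2.0) ** 2)
        fit = sr.fwhm_line_profile(ridge, (10, 20), (54, 20), pixel_size=20.0)
        assert fit.fwhm_nm == pytest.approx(SIGMA_TO_FWHM * 2.0 * 20.0,
                                            rel=0.01)

    def test_translation_invariant_along_profile(self):
        y = np.arange(96)[:, None] * np.ones((1, 96))
        ridge = np.exp(-0.5 * ((y - 48) / 2.5) ** 2)
        a = sr.fwhm_line_profile(ridge, (20, 30), (76, 30), 20.0)
        b = sr.fwhm_line_profile(ridge, (10, 60), (86, 60), 20.0)
        assert a.fwhm_nm == pytest.approx(b.fwhm_nm, rel=1e-6)

    def test_estimator_unbiased_over_sigma_range(self):
        # 50 noiseless profiles across sigma in [1.5, 4] px
        for sigma in np.linspace(1.5, 4.0, 50):
            y = np.arange(96)[:, None] * np.ones((1, 8))
            ridge = np.exp(-0.5 * ((y - 48) / sigma) ** 2)
            fit = sr.fwhm_line_profile(ridge, (20, 4), (76, 4), 20.0)
            expected = SIGMA_TO_FWHM * sigma * 20.0
            assert fit.fwhm_nm == pytest.approx(expected, rel=0.02)

    def test_ten_profile_aggregate_mean_and_sem(self, bead_image):
        peaks = []
        img = bead_image
        for y in range(40, 480, 16):
            row = img[y - 4:y + 4].sum(axis=0)
            x = int(np.argmax(row))
            if 20 < x < 492 and row[x] > 50:
                peaks.append((y, x))
            if len(peaks) == 10:
                break
        lines = [((y, x - 10), (y, x + 10)) for y, x in peaks]
        mean, sem, table = sr.aggregate_fwhm(img, lines, pixel_size=20.0)
        assert len(table) == 10
        assert mean > 0 and np.isfinite(sem)


class TestDecorrelation:
    def test_60nm_high_snr_within_15_percent(self, bead_image):
        est = sr.decorrelation_resolution(bead_image, pixel_size=20.0)
        assert est == pytest.approx(60.0, rel=0.15)

    def test_default_parameters_match_plugin_convention(self):
        import inspect
        sig = inspect.signature(sr.decorrelation_resolution)
        assert sig.parameters["radius_min"].default == 0
        assert sig.parameters["radius_max"].default == 1
        assert sig.parameters["nr"].default == 50
        assert sig.parameters["ng"].default == 10

    def test_monotone_with_sted_power(self):
        phantom = sr.make_phantom("puncta", (512, 512), 20.0, 250, seed=4)
        estimates = []
        for power in (2.0, 5.0, 10.0, 15.0):
            optics = sr.OpticsModel(240.0, power, 1.0)
            scene = sr.blur(sr.render_phantom(phantom), optics, 20.0)
            noisy = sr.acquire(scene, sr.AcquisitionModel(2.3, 800.0, 0.1,
                                                          seed=1))
            estimates.append(sr.decorrelation_resolution(noisy,
                                                         pixel_size=20.0))
        assert all(a > b for a, b in zip(estimates, estimates[1:]))

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            sr.decorrelation_resolution(np.ones((64, 64)))

    def test_agrees_with_fwhm_on_beads(self, bead_image):
        # the two resolution estimators cross-validate within 20%
        est = sr.decorrelation_resolution(bead_image, pixel_size=20.0)
        peaks = []
        for y in range(40, 480, 16):
            row = bead_image[y - 4:y + 4].sum(axis=0)
            x = int(np.argmax(row))
            if 20 < x < 492 and row[x] > 50:
                peaks.append((y, x))
        lines = [((y, x - 10), (y, x + 10)) for y, x in peaks[:10]]
        mean, _, _ = sr.aggregate_fwhm(bead_image, lines, pixel_size=20.0)
        assert est == pytest.approx(mean, rel=0.2)


@pytest.fixture(scope="module")
def phantom_and_optics():
    return (sr.make_phantom("filaments", (64, 64), 20.0, 8, seed=7),
            sr.OpticsModel(240.0, 15.0, 1.0))


class TestBleachCurve:

    def test_stationary_series_stays_near_one(self, phantom_and_optics):
        phantom, optics = phantom_and_optics
        stack = sr.simulate_timelapse(
            phantom, optics, sr.AcquisitionModel(2.3, 60.0, 0.1, seed=3),
            12, bleach_rate=0.0)
        curve = sr.bleach_curve(stack)
        assert curve.trace.min() > 0.9

    def test_half_frame_matches_closed_form(self, phantom_and_optics):
        phantom, optics = phantom_and_optics
        rate, dwell = 0.035, 2.3
        stack = sr.simulate_timelapse(
            phantom, optics, sr.AcquisitionModel(dwell, 60.0, 0.1, seed=1),
            40, rate)
        curve = sr.bleach_curve(stack)
        assert curve.half_frame == pytest.approx(np.log(2) / (rate * dwell),
                                                 rel=0.1)

    def test_norm_vector_anchored_at_one(self, phantom_and_optics):
        phantom, optics = phantom_and_optics
        stack = sr.simulate_timelapse(
            phantom, optics, sr.AcquisitionModel(2.3, 60.0, 0.1, seed=2),
            10, 0.05)
        curve = sr.bleach_curve(stack)
        assert curve.norm_vector.max() == pytest.approx(1.0)
        assert curve.trace.max() == pytest.approx(1.0)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            sr.bleach_curve(np.ones((1, 8, 8)))

    def test_prediction_rescaling_restores_decay(self, phantom_and_optics):
        phantom, optics = phantom_and_optics
        rate, dwell = 0.035, 2.3
        stack = sr.simulate_timelapse(
            phantom, optics, sr.AcquisitionModel(dwell, 60.0, 0.1, seed=4),
            40, rate)
        # a perfectly denoised (constant-brightness) prediction stand-in
        prediction = np.stack([stack.mean(axis=0)] * 40)
        curve = sr.bleach_curve(stack, prediction)
        assert curve.half_frame == pytest.approx(np.log(2) / (rate * dwell),
                                                 rel=0.15)


class TestMetricsReport:
    def test_report_aggregates_mean_and_sd(self, noiseless_scene):
        scene = np.pad(noiseless_scene, 32)
        refs, tests = [], []
        for s in range(3):
            refs.append(2.3 * (60.0 * scene + 0.1))
            tests.append(sr.acquire(scene, sr.AcquisitionModel(2.3, 60.0, 0.1,
                                                               seed=s)))
        report = sr.MetricsReport.from_pairs(refs, tests)
        agg = report.aggregate()
        assert set(report.table.columns) >= {"psnr_db", "nmse", "ms_ssim"}
        assert agg.loc["ms_ssim", "mean"] <= 1.0
        assert agg.loc["nmse", "sd"] >= 0.0

    def test_error_map_absolute_and_signed(self, rng):
        a, b = rng.random((8, 8)), rng.random((8, 8))
        assert (sr.error_map(a, b) >= 0).all()
        assert np.allclose(sr.error_map(a, b, signed=True), a - b)
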