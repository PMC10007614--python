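"""Preprocessing chain: crop, flagging, trimming, smoothing, folding."""

import numpy as np
import pytest
from dataclasses import replace
from scipy.signal import savgol_filter

from sorsnet import (PreprocessConfig, SimulationConfig, generate_dataset,
                     generate_reference_spectra, simulate_sample,
                     to_raman_shift)
from sorsnet.errors import ConfigError, InputError, ROIError
from sorsnet.preprocess import (band_average, crop_roi, detect_typical_peaks,
                                fold_offsets, preprocess_pipeline,
                                remove_anomalous_spectra, remove_cosmic_rays,
                                average_and_smooth)
from sorsnet.simulate import ScatterCube, noiseless_signal


class TestRamanShift:
    @pytest.mark.parametrize("wavelength, expected", [
        (785.0, 0.0),             # the excitation line itself
        (823.83, 600.43),         # red edge of the band of interest
        (914.30, 1801.52),        # blue edge
    ])
    def test_stokes_conversion(self, wavelength, expected):
        got = to_raman_shift(np.array([wavelength]), 785.0)[0]
        assert got == pytest.approx(expected, abs=0.01)

    def test_monotone_order_preserved(self):
        lam = np.linspace(800, 900, 50)
        shift = to_raman_shift(lam, 785.0)
        assert np.all(np.diff(shift) > 0)

    def test_nonpositive_wavelength_rejected(self):
        with pytest.raises(InputError):
            to_raman_shift(np.array([-1.0]), 785.0)


class TestCropRoi:
    def test_default_geometry_51_columns(self, small_dataset,
                                         preprocess_config):
        roi = crop_roi(small_dataset.cube(0), preprocess_config)
        assert roi.data.shape[1] == 51          # 25 px each side + center
        assert roi.pixel_pitch_mm == pytest.approx(0.2)
        assert roi.laser_column == 25

    def test_band_crop_limits(self, small_dataset, preprocess_config):
        roi = crop_roi(small_dataset.cube(0), preprocess_config)
        assert roi.shift_axis.min() >= 600.0 - 1e-3
        assert roi.shift_axis.max() <= 1800.0 + 1e-3

    def test_zero_halfwidth_single_column(self, small_dataset):
        cfg = PreprocessConfig(roi_halfwidth_mm=0.0)
        roi = crop_roi(small_dataset.cube(0), cfg)
        assert roi.data.shape[1] == 1

    def test_laser_near_edge_raises(self, small_config, preprocess_config):
        cube = simulate_sample(0, 1, small_config, np.random.default_rng(0))
        cube.laser_index = 3
        with pytest.raises(ROIError):
            crop_roi(cube, preprocess_config)


class TestPeakDetection:
    def test_constant_spectrum_no_peaks(self, preprocess_config):
        axis = np.linspace(600, 1800, 500)
        found = detect_typical_peaks(np.ones(500), axis, preprocess_config)
        assert found.size == 0

    def test_single_gaussian_found_once(self, preprocess_config):
        axis = np.linspace(600, 1800, 1000)
        spec = np.exp(-0.5 * ((axis - 1003.0) / 12.0) ** 2)
        found = detect_typical_peaks(spec, axis, preprocess_config)
        assert found.size == 1
        assert found[0] == pytest.approx(1003.0, abs=2.0)


class TestAnomalyRemoval:
    def test_clean_cube_keeps_all_positions(self, clean_config,
                                            meat_reference,
                                            preprocess_config):
        cube = simulate_sample(0, 1, clean_config, np.random.default_rng(1))
        roi = crop_roi(cube, preprocess_config)
        roi = remove_anomalous_spectra(roi, meat_reference, preprocess_config)
        assert roi.removed_columns.size == 0

    def test_seeded_anomalies_are_flagged_exactly(self, clean_config,
                                                  meat_reference,
                                                  preprocess_config):
        cfg = replace(clean_config, anomaly_rate=0.1, seed=11)
        cube = simulate_sample(0, 2, cfg, np.random.default_rng(2))
        roi = crop_roi(cube, preprocess_config)
        lo = cube.laser_index - 25
        truth = sorted(p - lo for p in cube.anomaly_positions
                       if 0 <= p - lo <= 50)
        roi = remove_anomalous_spectra(roi, meat_reference, preprocess_config)
        assert sorted(roi.removed_columns) == truth
        assert len(truth) > 0

    def test_all_positions_anomalous_rejects_sample(self, clean_config,
                                                    meat_reference,
                                                    preprocess_config):
        from sorsnet.errors import SampleRejectionError
        from sorsnet.simulate import shell_spectrum
        cube = simulate_sample(0, 1, clean_config, np.random.default_rng(3))
        # every pixel replaced by a featureless shell spectrum
        cube.data[:] = shell_spectrum(clean_config)[None, None, :]
        roi = crop_roi(cube, preprocess_config)
        with pytest.raises(SampleRejectionError):
            remove_anomalous_spectra(roi, meat_reference, preprocess_config)

    def test_zero_required_matches_removes_nothing(self, small_dataset,
                                                   meat_reference):
        cfg = PreprocessConfig(min_peaks_matched=0)
        roi = crop_roi(small_dataset.cube(1), cfg)
        roi = remove_anomalous_spectra(roi, meat_reference, cfg)
        assert roi.removed_columns.size == 0

    def test_flagging_precision_and_recall(self, preprocess_config):
        """>= 0.95 precision and recall against generator ground truth."""
        tp = fp = fn = 0
        for seed in (0, 1):
            cfg = SimulationConfig(n_shrimp=4, seed=seed)
            ds = generate_dataset(cfg)
            meat, _ = generate_reference_spectra(cfg)
            for i in range(len(ds)):
                cube = ds.cube(i)
                roi = crop_roi(cube, preprocess_config)
                lo = cube.laser_index - 25
                truth = set(int(p - lo) for p in cube.anomaly_positions
                            if 0 <= p - lo <= 50)
                roi = remove_anomalous_spectra(roi, meat,
                                               preprocess_config)
                flagged = set(int(c) for c in roi.removed_columns)
                tp += len(truth & flagged)
                fp += len(flagged - truth)
                fn += len(truth - flagged)
        assert tp / (tp + fp) >= 0.95
        assert tp / (tp + fn) >= 0.95


class TestCosmicRayTrimming:
    def test_spike_removed_by_trimming(self):
        cell = np.array([1.0, 1.0, 1.0, 1.0, 100.0]).reshape(5, 1, 1)
        assert remove_cosmic_rays(cell).mean() == pytest.approx(1.0)

    def test_constant_repeats_unchanged(self):
        cell = np.full((4, 1, 1), 5.0)
        assert remove_cosmic_rays(cell).mean() == pytest.approx(5.0)

    def test_matches_sort_drop_average_oracle(self, rng):
        data = rng.normal(size=(10, 3, 7))
        trimmed = remove_cosmic_rays(data).mean(axis=0)
        oracle = np.empty((3, 7))
        for i in range(3):
            for j in range(7):
                vals = np.sort(data[:, i, j])
                oracle[i, j] = vals[1:-1].mean()
        np.testing.assert_allclose(trimmed, oracle)

    def test_too_few_repeats_rejected(self):
        with pytest.raises(InputError):
            remove_cosmic_rays(np.ones((2, 1, 1)))


class TestSmoothing:
    def test_cubic_polynomial_reproduced(self):
        x = np.linspace(0, 1, 100)
        spec = 1 + x - 2 * x ** 2 + 0.5 * x ** 3
        data = np.tile(spec, (4, 2, 1))
        out = average_and_smooth(data, PreprocessConfig())
        np.testing.assert_allclose(out, np.tile(spec, (2, 1)), atol=1e-10)

    def test_noise_variance_reduced(self, rng):
        x = np.linspace(0, 4 * np.pi, 500)
        clean = np.sin(x)
        noisy = clean + rng.normal(0, 0.2, size=500)
        out = average_and_smooth(noisy.reshape(1, 1, -1), PreprocessConfig())
        assert np.var(out[0] - clean) < np.var(noisy - clean)

    def test_window_larger_than_bands_rejected(self):
        with pytest.raises(ConfigError):
            average_and_smooth(np.ones((3, 1, 5)), PreprocessConfig())


class TestBandAverage:
    def test_block_means(self):
        image = np.arange(1.0, 11.0).reshape(1, 10)
        centers = np.arange(10.0)
        out, c = band_average(image, centers, 2)
        np.testing.assert_allclose(out, [[3.0, 8.0]])
        np.testing.assert_allclose(c, [2.0, 7.0])

    def test_constant_image_unchanged(self):
        out, _ = band_average(np.full((3, 1000), 2.5),
                              np.linspace(600, 1800, 1000), 200)
        assert out.shape == (3, 200)
        np.testing.assert_allclose(out, 2.5)

    def test_non_divisible_rejected(self):
        with pytest.raises(ConfigError):
            band_average(np.ones((1, 998)), np.arange(998.0), 200)


class TestFolding:
    def test_mirror_symmetric_image_folds_to_binned_half(self):
        bands = 4
        dist = np.abs(np.arange(51) - 25)[:, None]  # symmetric about laser
        image = (dist * np.arange(1, bands + 1)[None, :]).astype(float)
        matrix, offsets = fold_offsets(image, 25, 0.2, 11, 5.0)
        assert matrix.shape == (bands, 11)
        np.testing.assert_allclose(offsets, np.arange(11) * 0.5)
        # folding a symmetric image = binning the right half directly
        expected = np.zeros((bands, 11))
        counts = np.zeros(11)
        for d in range(26):
            k = min(int(d * 0.2 / 0.5), 10)
            expected[:, k] += image[25 + d]
            counts[k] += 1
        np.testing.assert_allclose(matrix, expected / counts)

    def test_opposite_columns_average(self):
        image = np.zeros((3, 2))
        image[0] = 0.0   # left at d = 0.2 mm... laser center row 1
        image[2] = 2.0
        matrix, _ = fold_offsets(image, 1, 0.2, 2, 0.2)
        # bin containing d=0.2 holds the average of columns 0 and 2
        assert matrix[0, 1] == pytest.approx(1.0)

    def test_51_columns_yield_11_offsets(self):
        image = np.random.default_rng(0).random((51, 8))
        matrix, offsets = fold_offsets(image, 25, 0.2, 11, 5.0)
        assert matrix.shape == (8, 11)
        np.testing.assert_allclose(offsets, np.arange(11) * 0.5)

    def test_even_column_count_rejected(self):
        with pytest.raises(InputError):
            fold_offsets(np.ones((50, 3)), 25, 0.2, 11, 5.0)

    def test_removed_column_partner_used_alone(self):
        image = np.zeros((5, 1))
        image[0] = 4.0
        image[4] = 2.0
        # without removal the outermost bin averages to 3; removing the
        # left column leaves the right partner alone
        m_all, _ = fold_offsets(image, 2, 0.5, 2, 1.0)
        m_rm, _ = fold_offsets(image, 2, 0.5, 2, 1.0,
                               removed_columns=np.array([0]))
        assert m_all[0, 1] == pytest.approx(3.0)
        assert m_rm[0, 1] == pytest.approx(2.0)


class TestPipeline:
    def test_default_output_is_200_by_11(self, small_dataset, meat_reference,
                                         preprocess_config):
        s = preprocess_pipeline(small_dataset.cube(0), meat_reference,
                                preprocess_config)
        assert s.matrix.shape == (200, 11)
        assert np.all(np.isfinite(s.matrix))
        assert np.all(s.matrix >= 0)
        assert s.band_centers.size == 200
        assert np.all(np.diff(s.band_centers) > 0)

    def test_noiseless_sample_matches_closed_form(self, clean_config,
                                                  meat_reference,
                                                  preprocess_config):
        """Pipeline output equals the folded closed-form signal."""
        cube = simulate_sample(0, 4, clean_config, np.random.default_rng(5))
        got = preprocess_pipeline(cube, meat_reference, preprocess_config)

        # independent path: closed-form spectra at the 51 ROI offsets,
        # SG-smoothed, block-averaged, mirror-folded, distance-binned
        offs = (np.arange(51) - 25) * 0.2
        sig = noiseless_signal(clean_config, 4, offs)        # 51 x 1000
        sig = savgol_filter(sig, 11, 3, axis=-1)
        sig = sig.reshape(51, 200, 5).mean(axis=-1)
        expected = np.zeros((200, 11))
        counts = np.zeros(11)
        for d in range(26):
            cols = [25] if d == 0 else [25 - d, 25 + d]
            folded = np.mean([sig[c] for c in cols], axis=0)
            k = min(int(d * 0.2 / 0.5), 10)
            expected[:, k] += folded
            counts[k] += 1
        expected /= counts
        np.testing.assert_allclose(got.matrix, expected, rtol=1e-10)

    def test_mirror_equivariance(self, clean_config, meat_reference,
                                 preprocess_config):
        """Spatially flipping the cube about the laser leaves output fixed."""
        cube = simulate_sample(0, 2, clean_config, np.random.default_rng(9))
        a = preprocess_pipeline(cube, meat_reference, preprocess_config)
        li = cube.laser_index
        flipped = cube.data.copy()
        lo, hi = li - 25, li + 25
        flipped[:, lo:hi + 1, :] = flipped[:, lo:hi + 1, :][:, ::-1, :]
        mirrored = ScatterCube(data=flipped,
                               wavelength_axis=cube.wavelength_axis,
                               laser_index=li, shrimp_id=0, day=2)
        b = preprocess_pipeline(mirrored, meat_reference, preprocess_config)
        np.testing.assert_allclose(a.matrix, b.matrix)

    def test_single_spike_changes_output_below_noise_floor(
            self, clean_config, meat_reference, preprocess_config):
        cube = simulate_sample(0, 3, clean_config, np.random.default_rng(4))
        base = preprocess_pipeline(cube, meat_reference, preprocess_config)
        spiked = cube.data.copy()
        rng = np.random.default_rng(8)
        for r in range(spiked.shape[0]):   # one spike per repeat
            px = rng.integers(cube.laser_index - 25, cube.laser_index + 26)
            spiked[r, px, rng.integers(0, spiked.shape[2])] += 30.0
        cube2 = ScatterCube(data=spiked,
                            wavelength_axis=cube.wavelength_axis,
                            laser_index=cube.laser_index, shrimp_id=0, day=3)
        out = preprocess_pipeline(cube2, meat_reference, preprocess_config)
        assert np.max(np.abs(out.matrix - base.matrix)) < 0.05

    def test_roi_crop_idempotent(self, small_dataset, preprocess_config):
        roi1 = crop_roi(small_dataset.cube(0), preprocess_config)
        # re-crop the already-cropped cube (wavelengths rebuilt from the
        # retained shift axis); nothing further should be removed
        lam = 1e7 / (1e7 / 785.0 - roi1.shift_axis)
        cube_like = ScatterCube(
            data=roi1.data, wavelength_axis=lam,
            laser_index=roi1.laser_column, shrimp_id=0, day=1)
        roi2 = crop_roi(cube_like, preprocess_config,
                        window_mm=roi1.pixel_pitch_mm * roi1.data.shape[1])
        np.testing.assert_array_equal(roi1.data, roi2.data)
        np.testing.assert_allclose(roi1.shift_axis, roi2.shift_axis)
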