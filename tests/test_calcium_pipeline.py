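import numpy as np
import pytest
from scipy import signal

from activecomm import generate_movie
from activecomm.calcium_pipeline import (BrainMask, DffMovie,
                                         DualChannelMovie,
                                         PreprocessingPipeline, average_masks,
                                         compute_dff, pair_channels,
                                         read_dff_h5, read_movie_h5,
                                         read_movie_tiff,
                                         rigid_motion_correct,
                                         segregate_channels, spatial_bin,
                                         spatial_smooth, temporal_bandpass,
                                         write_dff_h5, write_movie_h5,
                                         write_movie_tiff, zscore_pixels)
from activecomm.errors import (BaselineError, ParameterError,
                               PipelineOrderError, SeparabilityError)


@pytest.fixture(scope="module")
def clean_movie():
    return generate_movie((300, 32, 32), hemo_amp=0.03, outlier_frac=0.0,
                          max_shift_px=0, seed=10)


class TestSegregation:
    def test_perfect_labels_on_clean_movie(self, clean_movie):
        movie, truth = clean_movie
        labels = segregate_channels(movie)
        assert np.array_equal(labels, truth.labels)

    def test_led_dropout_flagged_as_outlier(self):
        movie, truth = generate_movie((200, 16, 16), outlier_frac=0.0, seed=1)
        frames = movie.frames.copy()
        frames[50] = 0           # LED dropout
        labels = segregate_channels(DualChannelMovie(frames, 30.0))
        assert labels[50] == "outlier"
        keep = np.arange(200) != 50
        assert np.array_equal(labels[keep], truth.labels[keep])

    def test_injected_outliers_all_caught(self):
        movie, truth = generate_movie((500, 16, 16), outlier_frac=0.01, seed=2)
        labels = segregate_channels(movie)
        assert np.array_equal(np.flatnonzero(labels == "outlier"),
                              truth.outlier_frames)

    def test_constant_movie_not_separable(self):
        frames = np.full((50, 8, 8), 100, dtype=np.uint16)
        with pytest.raises(SeparabilityError):
            segregate_channels(DualChannelMovie(frames, 30.0))

    def test_clean_movie_has_zero_outliers(self, clean_movie):
        movie, _ = clean_movie
        labels = segregate_channels(movie)
        assert np.sum(labels == "outlier") == 0

    def test_pairing_drops_outliers_from_both_channels(self):
        movie, truth = generate_movie((300, 16, 16), outlier_frac=0.01, seed=3)
        segregate_channels(movie)
        blue, green, blue_idx = pair_channels(movie)
        assert len(blue) == len(green)
        assert not np.isin(blue_idx, truth.outlier_frames).any()


class TestMotionCorrection:
    def test_planted_integer_shifts_recovered_exactly(self):
        movie, truth = generate_movie((400, 64, 64), hemo_amp=0.0,
                                      outlier_frac=0.0, max_shift_px=3,
                                      seed=4)
        blue = movie.frames[::2].astype(float)
        corrected, shifts = rigid_motion_correct(blue, template=blue[0])
        np.testing.assert_array_equal(shifts.dxy, truth.shifts[::2])

    def test_aligned_stack_untouched(self, clean_movie):
        movie, _ = clean_movie
        blue = movie.frames[::2].astype(float)
        corrected, shifts = rigid_motion_correct(blue)
        assert np.all(shifts.dxy == 0)
        np.testing.assert_array_equal(corrected, blue)

    def test_constant_stack_zero_shifts(self):
        stack = np.full((5, 16, 16), 7.0)
        _, shifts = rigid_motion_correct(stack)
        assert np.all(shifts.dxy == 0)

    def test_all_zero_frame_warns_and_zero_shift(self, caplog):
        stack = np.random.default_rng(0).uniform(1, 2, (4, 16, 16))
        stack[2] = 0.0
        with caplog.at_level("WARNING"):
            _, shifts = rigid_motion_correct(stack)
        assert tuple(shifts.dxy[2]) == (0.0, 0.0)

    def test_shift_trace_micron_conversion(self):
        from activecomm.calcium_pipeline import ShiftTrace
        tr = ShiftTrace(np.array([[1.0, -2.0]]))
        np.testing.assert_allclose(tr.to_um(5.5), [[5.5, -11.0]])


class TestSpatialBin:
    def test_constant_frame_stays_constant(self):
        out = spatial_bin(np.full((10, 10), 3.5), 0.8)
        assert out.shape == (8, 8)
        np.testing.assert_allclose(out, 3.5)

    def test_fraction_one_is_identity(self):
        frame = np.random.default_rng(0).uniform(size=(12, 12))
        np.testing.assert_array_equal(spatial_bin(frame, 1.0), frame)

    def test_checkerboard_mean_preserved(self):
        frame = np.indices((10, 10)).sum(axis=0) % 2 * 1.0
        out = spatial_bin(frame, 0.8)
        assert abs(out.mean() - frame.mean()) / frame.mean() < 0.005

    def test_stack_mean_preserved(self):
        stack = np.random.default_rng(1).uniform(10, 20, (5, 25, 33))
        out = spatial_bin(stack, 0.8)
        assert out.shape == (5, 20, 26)
        np.testing.assert_allclose(out.mean(axis=(1, 2)),
                                   stack.mean(axis=(1, 2)), rtol=1e-12)


class TestMasks:
    def test_identical_masks_unchanged(self):
        m = np.zeros((4, 4), dtype=bool)
        m[1:3, 1:3] = True
        avg = average_masks([m, m, m])
        np.testing.assert_array_equal(avg.mask, m)
        assert avg.provenance == "averaged"

    def test_majority_vote(self):
        a = np.zeros((2, 2), dtype=bool); a[0, 0] = True
        b = np.zeros((2, 2), dtype=bool); b[0, 0] = True
        c = np.zeros((2, 2), dtype=bool); c[1, 1] = True
        avg = average_masks([a, b, c], vote=0.5)
        assert avg.mask[0, 0] and not avg.mask[1, 1]

    def test_vote_one_is_intersection(self):
        a = np.ones((3, 3), dtype=bool)
        b = np.zeros((3, 3), dtype=bool); b[0] = True
        avg = average_masks([a, b], vote=1.0)
        np.testing.assert_array_equal(avg.mask, a & b)

    def test_shape_mismatch(self):
        with pytest.raises(ParameterError):
            average_masks([np.ones((2, 2), bool), np.ones((3, 3), bool)])


class TestDff:
    def test_constant_channels_give_zero(self):
        blue = np.full((20, 8, 8), 150.0)
        green = np.full((20, 8, 8), 60.0)
        mask = BrainMask(np.ones((8, 8), bool))
        unc, corr = compute_dff(blue, green, mask)
        np.testing.assert_allclose(unc.data, 0.0, atol=1e-12)
        np.testing.assert_allclose(corr.data, 0.0, atol=1e-12)

    def test_green_constant_means_no_correction(self):
        rng = np.random.default_rng(2)
        blue = rng.uniform(100, 200, (30, 8, 8))
        green = np.full((30, 8, 8), 60.0)
        mask = BrainMask(np.ones((8, 8), bool))
        unc, corr = compute_dff(blue, green, mask)
        np.testing.assert_allclose(corr.data, unc.data, atol=1e-12)

    def test_correction_removes_shared_hemodynamics(self, clean_movie):
        movie, truth = clean_movie
        segregate_channels(movie)
        blue, green, bidx = pair_channels(movie)
        mask = BrainMask(truth.mask)
        unc, corr = compute_dff(blue, green, mask)
        roi = (truth.footprints[0] > 0.3) & truth.mask
        gt = truth.roi_truth_trace(roi)[bidx // 2]
        r_unc = np.corrcoef(unc.data[:, roi].mean(axis=1), gt)[0, 1]
        r_corr = np.corrcoef(corr.data[:, roi].mean(axis=1), gt)[0, 1]
        assert r_corr > r_unc

    def test_regression_variant_also_helps(self, clean_movie):
        movie, truth = clean_movie
        segregate_channels(movie)
        blue, green, bidx = pair_channels(movie)
        mask = BrainMask(truth.mask)
        unc, corr = compute_dff(blue, green, mask, method="regression")
        roi = (truth.footprints[0] > 0.3) & truth.mask
        gt = truth.roi_truth_trace(roi)[bidx // 2]
        assert np.corrcoef(corr.data[:, roi].mean(axis=1), gt)[0, 1] > \
            np.corrcoef(unc.data[:, roi].mean(axis=1), gt)[0, 1]

    def test_nonpositive_baseline_rejected(self):
        blue = np.zeros((10, 4, 4))
        green = np.full((10, 4, 4), 60.0)
        with pytest.raises(BaselineError):
            compute_dff(blue, green, BrainMask(np.ones((4, 4), bool)))

    def test_out_of_mask_pixels_zero(self):
        rng = np.random.default_rng(3)
        blue = rng.uniform(100, 200, (10, 4, 4))
        green = rng.uniform(50, 70, (10, 4, 4))
        m = np.zeros((4, 4), bool); m[:2] = True
        _, corr = compute_dff(blue, green, BrainMask(m))
        assert np.all(corr.data[:, ~m] == 0.0)


class TestBandpass:
    def test_dc_rejected(self):
        dff = DffMovie(np.full((300, 2, 2), 5.0), fps_channel=15.0)
        out = temporal_bandpass(dff)
        assert np.abs(out.data).max() < 1e-6 * 5.0

    def test_passband_gain_at_1hz(self):
        t = np.arange(0, 240, 1 / 15)
        x = np.sin(2 * np.pi * 1.0 * t)
        dff = DffMovie(x[:, None, None] * np.ones((1, 1)), fps_channel=15.0)
        out = temporal_bandpass(dff).data[:, 0, 0]
        core = slice(600, -600)        # clear of filtfilt edge transients
        design = np.column_stack([np.sin(2 * np.pi * t[core]),
                                  np.cos(2 * np.pi * t[core])])
        coef, *_ = np.linalg.lstsq(design, out[core], rcond=None)
        amp = float(np.hypot(*coef))
        assert 0.9 <= amp <= 1.0

    def test_zero_phase_no_lag(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(1200)
        sos = signal.cheby1(3, 0.5, [0.5, 3], btype="bandpass", fs=15,
                            output="sos")
        inband = signal.sosfiltfilt(sos, x)    # in-band input
        dff = DffMovie(inband[:, None, None] * np.ones((1, 1)), 15.0)
        out = temporal_bandpass(dff).data[:, 0, 0]
        xc = np.correlate(out - out.mean(), inband - inband.mean(), "full")
        lag = int(np.argmax(xc)) - (len(inband) - 1)
        assert lag == 0

    def test_fps_too_low_rejected(self):
        dff = DffMovie(np.zeros((50, 2, 2)), fps_channel=8.0)
        with pytest.raises(ParameterError):
            temporal_bandpass(dff, high_hz=5.0)


class TestSpatialSmooth:
    def test_constant_frame_unchanged(self):
        m = BrainMask(np.ones((20, 20), bool))
        dff = DffMovie(np.full((3, 20, 20), 2.5), 15.0)
        out = spatial_smooth(dff, m, 7)
        np.testing.assert_allclose(out.data, 2.5)

    def test_impulse_spreads_over_49_pixels(self):
        m = BrainMask(np.ones((25, 25), bool))
        data = np.zeros((1, 25, 25)); data[0, 12, 12] = 1.0
        out = spatial_smooth(DffMovie(data, 15.0), m, 7).data[0]
        window = out[9:16, 9:16]
        np.testing.assert_allclose(window, 1 / 49, atol=1e-12)
        assert out.sum() == pytest.approx(1.0)

    def test_masked_neighbours_excluded(self):
        m = np.ones((9, 9), bool)
        m[:, 5:] = False                      # mask edge at column 4
        data = np.ones((1, 9, 9))
        data[0, :, :] *= np.arange(9)[None, :]  # value = column index
        out = spatial_smooth(DffMovie(data, 15.0), BrainMask(m), 3).data[0]
        # at column 4 the window spans columns 3..5 but 5 is masked out
        assert out[4, 4] == pytest.approx((3 + 4) / 2)

    def test_even_size_rejected(self):
        with pytest.raises(ParameterError):
            spatial_smooth(DffMovie(np.zeros((1, 4, 4)), 15.0),
                           BrainMask(np.ones((4, 4), bool)), 4)


class TestZscore:
    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(5)
        dff = DffMovie(rng.uniform(1, 3, (200, 6, 6)), 15.0)
        m = BrainMask(np.ones((6, 6), bool))
        out = zscore_pixels(dff, m).data
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-6)
        np.testing.assert_allclose(out.std(axis=0), 1.0, atol=1e-6)

    def test_affine_invariance(self):
        rng = np.random.default_rng(6)
        base = rng.standard_normal((100, 3, 3))
        m = BrainMask(np.ones((3, 3), bool))
        a = zscore_pixels(DffMovie(base, 15.0), m).data
        b = zscore_pixels(DffMovie(3.0 * base + 7.0, 15.0), m).data
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_three_sample_closed_form_population_sd(self):
        data = np.array([1.0, 2.0, 3.0])[:, None, None]
        m = BrainMask(np.ones((1, 1), bool))
        out = zscore_pixels(DffMovie(data, 15.0), m).data[:, 0, 0]
        expected = (data[:, 0, 0] - 2.0) / np.sqrt(2.0 / 3.0)
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_zero_variance_pixel_zeroed(self):
        data = np.random.default_rng(7).standard_normal((50, 2, 2))
        data[:, 0, 0] = 4.2
        m = BrainMask(np.ones((2, 2), bool))
        out = zscore_pixels(DffMovie(data, 15.0), m).data
        assert np.all(out[:, 0, 0] == 0.0)


class TestPipelineRunner:
    def test_out_of_order_stage_rejected(self):
        pipe = PreprocessingPipeline()
        with pytest.raises(PipelineOrderError):
            pipe.apply("bandpass", DffMovie(np.zeros((50, 2, 2)), 15.0))

    def test_full_run_produces_zscored_output(self, clean_movie):
        movie, truth = clean_movie
        movie = DualChannelMovie(movie.frames.copy(), movie.fps_total)
        pipe = PreprocessingPipeline()
        dff, qc = pipe.run(movie, masks=[truth.mask])
        m = qc["mask"].mask
        inmask = dff.data[:, m]
        np.testing.assert_allclose(inmask.mean(axis=0), 0.0, atol=1e-6)
        sds = inmask.std(axis=0)
        assert np.all((np.abs(sds - 1.0) < 1e-6) | (sds == 0.0))
        assert qc["n_outliers"] == 0
        assert dff.fps_channel == 15.0


class TestMovieIO:
    def test_h5_round_trip(self, tmp_path, clean_movie):
        movie, _ = clean_movie
        path = tmp_path / "m.h5"
        write_movie_h5(movie, path)
        back = read_movie_h5(path)
        np.testing.assert_array_equal(back.frames, movie.frames)
        assert back.fps_total == movie.fps_total

    def test_tiff_round_trip(self, tmp_path, clean_movie):
        movie, _ = clean_movie
        path = tmp_path / "m.tif"
        write_movie_tiff(movie, path)
        back = read_movie_tiff(path, fps_total=movie.fps_total)
        np.testing.assert_array_equal(back.frames, movie.frames)

    def test_dff_round_trip(self, tmp_path):
        dff = DffMovie(np.random.default_rng(0).standard_normal(
            (10, 4, 4)).astype(np.float32), 15.0)
        path = tmp_path / "d.h5"
        write_dff_h5(dff, path)
        back = read_dff_h5(path)
        np.testing.assert_allclose(back.data, dff.data, atol=1e-7)
        assert back.fps_channel == 15.0
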