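"""Kymograph construction, peak tracking, oscillation FFT and image spectra."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fp_photodyn import kymograph as ky
from fp_photodyn.er_dynamics import MovieStack


def flood_fill_components(mask):
    """Brute-force 8-connected labelling (independent of skimage)."""
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            if mask[i, j] and labels[i, j] == 0:
                current += 1
                stack = [(i, j)]
                while stack:
                    y, x = stack.pop()
                    if not (0 <= y < mask.shape[0] and 0 <= x < mask.shape[1]):
                        continue
                    if not mask[y, x] or labels[y, x]:
                        continue
                    labels[y, x] = current
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            stack.append((y + dy, x + dx))
    return labels, current


class TestRemoveSmallComponents:
    def blob(self, n):
        m = np.zeros((10, 10), dtype=bool)
        m.flat[:n] = True  # first rows, 8-connected single blob
        return m

    def test_nineteen_pixel_blob_removed_at_threshold_20(self):
        assert not ky.remove_small_components(self.blob(19), 20).any()

    def test_twenty_pixel_blob_kept(self):
        m = self.blob(20)
        np.testing.assert_array_equal(ky.remove_small_components(m, 20), m)

    def test_matches_flood_fill_oracle_on_random_field(self):
        rng = np.random.default_rng(42)
        mask = rng.random((48, 48)) > 0.7
        got = ky.remove_small_components(mask, 8)
        labels, n = flood_fill_components(mask)
        expected = np.zeros_like(mask)
        for lab in range(1, n + 1):
            sel = labels == lab
            if sel.sum() >= 8:
                expected |= sel
        np.testing.assert_array_equal(got, expected)

    def test_idempotent_and_monotone_in_min_area(self):
        rng = np.random.default_rng(1)
        mask = rng.random((40, 40)) > 0.72
        once = ky.remove_small_components(mask, 10)
        np.testing.assert_array_equal(ky.remove_small_components(once, 10), once)
        stricter = ky.remove_small_components(mask, 25)
        assert not (stricter & ~once).any()  # larger threshold removes a superset


class TestMaskedCrop:
    def test_full_mask_is_identity(self):
        img = np.arange(12, dtype=np.uint16).reshape(3, 4)
        np.testing.assert_array_equal(ky.masked_crop(img, np.ones_like(img, bool)), img)

    def test_empty_mask_zeroes_everything(self):
        img = np.arange(12, dtype=np.uint16).reshape(3, 4)
        out = ky.masked_crop(img, np.zeros_like(img, bool))
        assert out.dtype == np.uint16 and not out.any()

    def test_checkerboard_matches_elementwise_product(self):
        img = np.arange(64, dtype=np.uint16).reshape(8, 8)
        mask = (np.indices((8, 8)).sum(axis=0) % 2).astype(bool)
        np.testing.assert_array_equal(ky.masked_crop(img, mask), img * mask)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ky.masked_crop(np.zeros((4, 4)), np.zeros((4, 5), bool))


class TestPerpendicularProfile:
    def test_uniform_image_flat_profile(self):
        axis = ky.AxisSpec(p1=(10, 20), p2=(30, 20), profile_halflength=8)
        prof = ky.perpendicular_profile(np.full((40, 40), 3.0), axis)
        np.testing.assert_allclose(prof, 3.0)

    def test_distance_function_image_reproduced(self):
        # image depends only on signed distance from the horizontal axis line
        h, w = 64, 64
        y = np.arange(h, dtype=float)
        img = np.tile((y - 32.0)[:, None], (1, w))
        axis = ky.AxisSpec(p1=(10, 32), p2=(50, 32), profile_halflength=10, sample_spacing=0.5)
        prof = ky.perpendicular_profile(img, axis)
        np.testing.assert_allclose(prof, axis.positions, atol=1e-9)

    def test_gaussian_ridge_peak_at_known_offset(self):
        h, w = 64, 64
        d_true = 4.0
        yy = np.arange(h, dtype=float)[:, None]
        img = np.exp(-((yy - (32.0 + d_true)) ** 2) / (2 * 2.0**2)) * np.ones((h, w))
        axis = ky.AxisSpec(p1=(20, 32), p2=(44, 32), profile_halflength=10, sample_spacing=0.5)
        prof = ky.perpendicular_profile(img, axis)
        peak_pos = axis.positions[np.argmax(prof)]
        assert abs(peak_pos - d_true) <= axis.sample_spacing

    def test_out_of_bounds_samples_clipped_with_warning(self):
        axis = ky.AxisSpec(p1=(2, 1), p2=(4, 1), profile_halflength=10)
        with pytest.warns(UserWarning):
            ky.perpendicular_profile(np.ones((8, 8)), axis)


class TestBuildKymograph:
    def test_static_movie_all_rows_identical(self):
        frames = np.tile(np.random.default_rng(0).random((32, 32))[None], (5, 1, 1))
        movie = MovieStack(frames, frame_interval=0.1)
        axis = ky.AxisSpec(p1=(8, 16), p2=(24, 16), profile_halflength=6)
        k = ky.build_kymograph(movie, axis)
        assert k.frame_rate == pytest.approx(10.0)
        for row in k.matrix[1:]:
            np.testing.assert_allclose(row, k.matrix[0])

    def test_translating_ridge_tracks_linearly(self):
        T, h, w = 12, 48, 48
        v = 0.8  # pixels per frame toward +y
        frames = np.zeros((T, h, w))
        yy = np.arange(h, dtype=float)[:, None]
        for t in range(T):
            frames[t] = np.exp(-((yy - (18.0 + v * t)) ** 2) / 8.0)
        movie = MovieStack(frames, frame_interval=1.0)
        axis = ky.AxisSpec(p1=(10, 22), p2=(38, 22), profile_halflength=10, sample_spacing=0.25)
        track = ky.peak_position_track(ky.build_kymograph(movie, axis))
        # bilinear interpolation quantizes maxima to the pixel grid, so check
        # the fitted slope and the per-frame positions at half-pixel accuracy
        slope = np.polyfit(np.arange(T), track.positions, 1)[0]
        assert slope == pytest.approx(v, abs=0.1)
        truth = -4.0 + v * np.arange(T)
        np.testing.assert_allclose(track.positions, truth, atol=0.5 + 1e-9)


class TestPeakPositionTrack:
    def kymo(self, rows, spacing=1.0):
        rows = np.asarray(rows, dtype=float)
        n = rows.shape[1] // 2
        positions = (np.arange(rows.shape[1]) - n) * spacing
        return ky.Kymograph(matrix=rows, positions=positions, frame_rate=1.0)

    def test_single_gaussian_rows_give_exact_centers(self):
        pos = np.linspace(-8, 8, 17)
        rows = [np.exp(-((pos - c) ** 2) / 2.0) for c in (-3.0, 0.0, 2.0)]
        track = ky.peak_position_track(self.kymo(rows))
        np.testing.assert_allclose(track.positions, [-3.0, 0.0, 2.0])
        assert track.single_peak.all()

    def test_two_equal_symmetric_maxima_report_zero_flag_false(self):
        row = np.zeros(17)
        row[4] = row[12] = 5.0  # positions -4 and +4
        track = ky.peak_position_track(self.kymo([row]))
        assert track.positions[0] == 0.0
        assert not track.single_peak[0]

    def test_all_zero_row_is_missing(self):
        track = ky.peak_position_track(self.kymo([np.zeros(9), np.ones(9)]))
        assert np.isnan(track.positions[0])
        assert track.positions[1] == 0.0

    def test_noisy_sinusoid_rmse_below_sample_spacing(self):
        rng = np.random.default_rng(12)
        spacing = 0.5
        pos = (np.arange(41) - 20) * spacing
        T = 200
        truth = 3.0 * np.sin(2 * np.pi * 0.05 * np.arange(T))
        rows = np.exp(-((pos[None, :] - truth[:, None]) ** 2) / (2 * 1.5**2))
        rows += rng.normal(0, 0.1, rows.shape)  # SNR ~ 10
        k = ky.Kymograph(matrix=rows, positions=pos, frame_rate=1.0)
        track = ky.peak_position_track(k)
        rmse = np.sqrt(np.mean((track.positions - truth) ** 2))
        assert rmse < spacing


class TestWindowedFFT:
    def test_frequency_unit_at_published_settings(self):
        track = np.sin(np.arange(256) * 0.3)
        spec = ky.windowed_fft(track, frame_rate=134.47, window=128)
        assert spec.freqs[1] == pytest.approx(134.47 / 128, rel=1e-12)
        assert round(spec.freqs[1], 2) == 1.05
        assert len(spec.freqs) == 65

    def test_constant_track_has_zero_spectrum(self):
        spec = ky.windowed_fft(np.full(128, 3.3), frame_rate=10.0, window=128)
        np.testing.assert_allclose(spec.amplitudes, 0.0, atol=1e-9)

    def test_pure_sine_at_bin_concentrates_in_single_bin(self):
        window, kbin = 128, 9
        t = np.arange(window)
        track = np.sin(2 * np.pi * kbin * t / window)
        spec = ky.windowed_fft(track, frame_rate=134.47, window=window)
        amps = spec.amplitudes[0]
        assert np.argmax(amps) == kbin
        others = np.delete(amps, kbin)
        np.testing.assert_allclose(others, 0.0, atol=1e-9)

    def test_windows_with_missing_values_skipped(self):
        track = np.sin(np.arange(384) * 0.2)
        track[130] = np.nan
        spec = ky.windowed_fft(track, frame_rate=10.0, window=128)
        assert spec.amplitudes.shape[0] == 2

    def test_non_power_of_two_window_warned_but_accepted(self):
        with pytest.warns(UserWarning):
            spec = ky.windowed_fft(np.sin(np.arange(200) * 0.3), 10.0, window=100)
        assert spec.freqs[1] == pytest.approx(0.1)

    def test_track_shorter_than_window_rejected(self):
        with pytest.raises(ValueError):
            ky.windowed_fft(np.zeros(64), 10.0, window=128)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(frame_rate=st.floats(1.0, 500.0), window=st.sampled_from([32, 64, 128, 256]))
def test_frequency_spacing_exact_for_all_inputs(frame_rate, window):
    track = np.sin(np.arange(window) * 0.37)
    spec = ky.windowed_fft(track, frame_rate=frame_rate, window=window)
    np.testing.assert_array_equal(
        spec.freqs, np.arange(window // 2 + 1) * (frame_rate / window)
    )
    assert len(spec.freqs) == window // 2 + 1


class TestImageFFTSpectrum:
    def test_white_noise_spectrum_is_flat(self):
        rng = np.random.default_rng(3)
        img = rng.normal(0, 1, (128, 128))
        spec = ky.image_fft_spectrum(img)
        inner = spec.log_magnitude[2:]  # skip DC-adjacent bins
        assert inner.max() - inner.min() < 0.5

    def test_lowpass_filtered_copy_loses_high_frequencies(self):
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(4)
        img = rng.normal(0, 1, (128, 128))
        orig = ky.image_fft_spectrum(img)
        low = ky.image_fft_spectrum(gaussian_filter(img, 2.0))
        tail = slice(len(orig.freqs) // 2, None)
        assert np.all(low.log_magnitude[tail] <= orig.log_magnitude[tail])

    def test_plane_waves_peak_at_their_radial_frequencies(self):
        n = 128
        yy, xx = np.indices((n, n))
        f1, f2 = 10 / n, 40 / n
        img = np.sin(2 * np.pi * f1 * xx) + np.sin(2 * np.pi * f2 * yy)
        spec = ky.image_fft_spectrum(img)
        mags = spec.log_magnitude[3:]  # skip the DC-residue bins
        top2 = np.sort(np.argsort(mags)[-2:]) + 3
        got = np.sort(spec.freqs[top2])
        np.testing.assert_allclose(got, [f1, f2], atol=1.0 / n)

    def test_pixel_size_converts_axis(self):
        spec = ky.image_fft_spectrum(np.random.default_rng(0).random((32, 32)),
                                     pixel_size_nm=100.0)
        np.testing.assert_allclose(spec.freqs_per_um, spec.freqs * 10.0)


def test_full_pipeline_invariant_under_global_gain():
    """Mask -> crop -> kymograph -> track -> FFT gives identical spectra at any gain."""
    from fp_photodyn import er_dynamics, pick_kymograph_axis, simulate_er_movie

    movie, truth = simulate_er_movie(osc_freq=6.0, n_frames=128, seed=8, snr=None)
    axis = pick_kymograph_axis(truth)

    def analyse(frames):
        mv = MovieStack(frames, movie.frame_interval)

        def preprocess(frame):
            mask, _, _ = er_dynamics.binarize_frame(frame, np.ones(frame.shape, bool))
            mask = ky.remove_small_components(mask, 20)
            return ky.masked_crop(frame, mask)

        k = ky.build_kymograph(mv, axis, preprocess=preprocess)
        track = ky.peak_position_track(k)
        return ky.windowed_fft(track.positions, mv.frame_rate, window=128)

    s1 = analyse(movie.frames)
    s2 = analyse(movie.frames * 250.0)
    np.testing.assert_allclose(s1.amplitudes, s2.amplitudes, atol=1e-9)
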