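"""Sliding-kurtosis detector: statistic, screening, selection, peaks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from dopbeat import (
    BeatSeries,
    DopbeatError,
    RunConfig,
    SampledSignal,
    SignalTooNoisyError,
    build_kurtosis_matrix,
    chebyshev_screen,
    detect_beats,
    estimate_fhr,
    kurtosis,
    mismatch_error,
    select_vectors,
    simulate,
    sliding_kurtosis,
    var_b_loc,
)
from dopbeat.decomposition import IMFSet, eemd
from dopbeat.kurtosis import KurtosisVector
from dopbeat.preprocess import denoise_wavelet


def brute_force_kurtosis(x):
    x = np.asarray(x, dtype=float)
    peak = np.max(np.abs(x))
    if peak > 0:
        x = x / peak  # the ratio is scale-invariant; avoid over/underflow
    return (len(x) - 1) * np.sum(x**4) / np.sum(x**2) ** 2


class TestKurtosisStatistic:
    def test_constant_vector_value(self):
        assert kurtosis(np.full(10, 3.7)) == pytest.approx(0.9)

    def test_single_impulse_value(self):
        x = np.zeros(10)
        x[4] = -2.0
        assert kurtosis(x) == pytest.approx(9.0)

    def test_gaussian_converges_to_three(self):
        vals = [
            kurtosis(np.random.default_rng(seed).standard_normal(100_000))
            for seed in range(20)
        ]
        assert np.mean(vals) == pytest.approx(3.0, abs=0.1)

    def test_all_zero_window_defined_as_zero(self):
        assert kurtosis(np.zeros(16)) == 0.0

    @given(
        hnp.arrays(
            np.float64,
            st.integers(4, 60),
            elements=st.floats(-1e3, 1e3, allow_nan=False, width=64),
        )
    )
    @settings(max_examples=100, derandomize=True)
    def test_matches_brute_force_on_arbitrary_vectors(self, x):
        if np.sum(x**2) == 0:
            assert kurtosis(x) == 0.0
        else:
            assert kurtosis(x) == pytest.approx(brute_force_kurtosis(x), rel=1e-9)


class TestSlidingKurtosis:
    def test_constant_signal_every_window_constant(self):
        v = sliding_kurtosis(np.ones(500), fs=1000.0, window_ms=100.0)
        np.testing.assert_allclose(v.values, 99.0 / 100.0)

    def test_length_contract(self):
        v = sliding_kurtosis(np.random.default_rng(0).standard_normal(60_000),
                             fs=1000.0, window_ms=300.0)
        assert v.values.size == 59_701

    def test_impulse_maximum_near_the_impulse(self):
        x = 0.01 * np.random.default_rng(1).standard_normal(3000)
        x[1500] = 5.0
        v = sliding_kurtosis(x, fs=1000.0, window_ms=100.0)
        peak_center = np.argmax(v.values) + v.center_offset_samples
        assert abs(peak_center - 1500) <= 100

    def test_agrees_with_per_window_brute_force(self):
        x = np.random.default_rng(2).standard_normal(400)
        w = 50
        v = sliding_kurtosis(x, fs=1000.0, window_ms=float(w))
        expected = [brute_force_kurtosis(x[k : k + w]) for k in range(x.size - w + 1)]
        np.testing.assert_allclose(v.values, expected, rtol=1e-8)

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(DopbeatError):
            sliding_kurtosis(np.ones(100), fs=1000.0, window_ms=200.0)


class TestChebyshevScreen:
    @pytest.mark.parametrize("seed", range(20))
    def test_white_gaussian_is_noise_like(self, seed):
        v = np.random.default_rng(seed).standard_normal(5000)
        assert chebyshev_screen(v) is False

    def test_sparse_sharp_peaks_are_peaked(self):
        v = 0.01 * np.random.default_rng(0).standard_normal(2000)
        v[::100] = 1.0  # rare spikes many SDs above the mean
        sd = np.std(v)
        assert np.max(np.abs(v - v.mean())) > 8 * sd
        assert chebyshev_screen(v) is True

    def test_constant_vector_is_rejected(self):
        assert chebyshev_screen(np.full(100, 5.0)) is False


def _bursty_imf(freq_hz, n=20_000, period=400, width=30, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(n) / 1000.0
    x = 0.05 * rng.standard_normal(n)
    for c in range(period // 2, n - period // 2, period):
        w = np.exp(-0.5 * ((np.arange(n) - c) / (width / 4.0)) ** 2)
        x += w * np.cos(2 * np.pi * freq_hz * (t - t[c]))
    return x


@pytest.fixture(scope="module")
def bursty_imfset():
    imfs = tuple(_bursty_imf(f, seed=i) for i, f in enumerate((120.0, 60.0, 25.0)))
    noise = tuple(
        0.3 * np.random.default_rng(10 + i).standard_normal(20_000) for i in range(2)
    )
    return IMFSet(imfs + noise, np.zeros(20_000), 20_000)


class TestMatrixAndSelection:
    def test_three_surviving_imfs_give_36_vectors(self, bursty_imfset):
        matrix = build_kurtosis_matrix(bursty_imfset, fs=1000.0)
        assert matrix.imf_indices == (1, 2, 3)
        assert len(matrix.vectors) == 36

    def test_empty_window_list_rejected(self, bursty_imfset):
        with pytest.raises(DopbeatError):
            build_kurtosis_matrix(bursty_imfset, fs=1000.0, windows_ms=())

    def test_valve_scale_imf_survives_on_synthetic_record(self, record_short, fast_config):
        den = denoise_wavelet(record_short.dus)
        imfs = eemd(den, ensemble_size=5, noise_sd_fraction=0.2, seed=1)
        matrix = build_kurtosis_matrix(imfs, fs=record_short.dus.fs)
        assert any(i in (1, 2) for i in matrix.imf_indices)

    def test_noise_only_imfs_all_screened_out(self):
        noise = tuple(
            np.random.default_rng(i).standard_normal(20_000) for i in range(3)
        )
        s = IMFSet(noise, np.zeros(20_000), 20_000)
        with pytest.raises(SignalTooNoisyError):
            build_kurtosis_matrix(s, fs=1000.0)

    def test_default_mode_selects_optimal_region(self, bursty_imfset):
        matrix = build_kurtosis_matrix(bursty_imfset, fs=1000.0)
        sel = select_vectors(matrix, None, fs=1000.0)
        assert sel.mode == "default"
        assert set(sel.selected) == {
            (i, w) for i in (1, 2, 3) for w in (300.0, 350.0, 400.0)
        }

    def test_single_vector_matrix_selects_that_vector(self, bursty_imfset):
        matrix = build_kurtosis_matrix(bursty_imfset, fs=1000.0, windows_ms=(300.0,),
                                       max_levels=1)
        sel = select_vectors(matrix, None, fs=1000.0)
        assert sel.selected == ((1, 300.0),)


class TestMismatchAndVarBLoc:
    @pytest.mark.parametrize(
        "true_count,est_count,expected",
        [(100, 100, 0.0), (150, 147, 2.0), (100, 105, -5.0)],
    )
    def test_signed_percentage(self, true_count, est_count, expected):
        assert mismatch_error(true_count, est_count) == pytest.approx(expected)

    def test_zero_true_count_rejected(self):
        with pytest.raises(DopbeatError):
            mismatch_error(0, 10)

    def test_identical_beats_zero_spread(self):
        b = BeatSeries(np.arange(10) * 400.0 + 100.0)
        assert var_b_loc(b, b) == 0.0

    def test_constant_offset_zero_spread(self):
        t = BeatSeries(np.arange(10) * 400.0 + 100.0)
        e = BeatSeries(t.beat_times + 20.0)
        assert var_b_loc(t, e) == pytest.approx(0.0)

    def test_alternating_offsets_hand_value(self):
        t = BeatSeries(np.arange(4) * 400.0 + 100.0)
        e = BeatSeries(t.beat_times + np.array([5.0, 15.0, 5.0, 15.0]))
        assert var_b_loc(t, e) == pytest.approx(np.std([5, 15, 5, 15], ddof=1))
        assert var_b_loc(t, e) == pytest.approx(5.7735, abs=1e-3)

    def test_no_pairs_within_window_rejected(self):
        t = BeatSeries(np.arange(5) * 400.0)
        e = BeatSeries(np.arange(5) * 400.0 + 10_000.0)
        with pytest.raises(DopbeatError):
            var_b_loc(t, e)


def _vector(values, window_ms=100.0, fs=1000.0):
    w = int(window_ms)
    return KurtosisVector(np.asarray(values, dtype=float), window_ms, 1, w, fs)


class TestDetectBeats:
    def test_recovers_known_impulse_locations_exactly(self):
        values = np.zeros(3000)
        true_at = np.array([400, 850, 1400, 1900, 2500])
        values[true_at] = 5.0
        v = _vector(values)
        beats = detect_beats([v], fs=1000.0)
        expected = (true_at + v.center_offset_samples) * 1.0
        np.testing.assert_allclose(beats.beat_times, expected)

    def test_refractory_keeps_only_the_taller_peak(self):
        values = np.zeros(1000)
        values[400] = 2.0
        values[600] = 1.0
        beats = detect_beats([_vector(values)], fs=1000.0, min_distance_ms=300.0)
        assert beats.n_beats == 1
        assert beats.beat_times[0] == 400.0 + _vector(values).center_offset_samples

    @pytest.mark.parametrize("seed", range(10))
    def test_min_distance_invariant_on_random_input(self, seed):
        values = np.abs(np.random.default_rng(seed).standard_normal(5000))
        try:
            beats = detect_beats([_vector(values)], fs=1000.0, min_distance_ms=300.0)
        except DopbeatError:
            return
        if beats.n_beats > 1:
            assert np.all(beats.intervals >= 300.0)

    def test_empty_vector_list_rejected(self):
        with pytest.raises(DopbeatError):
            detect_beats([], fs=1000.0)

    def test_center_alignment_across_window_sizes(self):
        """Vectors of different windows vote for the same beat time."""
        base = np.zeros(4000)
        base[[1000, 1500, 2000, 2500]] = 4.0
        v100 = sliding_kurtosis(base, 1000.0, 100.0)
        v300 = sliding_kurtosis(base, 1000.0, 300.0)
        merged = detect_beats([v100, v300], fs=1000.0)
        single = detect_beats([v100], fs=1000.0)
        np.testing.assert_allclose(
            merged.beat_times, single.beat_times, atol=2.0
        )


class TestEndToEnd:
    def test_pipeline_is_deterministic(self, record_short, fast_config):
        a = estimate_fhr(record_short.dus, fast_config)
        b = estimate_fhr(record_short.dus, fast_config)
        np.testing.assert_array_equal(a.beat_times, b.beat_times)

    def test_noise_only_record_raises_instead_of_inventing_beats(self):
        x = SampledSignal(np.random.default_rng(3).standard_normal(20_000), 1000.0)
        cfg = RunConfig(ensemble_size=3, seed=1)
        with pytest.raises(DopbeatError):
            estimate_fhr(x, cfg)

    def test_short_record_rejected(self):
        x = SampledSignal(np.random.default_rng(4).standard_normal(2000), 1000.0)
        with pytest.raises(DopbeatError, match="5 s"):
            estimate_fhr(x)

    def test_calibrated_mode_produces_surfaces(self, record_short, fast_config):
        beats, details = estimate_fhr(
            record_short.dus, fast_config, truth=record_short.true_beats,
            return_details=True,
        )
        sel = details["selection"]
        assert sel.mode == "calibrated"
        assert sel.mismatch_surface.shape == (
            len(details["matrix"].imf_indices), 12,
        )
        assert beats.n_beats > 0
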