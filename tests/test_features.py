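"""Spectral feature extraction: closed forms, invariants, normalization."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from songsim.config import RunConfig
from songsim.features import (AudioTooShortError, FeatureSet, SampleRateError,
                              Spectrogram, Waveform, compute_features,
                              compute_spectrogram, denormalize_features,
                              fit_normalization, frequency_modulation,
                              gravity_center, normalize_features,
                              pitch_and_goodness, spectral_width,
                              wiener_entropy)
from songsim.synth import MotifSpec, SyllableSpec, render_motif

FS = 44100


def tone(freq, dur_ms=100.0, fs=FS, amp=1.0):
    t = np.arange(int(round(dur_ms * fs / 1000.0))) / fs
    return Waveform(amp * np.sin(2 * np.pi * freq * t), fs)


def flat_spec(power_rows, freqs):
    power = np.atleast_2d(np.asarray(power_rows, float))
    return Spectrogram(power, np.asarray(freqs, float),
                       np.arange(power.shape[0], dtype=float))


class TestSpectrogram:
    def test_frame_count_1000ms(self):
        spec = compute_spectrogram(tone(3000, 1000.0))
        assert spec.n_frames == 992  # floor((1000 - 9)/1) + 1

    @given(st.integers(min_value=9, max_value=1500))
    def test_frame_count_formula(self, dur_ms):
        # 32 kHz has an integer number of samples per ms, so integer-ms
        # durations are exactly representable
        wave = Waveform(np.zeros(dur_ms * 32), 32000)
        spec = compute_spectrogram(wave)
        assert spec.n_frames == (dur_ms - 9) // 1 + 1

    def test_tone_localized(self):
        spec = compute_spectrogram(tone(3000))
        peak_freqs = spec.freqs[np.argmax(spec.power, axis=1)]
        df = np.mean(np.diff(spec.freqs))
        assert np.all(np.abs(peak_freqs - 3000) <= df)

    def test_silence_is_zero_power(self):
        spec = compute_spectrogram(Waveform(np.zeros(FS // 2), FS))
        assert np.all(spec.power == 0)

    def test_too_short_audio_rejected(self):
        with pytest.raises(AudioTooShortError):
            compute_spectrogram(Waveform(np.zeros(100), FS))

    def test_low_sample_rate_rejected(self):
        with pytest.raises(SampleRateError):
            compute_spectrogram(Waveform(np.zeros(8000), 8000))

    def test_band_restriction(self):
        spec = compute_spectrogram(tone(3000))
        assert spec.freqs[0] >= 500 and spec.freqs[-1] <= 8600


class TestWienerEntropy:
    def test_flat_spectrum_zero(self):
        spec = flat_spec([[2.0, 2.0, 2.0, 2.0]], [1000, 2000, 3000, 4000])
        assert wiener_entropy(spec).values[0] == pytest.approx(0.0, abs=1e-12)

    def test_two_bin_example(self):
        # geometric mean 2, arithmetic mean 2.5 -> log(0.8)
        spec = flat_spec([[1.0, 4.0]], [1000, 2000])
        assert wiener_entropy(spec).values[0] == pytest.approx(
            np.log(2.0 / 2.5), abs=1e-12)

    def test_near_tonal_large_negative(self):
        spec = flat_spec([[1.0, 1e-8]], [1000, 2000])
        assert wiener_entropy(spec).values[0] < -5

    def test_silent_frame_floored(self):
        spec = flat_spec([[0.0, 0.0]], [1000, 2000])
        assert wiener_entropy(spec, floor=-10.0).values[0] == -10.0

    def test_always_nonpositive_on_song(self):
        wave, _ = render_motif(MotifSpec(
            (SyllableSpec("noise_burst", 80, f0=1000, f1=8000),), (), "n"))
        spec = compute_spectrogram(wave)
        assert np.all(wiener_entropy(spec).values <= 0)


class TestSpectralMoments:
    def test_delta_spectrum(self):
        spec = flat_spec([[0.0, 5.0, 0.0]], [1000, 2000, 3000])
        assert gravity_center(spec).values[0] == pytest.approx(2000)
        assert spectral_width(spec).values[0] == pytest.approx(0.0)

    def test_symmetric_two_point(self):
        spec = flat_spec([[1.0, 1.0]], [1000, 3000])
        assert gravity_center(spec).values[0] == pytest.approx(2000)
        assert spectral_width(spec).values[0] == pytest.approx(1000)

    def test_weighted_example(self):
        spec = flat_spec([[1.0, 3.0]], [1000, 2000])
        assert gravity_center(spec).values[0] == pytest.approx(1750)
        assert spectral_width(spec).values[0] == pytest.approx(
            np.sqrt(0.25 * 750 ** 2 + 0.75 * 250 ** 2))

    def test_scaling_invariance(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.1, 1.0, (5, 20))
        f = np.linspace(500, 8600, 20)
        a, b = flat_spec(p, f), flat_spec(7.3 * p, f)
        np.testing.assert_allclose(gravity_center(a).values,
                                   gravity_center(b).values, rtol=1e-12)

    def test_silent_frame_fallbacks(self):
        spec = flat_spec([[0.0, 0.0]], [1000, 3000])
        assert gravity_center(spec).values[0] == pytest.approx(2000)
        assert spectral_width(spec).values[0] == 0.0


class TestPitch:
    def test_harmonic_stack_pitch(self):
        wave, _ = render_motif(MotifSpec(
            (SyllableSpec("harmonic_stack", 120, f0=700),), (), "s"),
            noise_floor_db=None, pad_ms=0.0)
        spec = compute_spectrogram(wave)
        pitch, goodness = pitch_and_goodness(spec)
        mid = slice(30, 90)  # avoid onset/offset ramps
        assert np.median(pitch.values[mid]) == pytest.approx(700, abs=25)
        assert np.all(goodness.values[mid] > 0)

    def test_white_noise_goodness_much_lower_than_stack(self):
        stack, _ = render_motif(MotifSpec(
            (SyllableSpec("harmonic_stack", 120, f0=700),), (), "s"),
            noise_floor_db=None, pad_ms=0.0)
        white = Waveform(
            np.random.default_rng(3).standard_normal(stack.samples.size),
            FS)
        g_stack = pitch_and_goodness(compute_spectrogram(stack))[1].values
        g_noise = pitch_and_goodness(compute_spectrogram(white))[1].values
        assert np.median(g_stack[30:90]) > 10 * np.median(g_noise[30:90])

    def test_pitch_amplitude_invariant(self):
        a = compute_spectrogram(tone(1200, amp=0.3))
        b = compute_spectrogram(tone(1200, amp=0.9))
        pa = pitch_and_goodness(a)[0].values
        pb = pitch_and_goodness(b)[0].values
        np.testing.assert_allclose(pa, pb, rtol=1e-9)

    def test_silent_frames_zero_goodness(self):
        spec = compute_spectrogram(Waveform(np.zeros(FS // 10), FS))
        pitch, goodness = pitch_and_goodness(spec)
        assert np.all(goodness.values == 0)
        assert np.all(pitch.values == pytest.approx(0.5 * (spec.freqs[0]
                                                           + spec.freqs[-1])))


class TestFrequencyModulation:
    def test_stationary_tone_near_zero(self):
        # sub-sample frame-start jitter leaves a little sidelobe noise in
        # the time derivative; the angle still stays far below sweep FM
        spec = compute_spectrogram(tone(2000, 200.0))
        fm = frequency_modulation(spec).values[20:-20]
        assert np.median(fm) < 0.1
        assert np.all(fm < 0.3)

    def test_sweep_constant_positive(self):
        wave, _ = render_motif(MotifSpec(
            (SyllableSpec("sweep", 200, f0=1000, f1=4000),), (), "c"),
            noise_floor_db=None, pad_ms=0.0)
        fm = frequency_modulation(compute_spectrogram(wave)).values[40:-40]
        assert np.all(fm > 0.05)
        assert np.std(fm) < 0.35 * np.mean(fm)

    def test_silence_flagged_zero(self):
        spec = compute_spectrogram(Waveform(np.zeros(FS // 10), FS))
        assert np.all(frequency_modulation(spec).values == 0)


class TestNormalization:
    def make_sets(self, arrays):
        return [FeatureSet(np.column_stack([a]), ("gravity_center",))
                for a in arrays]

    def test_mad_about_mean_example(self):
        stats = fit_normalization(self.make_sets([[1.0, 2.0, 3.0, 6.0]]))
        assert stats.center[0] == pytest.approx(3.0)
        assert stats.scale[0] == pytest.approx(1.5)  # median{2,1,0,3}

    def test_two_value_example(self):
        stats = fit_normalization(self.make_sets([[0.0, 2.0]]))
        assert stats.center[0] == pytest.approx(1.0)
        assert stats.scale[0] == pytest.approx(1.0)

    def test_constant_feature_rejected(self):
        with pytest.raises(ValueError, match="gravity_center"):
            fit_normalization(self.make_sets([[5.0, 5.0, 5.0]]))

    def test_apply_arithmetic(self):
        from songsim.features import NormalizationStats
        stats = NormalizationStats(("gravity_center",), [5.0], [2.0])
        fs = self.make_sets([[9.0]])[0]
        assert normalize_features(fs, stats).values[0, 0] == pytest.approx(2.0)

    def test_centering_on_fit_corpus(self):
        rng = np.random.default_rng(1)
        sets = self.make_sets([rng.normal(3, 1, 50) for _ in range(4)])
        stats = fit_normalization(sets)
        pooled = np.concatenate(
            [normalize_features(s, stats).values[:, 0] for s in sets])
        assert pooled.mean() == pytest.approx(0.0, abs=1e-10)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        sets = self.make_sets([rng.normal(0, 2, 30)])
        stats = fit_normalization(sets)
        back = denormalize_features(normalize_features(sets[0], stats), stats)
        np.testing.assert_allclose(back.values, sets[0].values, atol=1e-10)

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            fit_normalization([])


class TestEndToEnd:
    def test_motif_features_finite_and_reproducible(self, config):
        spec = MotifSpec((SyllableSpec("harmonic_stack", 80, f0=650),
                          SyllableSpec("pure_tone", 60, f0=2000),
                          SyllableSpec("sweep", 70, f0=1000, f1=1800)),
                         (30.0, 40.0), "m")
        wave, _ = render_motif(spec, seed=11)
        a = compute_features(wave, config)
        b = compute_features(wave, config)
        assert np.all(np.isfinite(a.values))
        np.testing.assert_array_equal(a.values, b.values)

    def test_multichannel_wav_rejected(self, tmp_path):
        from scipy.io import wavfile
        stereo = np.zeros((1000, 2), dtype=np.int16)
        wavfile.write(tmp_path / "stereo.wav", FS, stereo)
        with pytest.raises(ValueError, match="channel"):
            Waveform.from_wav(tmp_path / "stereo.wav")

    def test_csv_round_trip(self, tmp_path, config):
        wave, _ = render_motif(MotifSpec(
            (SyllableSpec("pure_tone", 60, f0=1500),), (), "t"))
        feats = compute_features(wave, config)
        feats.to_csv(tmp_path / "t.csv", sidecar=config.to_dict())
        back = FeatureSet.from_csv(tmp_path / "t.csv")
        assert back.names == feats.names
        np.testing.assert_allclose(back.values, feats.values, rtol=1e-6)
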