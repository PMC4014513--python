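"""Spectral feature extraction: audio -> per-millisecond feature tracks.

Song is represented at each millisecond by a small set of spectral
features computed from a multitaper power spectrogram (9 ms DPSS windows,
1 ms steps, 500-8600 Hz band).  Six features are available:

* ``wiener_entropy`` -- log spectral flatness; 0 for white noise,
  increasingly negative for pure tones.
* ``frequency_modulation`` -- angle between the time- and
  frequency-derivatives of log power, aggregated across the band.
* ``pitch`` -- fundamental frequency from the cepstrum (Fourier
  transform of the log spectrum).
* ``pitch_goodness`` -- cepstral power at the detected pitch; large for
  harmonic stacks.
* ``gravity_center`` -- first moment of the power spectrum.
* ``spectral_width`` -- square root of the second central moment of the
  power spectrum.

Before any song comparison each feature is centred on its mean over a
reference corpus and scaled so the median absolute deviation from that
mean is one (standard-deviation scaling available as an option).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.fft import rfft, rfftfreq
from scipy.io import wavfile
from scipy.signal.windows import dpss

from .config import FEATURE_NAMES, RunConfig

__all__ = [
    "Waveform",
    "Spectrogram",
    "FeatureTrack",
    "FeatureSet",
    "NormalizationStats",
    "AudioTooShortError",
    "SampleRateError",
    "compute_spectrogram",
    "wiener_entropy",
    "gravity_center",
    "spectral_width",
    "pitch_and_goodness",
    "frequency_modulation",
    "compute_features",
    "fit_normalization",
    "normalize_features",
    "denormalize_features",
]


class AudioTooShortError(ValueError):
    """Audio shorter than one analysis window."""


class SampleRateError(ValueError):
    """Sample rate too low for the requested analysis band."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class Waveform:
    """Mono sound-pressure signal."""

    samples: np.ndarray
    sample_rate: int
    source_id: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("Waveform requires mono audio (1-D samples); "
                             f"got shape {self.samples.shape}")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration_ms(self) -> float:
        return self.samples.size * 1000.0 / self.sample_rate

    @classmethod
    def from_wav(cls, path: str | Path, source_id: str | None = None) -> "Waveform":
        rate, data = wavfile.read(str(path))
        if data.ndim != 1:
            raise ValueError(f"{path}: multi-channel WAV not supported "
                             f"({data.shape[1]} channels); supply mono audio")
        if data.dtype == np.int16:
            samples = data / 32768.0
        elif data.dtype == np.int32:
            samples = data / 2147483648.0
        elif data.dtype == np.uint8:
            samples = (data.astype(np.float64) - 128.0) / 128.0
        else:
            samples = data.astype(np.float64)
        return cls(samples, int(rate), source_id or Path(path).stem)

    def to_wav(self, path: str | Path) -> None:
        peak = np.max(np.abs(self.samples)) or 1.0
        scaled = np.clip(self.samples / max(peak, 1.0), -1.0, 1.0)
        wavfile.write(str(path), self.sample_rate,
                      (scaled * 32767.0).astype(np.int16))


@dataclass
class Spectrogram:
    """Multitaper power spectrogram restricted to the analysis band."""

    power: np.ndarray          # (frames, bins), nonnegative
    freqs: np.ndarray          # Hz, strictly increasing
    frame_times_ms: np.ndarray
    window_ms: float = 9.0
    step_ms: float = 1.0
    sample_rate: int | None = None

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=np.float64)
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        if self.power.ndim != 2 or self.power.shape[1] != self.freqs.size:
            raise ValueError("power must be (frames, bins) matching freqs")
        if np.any(self.power < 0):
            raise ValueError("spectrogram power must be nonnegative")
        if self.freqs.size > 1 and np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.power.shape[0]


@dataclass
class FeatureTrack:
    """Per-frame values of one spectral feature."""

    name: str
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.name not in FEATURE_NAMES:
            raise ValueError(f"unknown feature {self.name!r}")
        self.values = np.asarray(self.values, dtype=np.float64)


@dataclass
class FeatureSet:
    """Aligned feature tracks for one song (frames x features)."""

    values: np.ndarray
    names: tuple[str, ...]
    normalized: bool = False
    silent: np.ndarray | None = None   # frames with zero total power
    source_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.names = tuple(self.names)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.names):
            raise ValueError("values must be (frames, len(names))")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        if self.silent is not None:
            self.silent = np.asarray(self.silent, dtype=bool)
            if self.silent.size != self.values.shape[0]:
                raise ValueError("silent mask length must equal frame count")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def track(self, name: str) -> FeatureTrack:
        return FeatureTrack(name, self.values[:, self.names.index(name)],
                            self.normalized)

    def subset(self, names: Sequence[str]) -> "FeatureSet":
        idx = [self.names.index(n) for n in names]
        return FeatureSet(self.values[:, idx], tuple(names), self.normalized,
                          self.silent, self.source_id)

    def slice_frames(self, start: int, stop: int) -> "FeatureSet":
        return FeatureSet(self.values[start:stop], self.names, self.normalized,
                          None if self.silent is None else self.silent[start:stop],
                          self.source_id)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.names))
        df.insert(0, "frame_ms", np.arange(len(self)))
        return df

    def to_csv(self, path: str | Path, sidecar: dict | None = None) -> None:
        self.to_frame().to_csv(path, index=False)
        if sidecar is not None:
            Path(path).with_suffix(".json").write_text(
                json.dumps(sidecar, indent=2, sort_keys=True))

    @classmethod
    def from_csv(cls, path: str | Path, normalized: bool = False) -> "FeatureSet":
        df = pd.read_csv(path)
        names = tuple(c for c in df.columns if c != "frame_ms")
        return cls(df[list(names)].to_numpy(float), names, normalized,
                   source_id=Path(path).stem)


# ---------------------------------------------------------------------------
# spectrogram


def compute_spectrogram(wave: Waveform,
                        window_ms: float = 9.0,
                        step_ms: float = 1.0,
                        band: tuple[float, float] = (500.0, 8600.0),
                        time_bandwidth: float = 1.5,
                        n_tapers: int = 2) -> Spectrogram:
    """Multitaper (DPSS) power spectrogram on the analysis band.

    Frames advance in ``step_ms`` steps; the frame count is
    ``floor((duration_ms - window_ms)/step_ms) + 1``.  The FFT length is
    the next power of two at or above the window length, so bin spacing
    is stable across sample rates.
    """
    fs = wave.sample_rate
    if fs < 2 * band[1]:
        raise SampleRateError(
            f"sample rate {fs} Hz cannot represent the analysis band up to "
            f"{band[1]} Hz (need >= {2 * band[1]:.0f} Hz)")
    n = wave.samples.size
    dur_ms = n * 1000.0 / fs
    if dur_ms + 1e-9 < window_ms:
        raise AudioTooShortError(
            f"audio is {dur_ms:.2f} ms, shorter than one {window_ms} ms window")

    win = int(round(window_ms * fs / 1000.0))
    nfft = 1 << max(3, (win - 1).bit_length())
    n_frames = int(np.floor((dur_ms - window_ms) / step_ms + 1e-9)) + 1
    starts = np.round(np.arange(n_frames) * step_ms * fs / 1000.0).astype(np.int64)
    while n_frames > 0 and starts[n_frames - 1] + win > n:
        n_frames -= 1  # fractional-ms durations can overflow the last frame
    starts = starts[:n_frames]

    tapers = dpss(win, time_bandwidth, n_tapers)          # (k, win)
    frames = wave.samples[starts[:, None] + np.arange(win)]
    spectra = rfft(frames[:, None, :] * tapers[None, :, :], n=nfft, axis=-1)
    power = np.mean(np.abs(spectra) ** 2, axis=1)

    freqs = rfftfreq(nfft, 1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    return Spectrogram(power[:, mask], freqs[mask],
                       np.arange(n_frames) * step_ms,
                       window_ms, step_ms, fs)


def _log_power(power: np.ndarray) -> np.ndarray:
    """Elementwise log floored 100 dB below the global peak (silence-safe).

    The floor is global rather than per-frame so that floored bins keep a
    constant value across frames and do not create spurious time
    derivatives.
    """
    floor = max(power.max() * 1e-10, 1e-300)
    return np.log(np.maximum(power, floor))


# ---------------------------------------------------------------------------
# the six features


def wiener_entropy(spec: Spectrogram, floor: float = -10.0) -> FeatureTrack:
    """Log of geometric-to-arithmetic mean power ratio per frame (<= 0).

    All-zero (digitally silent) frames take the configured floor rather
    than -inf/NaN; deeply tonal frames are clipped at the same floor.
    """
    p = spec.power
    tot = p.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(p > 0, np.log(np.where(p > 0, p, 1.0)), -np.inf)
        ent = logs.mean(axis=1) - np.log(np.where(tot > 0, tot, 1.0))
    ent = np.where(tot > 0, ent, floor)
    ent = np.clip(ent, floor, 0.0)
    return FeatureTrack("wiener_entropy", ent)


def gravity_center(spec: Spectrogram) -> FeatureTrack:
    """First moment of the power spectrum; band midpoint on silent frames."""
    p, f = spec.power, spec.freqs
    tot = p.sum(axis=1)
    mid = 0.5 * (f[0] + f[-1])
    with np.errstate(invalid="ignore"):
        gc = np.where(tot > 0, p @ f / np.where(tot > 0, tot, 1.0), mid)
    return FeatureTrack("gravity_center", gc)


def spectral_width(spec: Spectrogram) -> FeatureTrack:
    """Sqrt of the power-weighted frequency variance about the gravity center."""
    p, f = spec.power, spec.freqs
    tot = p.sum(axis=1)
    safe = np.where(tot > 0, tot, 1.0)
    gc = np.where(tot > 0, p @ f / safe, 0.0)
    var = (p * (f[None, :] - gc[:, None]) ** 2).sum(axis=1) / safe
    width = np.where(tot > 0, np.sqrt(np.maximum(var, 0.0)), 0.0)
    return FeatureTrack("spectral_width", width)


def pitch_and_goodness(spec: Spectrogram,
                       pitch_band: tuple[float, float] = (400.0, 3000.0),
                       ) -> tuple[FeatureTrack, FeatureTrack]:
    """Cepstral pitch and its goodness.

    The cepstrum is the Fourier transform of the mean-removed log power
    spectrum; the pitch is the inverse quefrency of its largest peak in
    the configured fundamental-frequency band, and the goodness is the
    cepstral power at that peak.  Silent frames fall back to the
    analysis-band midpoint with goodness 0.
    """
    p, f = spec.power, spec.freqs
    if f.size < 4:
        raise ValueError("spectrum too narrow for cepstral analysis")
    df = float(np.mean(np.diff(f)))
    tot = p.sum(axis=1)
    lp = _log_power(p)
    lp = lp - lp.mean(axis=1, keepdims=True)

    nq = 1 << max(8, (p.shape[1] - 1).bit_length() + 3)  # fine quefrency grid
    cep = np.abs(rfft(lp, n=nq, axis=1)) ** 2
    quef = np.arange(cep.shape[1]) / (nq * df)           # seconds

    lo, hi = pitch_band
    band_mask = np.zeros(cep.shape[1], dtype=bool)
    valid = quef > 0
    band_mask[valid] = (1.0 / quef[valid] >= lo) & (1.0 / quef[valid] <= hi)
    if not band_mask.any():
        raise ValueError("pitch search band resolves to no cepstral bins")
    idx = np.flatnonzero(band_mask)
    peak = idx[np.argmax(cep[:, idx], axis=1)]

    mid = 0.5 * (f[0] + f[-1])
    pitch = np.where(tot > 0, 1.0 / quef[peak], mid)
    goodness = np.where(tot > 0, cep[np.arange(len(peak)), peak], 0.0)
    return (FeatureTrack("pitch", pitch),
            FeatureTrack("pitch_goodness", goodness))


def frequency_modulation(spec: Spectrogram) -> FeatureTrack:
    """Angle between time- and frequency-derivatives of log power.

    Per frame the two derivative fields (one-sided differences at the
    edges) are aggregated in quadrature across frequency bins, and the FM
    is ``arctan(|d/dt| / |d/df|)`` in [0, pi/2].  Silent frames give 0.
    """
    if spec.n_frames < 2:
        raise ValueError("frequency modulation needs at least 2 frames")
    lp = _log_power(spec.power)
    dt = np.gradient(lp, axis=0)
    dfreq = np.gradient(lp, axis=1)
    t_mag = np.sqrt((dt ** 2).sum(axis=1))
    f_mag = np.sqrt((dfreq ** 2).sum(axis=1))
    fm = np.arctan2(t_mag, f_mag)
    fm[(t_mag == 0) & (f_mag == 0)] = 0.0
    return FeatureTrack("frequency_modulation", fm)


def compute_features(wave: Waveform, config: RunConfig | None = None) -> FeatureSet:
    """All six raw feature tracks for one song."""
    cfg = config or RunConfig()
    spec = compute_spectrogram(wave, cfg.window_ms, cfg.step_ms, cfg.band,
                               cfg.time_bandwidth, cfg.n_tapers)
    ent = wiener_entropy(spec, cfg.entropy_floor)
    fm = frequency_modulation(spec)
    pitch, goodness = pitch_and_goodness(spec, cfg.pitch_band)
    gc = gravity_center(spec)
    width = spectral_width(spec)
    by_name = {t.name: t for t in (ent, fm, pitch, goodness, gc, width)}
    values = np.column_stack([by_name[n].values for n in FEATURE_NAMES])
    silent = spec.power.sum(axis=1) == 0
    return FeatureSet(values, FEATURE_NAMES, normalized=False, silent=silent,
                      source_id=wave.source_id)


# ---------------------------------------------------------------------------
# normalization


@dataclass
class NormalizationStats:
    """Per-feature centring/scaling constants fit on a reference corpus."""

    names: tuple[str, ...]
    center: np.ndarray
    scale: np.ndarray
    convention: str = "mad"

    def __post_init__(self) -> None:
        self.names = tuple(self.names)
        self.center = np.asarray(self.center, dtype=np.float64)
        self.scale = np.asarray(self.scale, dtype=np.float64)

    def to_dict(self) -> dict:
        return {"names": list(self.names),
                "center": self.center.tolist(),
                "scale": self.scale.tolist(),
                "convention": self.convention}

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationStats":
        return cls(tuple(d["names"]), np.array(d["center"]),
                   np.array(d["scale"]), d["convention"])


def fit_normalization(corpus: Iterable[FeatureSet],
                      convention: str = "mad") -> NormalizationStats:
    """Pooled center/scale per feature from a corpus of raw feature sets.

    Center is the pooled mean.  With the default ``mad`` convention the
    scale is the median absolute deviation from that mean; ``sd`` uses
    the pooled standard deviation.
    """
    sets = list(corpus)
    if not sets:
        raise ValueError("empty corpus")
    names = sets[0].names
    for fs in sets:
        if fs.names != names:
            raise ValueError("corpus feature sets must share names/order")
        if fs.normalized:
            raise ValueError("fit_normalization expects raw feature sets")
    pooled = np.concatenate([fs.values for fs in sets], axis=0)
    if pooled.shape[0] < 2:
        raise ValueError("need at least 2 pooled frames")
    center = pooled.mean(axis=0)
    dev = pooled - center
    if convention == "mad":
        scale = np.median(np.abs(dev), axis=0)
    elif convention == "sd":
        scale = dev.std(axis=0)
    else:
        raise ValueError("convention must be 'mad' or 'sd'")
    bad = np.flatnonzero(scale <= 0)
    if bad.size:
        raise ValueError("degenerate (zero-scale) feature(s): "
                         + ", ".join(names[i] for i in bad))
    return NormalizationStats(names, center, scale, convention)


def normalize_features(raw: FeatureSet, stats: NormalizationStats) -> FeatureSet:
    if raw.normalized:
        raise ValueError("feature set already normalized")
    if raw.names != stats.names:
        raise ValueError("feature names do not match normalization stats")
    if np.any(stats.scale <= 0):
        bad = [stats.names[i] for i in np.flatnonzero(stats.scale <= 0)]
        raise ValueError(f"zero scale for feature(s): {bad}")
    values = (raw.values - stats.center) / stats.scale
    return FeatureSet(values, raw.names, True, raw.silent, raw.source_id)


def denormalize_features(norm: FeatureSet, stats: NormalizationStats) -> FeatureSet:
    if not norm.normalized:
        raise ValueError("feature set is not normalized")
    if norm.names != stats.names:
        raise ValueError("feature names do not match normalization stats")
    values = norm.values * stats.scale + stats.center
    return FeatureSet(values, norm.names, False, norm.silent, norm.source_id)
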