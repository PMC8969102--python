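"""Audio-to-image front end.

Each recording is turned into a single 3-channel "spectrogram image": a
log-Mel spectrogram (dB), its delta (first-order local-regression derivative
along time) and its delta-delta (acceleration), each resized to 224 x 224 by
bilinear interpolation.  Defaults: 224 Mel bands, hop length 1024 samples,
Hann window, audio resampled to 16 kHz on load; FFT size 2048; dB relative
to the per-recording maximum power with an 80 dB floor.

Mel filterbank and scale follow the Slaney convention (linear below 1 kHz,
logarithmic above), with triangular filters normalized to unit area.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy.io import wavfile
from scipy.signal import get_window, resample_poly, savgol_filter
from skimage.transform import resize as _sk_resize

DEFAULT_SAMPLE_RATE = 16_000
DEFAULT_N_MELS = 224
DEFAULT_HOP = 1024
DEFAULT_N_FFT = 2048
DEFAULT_WINDOW = "hann"
DB_FLOOR = 80.0
DELTA_WIDTH = 9
IMAGE_SIZE = 224


class InvalidAudioError(ValueError):
    """Raised for empty or non-finite waveforms and undersized inputs."""


@dataclass(frozen=True)
class Waveform:
    """A mono audio signal with its sample rate in Hz."""

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size == 0:
            raise InvalidAudioError("waveform must be a non-empty 1-D signal")
        if not np.all(np.isfinite(samples)):
            raise InvalidAudioError("waveform contains non-finite samples")
        if self.sample_rate <= 0:
            raise InvalidAudioError("sample_rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate


@dataclass(frozen=True)
class MelMatrix:
    """dB-scaled Mel power spectrogram, rows = Mel bands, columns = frames."""

    values: np.ndarray
    n_mels: int
    hop_length: int
    window: str
    sample_rate: int

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != self.n_mels or v.shape[1] < 1:
            raise InvalidAudioError("MelMatrix must be (n_mels, n_frames>=1)")
        if not np.all(np.isfinite(v)):
            raise InvalidAudioError("MelMatrix contains non-finite values")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class SpectrogramImage:
    """3 x 224 x 224 image: (log_mel, delta, delta_delta) channels."""

    channels: np.ndarray
    channel_roles: Tuple[str, str, str] = ("log_mel", "delta", "delta_delta")
    normalization: dict = field(default_factory=dict)

    def __post_init__(self):
        c = np.asarray(self.channels, dtype=np.float64)
        if c.shape != (3, IMAGE_SIZE, IMAGE_SIZE):
            raise InvalidAudioError(f"image must be (3, {IMAGE_SIZE}, {IMAGE_SIZE})")
        if not np.all(np.isfinite(c)):
            raise InvalidAudioError("image contains non-finite values")
        object.__setattr__(self, "channels", c)


def load_wav(path, target_rate: int = DEFAULT_SAMPLE_RATE) -> Waveform:
    """Read a PCM WAV file, average channels to mono, resample to target_rate."""
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    data = data.astype(np.float64)
    if rate != target_rate:
        g = np.gcd(int(rate), int(target_rate))
        data = resample_poly(data, target_rate // g, rate // g)
    return Waveform(data, target_rate)


# -- Mel scale (Slaney convention) ---------------------------------------

_F_SP = 200.0 / 3.0
_MIN_LOG_HZ = 1000.0
_MIN_LOG_MEL = _MIN_LOG_HZ / _F_SP
_LOGSTEP = np.log(6.4) / 27.0


def hz_to_mel(f):
    f = np.asarray(f, dtype=np.float64)
    mel = f / _F_SP
    log_region = f >= _MIN_LOG_HZ
    mel = np.where(log_region,
                   _MIN_LOG_MEL + np.log(np.maximum(f, _MIN_LOG_HZ) / _MIN_LOG_HZ) / _LOGSTEP,
                   mel)
    return mel


def mel_to_hz(m):
    m = np.asarray(m, dtype=np.float64)
    f = m * _F_SP
    log_region = m >= _MIN_LOG_MEL
    f = np.where(log_region, _MIN_LOG_HZ * np.exp(_LOGSTEP * (m - _MIN_LOG_MEL)), f)
    return f


def mel_center_frequencies(n_mels: int, fmin: float, fmax: float) -> np.ndarray:
    """Center frequencies (Hz) of `n_mels` triangular filters in [fmin, fmax]."""
    mels = np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_mels + 2)
    return mel_to_hz(mels)[1:-1]


def mel_filterbank(sr: int, n_fft: int, n_mels: int,
                   fmin: float = 0.0, fmax: Optional[float] = None) -> np.ndarray:
    if fmax is None:
        fmax = sr / 2.0
    fft_freqs = np.linspace(0.0, sr / 2.0, 1 + n_fft // 2)
    mel_pts = mel_to_hz(np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_mels + 2))
    fb = np.zeros((n_mels, fft_freqs.size))
    for i in range(n_mels):
        lower, center, upper = mel_pts[i], mel_pts[i + 1], mel_pts[i + 2]
        up = (fft_freqs - lower) / max(center - lower, 1e-12)
        down = (upper - fft_freqs) / max(upper - center, 1e-12)
        fb[i] = np.maximum(0.0, np.minimum(up, down))
        # Slaney area normalization
        fb[i] *= 2.0 / (upper - lower)
    return fb


def _stft_power(samples: np.ndarray, n_fft: int, hop: int, window: str) -> np.ndarray:
    """Centered (reflect-padded) power spectrogram, shape (1+n_fft//2, frames)."""
    pad = n_fft // 2
    if samples.size > pad:
        padded = np.pad(samples, pad, mode="reflect")
    else:
        padded = np.pad(samples, pad, mode="constant")
    win = get_window(window, n_fft, fftbins=True)
    n_frames = 1 + (padded.size - n_fft) // hop
    n_frames = max(n_frames, 1)
    idx = np.arange(n_fft)[None, :] + hop * np.arange(n_frames)[:, None]
    idx = np.minimum(idx, padded.size - 1)
    frames = padded[idx] * win
    spec = np.fft.rfft(frames, axis=1)
    return (np.abs(spec) ** 2).T


def compute_log_mel(w: Waveform,
                    n_mels: int = DEFAULT_N_MELS,
                    hop_length: int = DEFAULT_HOP,
                    window: str = DEFAULT_WINDOW,
                    n_fft: int = DEFAULT_N_FFT) -> MelMatrix:
    """dB-scaled Mel power spectrogram of a waveform.

    dB reference is the per-recording maximum Mel power; values are floored
    at ``-DB_FLOOR`` dB below the reference, so digital silence maps to a
    constant floor.
    """
    if n_mels < 1:
        raise InvalidAudioError("n_mels must be >= 1")
    power = _stft_power(w.samples, n_fft, hop_length, window)
    mel = mel_filterbank(w.sample_rate, n_fft, n_mels) @ power
    amin = 1e-10
    ref = max(mel.max(), amin)
    db = 10.0 * np.log10(np.maximum(mel, amin)) - 10.0 * np.log10(ref)
    db = np.maximum(db, -DB_FLOOR)
    return MelMatrix(db, n_mels=n_mels, hop_length=hop_length, window=window,
                     sample_rate=w.sample_rate)


def compute_deltas(m: MelMatrix, width: int = DELTA_WIDTH
                   ) -> Tuple[np.ndarray, np.ndarray]:
    """First and second temporal derivatives by local linear regression.

    Uses a Savitzky-Golay filter of order 1 over `width` frames, the same
    estimator as the standard delta-feature recursion.  Requires at least
    `width` frames.
    """
    values = m.values
    if values.shape[1] < width:
        raise InvalidAudioError(
            f"need at least {width} frames for delta features, got {values.shape[1]}")
    delta = savgol_filter(values, width, polyorder=1, deriv=1, axis=1,
                          delta=1.0, mode="interp")
    delta_delta = savgol_filter(delta, width, polyorder=1, deriv=1, axis=1,
                                delta=1.0, mode="interp")
    return delta, delta_delta


def resize_channel(channel: np.ndarray, size: int = IMAGE_SIZE) -> np.ndarray:
    """Bilinear resize of a 2-D channel to (size, size)."""
    channel = np.asarray(channel, dtype=np.float64)
    if channel.shape == (size, size):
        return channel.copy()
    return _sk_resize(channel, (size, size), order=1, mode="edge",
                      anti_aliasing=False, preserve_range=True)


def build_spectrogram_image(m: MelMatrix,
                            normalize: bool = True,
                            mean: float = 0.5,
                            std: float = 0.5,
                            delta_width: int = DELTA_WIDTH) -> SpectrogramImage:
    """Stack (log_mel, delta, delta_delta), resize each channel to 224 x 224,
    then (optionally) min-max each channel to [0, 1] and standardize with the
    image encoder's expected mean/std."""
    delta, delta_delta = compute_deltas(m, width=delta_width)
    channels = np.stack([resize_channel(c) for c in (m.values, delta, delta_delta)])
    norm_info: dict = {"applied": bool(normalize)}
    if normalize:
        for i in range(3):
            lo, hi = channels[i].min(), channels[i].max()
            span = hi - lo
            channels[i] = (channels[i] - lo) / span if span > 0 else channels[i] * 0.0
            channels[i] = (channels[i] - mean) / std
        norm_info.update({"scheme": "minmax01", "mean": mean, "std": std})
    return SpectrogramImage(channels, normalization=norm_info)


def waveform_to_image(w: Waveform, **kwargs) -> SpectrogramImage:
    """Convenience: full audio-to-image pipeline with package defaults."""
    mel_kwargs = {k: kwargs.pop(k) for k in ("n_mels", "hop_length", "window", "n_fft")
                  if k in kwargs}
    return build_spectrogram_image(compute_log_mel(w, **mel_kwargs), **kwargs)
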