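"""Recording-level acoustic functionals and their projection for fusion.

:func:`extract_acoustic_functionals` computes an 88-dimensional vector of
acoustic functionals per recording, organized in the spirit of the extended
Geneva minimalistic parameter sets: frame-level low-level descriptors (F0 in
semitones above 27.5 Hz, voicing, energy, spectral shape) summarized by
statistics over the recording, plus temporal/rhythm features.  The layout is
fixed and named (see :data:`FEATURE_NAMES`); index 0 is the mean F0 in
semitones, so a 440 Hz tone scores ~48 (12*log2(440/27.5)).

:func:`project_and_tile` maps the 88-vector through a learnable linear layer
to 256 dimensions and repeats it once per text token, so the acoustic
"sequence" aligns with the word sequence for token-wise gating.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np

from ._tensor import Tensor
from .audio import InvalidAudioError, Waveform
from . import nn

N_FEATURES = 88
ACOUSTIC_PROJ_DIM = 256

_LLD_NAMES = [
    "f0_semitone", "voicing_prob", "energy_db", "spectral_centroid",
    "spectral_slope", "spectral_rolloff", "zcr", "spectral_flux",
    "low_high_ratio", "hnr_proxy",
]
_FUNCTIONAL_NAMES = ["mean", "std", "p10", "p50", "p90", "range", "slope_mean", "slope_std"]
_TEMPORAL_NAMES = [
    "voiced_fraction", "voiced_segments_per_sec", "mean_voiced_segment_s",
    "mean_unvoiced_segment_s", "silence_fraction", "energy_peaks_per_sec",
    "duration_s", "rms_overall",
]

FEATURE_NAMES: List[str] = (
    [f"{lld}_{fn}" for lld in _LLD_NAMES for fn in _FUNCTIONAL_NAMES] + _TEMPORAL_NAMES
)
assert len(FEATURE_NAMES) == N_FEATURES


def _frame(signal: np.ndarray, frame_len: int, hop: int) -> np.ndarray:
    n = 1 + max(0, (signal.size - frame_len)) // hop
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n)[:, None]
    return signal[idx]


def _autocorr_pitch(frame: np.ndarray, sr: int,
                    fmin: float = 60.0, fmax: float = 500.0) -> Tuple[float, float]:
    """(F0 in Hz or 0 if unvoiced, voicing strength in [0, 1])."""
    frame = frame - frame.mean()
    energy = float(np.dot(frame, frame))
    if energy < 1e-10:
        return 0.0, 0.0
    ac = np.correlate(frame, frame, mode="full")[frame.size - 1:]
    ac = ac / ac[0]
    lag_min = int(sr / fmax)
    lag_max = min(int(sr / fmin), ac.size - 1)
    if lag_max <= lag_min:
        return 0.0, 0.0
    seg = ac[lag_min:lag_max]
    peak = int(np.argmax(seg)) + lag_min
    strength = float(ac[peak])
    if strength < 0.45:
        return 0.0, max(strength, 0.0)
    return sr / peak, strength


def _functionals(x: np.ndarray) -> List[float]:
    if x.size == 0:
        return [0.0] * len(_FUNCTIONAL_NAMES)
    p10, p50, p90 = np.percentile(x, [10, 50, 90])
    slopes = np.diff(x) if x.size > 1 else np.zeros(1)
    return [float(x.mean()), float(x.std()), float(p10), float(p50), float(p90),
            float(p90 - p10), float(slopes.mean()), float(slopes.std())]


def extract_acoustic_functionals(w: Waveform,
                                 frame_s: float = 0.025,
                                 hop_s: float = 0.010) -> np.ndarray:
    """Compute the package's 88 acoustic functionals for a recording.

    Requires at least 1 s of audio (the functionals need support).
    Deterministic: same waveform in, identical vector out.
    """
    if w.duration < 1.0:
        raise InvalidAudioError("acoustic functionals require >= 1 s of audio")
    sr = w.sample_rate
    frame_len = int(round(frame_s * sr))
    hop = int(round(hop_s * sr))
    frames = _frame(w.samples, frame_len, hop)
    win = np.hanning(frame_len)

    n = frames.shape[0]
    f0_st = np.zeros(n)
    voicing = np.zeros(n)
    energy_db = np.zeros(n)
    centroid = np.zeros(n)
    slope = np.zeros(n)
    rolloff = np.zeros(n)
    zcr = np.zeros(n)
    flux = np.zeros(n)
    low_high = np.zeros(n)
    hnr = np.zeros(n)

    freqs = np.fft.rfftfreq(frame_len, 1.0 / sr)
    prev_spec: Optional[np.ndarray] = None
    for i in range(n):
        fr = frames[i]
        f0_hz, strength = _autocorr_pitch(fr, sr)
        voicing[i] = strength
        f0_st[i] = 12.0 * np.log2(f0_hz / 27.5) if f0_hz > 0 else 0.0
        rms = np.sqrt(np.mean(fr ** 2))
        energy_db[i] = 20.0 * np.log10(max(rms, 1e-10))
        spec = np.abs(np.fft.rfft(fr * win))
        total = spec.sum()
        if total > 1e-12:
            centroid[i] = float((freqs * spec).sum() / total)
            cum = np.cumsum(spec)
            rolloff[i] = float(freqs[np.searchsorted(cum, 0.95 * total)])
            # spectral slope by least squares of log magnitude on frequency
            logmag = 20.0 * np.log10(np.maximum(spec, 1e-10))
            slope[i] = float(np.polyfit(freqs, logmag, 1)[0] * 1000.0)  # dB/kHz
            low = spec[freqs < 2000.0].sum()
            high = spec[(freqs >= 2000.0) & (freqs < 5000.0)].sum()
            low_high[i] = float(10.0 * np.log10((low + 1e-12) / (high + 1e-12)))
            hnr[i] = float(10.0 * np.log10(max(strength, 1e-6) /
                                           max(1.0 - strength, 1e-6)))
        zcr[i] = float(np.mean(np.abs(np.diff(np.sign(fr))) > 0))
        if prev_spec is not None:
            flux[i] = float(np.sqrt(np.mean((spec - prev_spec) ** 2)))
        prev_spec = spec

    voiced = f0_st > 0
    features: List[float] = []
    for lld, mask in [
        (f0_st, voiced), (voicing, None), (energy_db, None), (centroid, None),
        (slope, None), (rolloff, None), (zcr, None), (flux, None),
        (low_high, None), (hnr, voiced),
    ]:
        features.extend(_functionals(lld[mask] if mask is not None else lld))

    # temporal / rhythm features
    dur = w.duration
    voiced_frac = float(voiced.mean()) if n else 0.0
    transitions = np.flatnonzero(np.diff(voiced.astype(int)))
    n_voiced_segments = int(voiced[0]) + int((np.diff(voiced.astype(int)) == 1).sum()) if n else 0
    seg_lengths = np.diff(np.concatenate([[0], transitions + 1, [n]])) if n else np.array([])
    seg_voiced = voiced[np.concatenate([[0], transitions + 1])] if n else np.array([])
    mean_voiced_s = float(seg_lengths[seg_voiced].mean() * hop_s) if np.any(seg_voiced) else 0.0
    mean_unvoiced_s = float(seg_lengths[~seg_voiced].mean() * hop_s) if np.any(~seg_voiced) else 0.0
    silence_thresh = energy_db.max() - 35.0
    silence_frac = float((energy_db < silence_thresh).mean())
    peaks = (np.diff(np.sign(np.diff(energy_db))) < 0).sum()
    features.extend([
        voiced_frac, n_voiced_segments / dur, mean_voiced_s, mean_unvoiced_s,
        silence_frac, peaks / dur, dur, float(np.sqrt(np.mean(w.samples ** 2))),
    ])
    out = np.asarray(features, dtype=np.float64)
    assert out.shape == (N_FEATURES,)
    if not np.all(np.isfinite(out)):
        raise InvalidAudioError("non-finite acoustic functionals")
    return out


class AcousticProjector(nn.Module):
    """Learnable 88 -> 256 linear map, initialized small."""

    def __init__(self, rng: np.random.Generator,
                 in_dim: int = N_FEATURES, out_dim: int = ACOUSTIC_PROJ_DIM):
        super().__init__()
        self.linear = nn.Linear(in_dim, out_dim, rng, scale=0.01)

    def __call__(self, a: Tensor) -> Tensor:
        return self.linear(a)


def project_and_tile(a: np.ndarray, n_tokens: int,
                     projector: AcousticProjector) -> np.ndarray:
    """Project the 88-vector to 256-d and repeat it once per token (rows
    identical by construction)."""
    a = np.asarray(a, dtype=np.float64)
    if a.shape != (N_FEATURES,):
        raise ValueError(f"expected ({N_FEATURES},) acoustic vector, got {a.shape}")
    row = projector(Tensor(a.reshape(1, -1))).data
    return np.repeat(row, n_tokens, axis=0)


def tile_rows(row: Tensor, n: int) -> Tensor:
    """Differentiable tiling of a (1, d) tensor to (n, d)."""
    ones = Tensor(np.ones((n, 1)))
    return ones @ row
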