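"""Synthetic picture-description corpora (WAV + CHAT + metadata).

The generator emulates the *structure* of a balanced dementia-screening
corpus — one recording and one CHAT transcript per subject, AD/HC groups of
configurable proportion, MMSE scores tied to group (HC in 25-30, AD below
25) — with a controllable group signal.  A per-subject severity scalar
derived from the MMSE drives three effects in both modalities:

* pauses: AD speech gets more and longer inter-utterance silences
  (``pause_rate_delta`` extra pauses per utterance at full severity);
* speech rate: syllable rate drops by ``speech_rate_delta`` syllables/s at
  full severity;
* vocabulary: the word pool shrinks by ``vocabulary_shrink`` at full
  severity, and retraced repetitions ("the boy [/] the boy ...") appear.

Audio is synthesized as harmonic syllable tones with amplitude envelopes
separated by silences — not realistic speech, but it carries the pause and
rate statistics an energy-based analysis can recover.  Setting all three
deltas to 0 removes every group difference from the signals while keeping
the MMSE/group link, which is the null condition for calibration checks.

Everything is deterministic from the corpus seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.io import wavfile

DEFAULT_SAMPLE_RATE = 16_000


@dataclass(frozen=True)
class SignalSpec:
    """Group-effect sizes at full severity."""

    pause_rate_delta: float = 1.5     # extra pauses per utterance
    speech_rate_delta: float = 1.2    # syllables/s slowdown
    vocabulary_shrink: float = 0.5    # fraction of the word pool lost

    def is_null(self) -> bool:
        return (self.pause_rate_delta == 0 and self.speech_rate_delta == 0
                and self.vocabulary_shrink == 0)


@dataclass(frozen=True)
class CorpusSpec:
    n_subjects: int = 24
    ad_fraction: float = 0.5
    seed: int = 0
    signal: SignalSpec = field(default_factory=SignalSpec)
    duration_s: float = 30.0
    sample_rate: int = DEFAULT_SAMPLE_RATE

    def __post_init__(self):
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be non-negative")
        if not 0.0 <= self.ad_fraction <= 1.0:
            raise ValueError("ad_fraction must be in [0, 1]")
        if self.duration_s <= 1.0:
            raise ValueError("duration_s must exceed 1 s")


@dataclass(frozen=True)
class SyntheticSubject:
    id: str
    group: str                 # "AD" | "HC"
    mmse: int
    wav_path: Path
    cha_path: Path

    @property
    def label(self) -> int:
        return 1 if self.group == "AD" else 0


# MMSE bands: HC clustered high-normal, AD in the moderate range
# (cohort-typical AD mean around 17).  Severity in [0, 1] is derived from
# the score so speech effects and the regression target stay coupled.
def _draw_mmse(rng: np.random.Generator, group: str) -> int:
    if group == "HC":
        return int(np.clip(round(rng.normal(28.0, 1.2)), 25, 30))
    return int(np.clip(round(rng.normal(17.0, 2.5)), 10, 24))


def _severity(mmse: int) -> float:
    return float(np.clip((30 - mmse) / 20.0, 0.0, 1.0))


_WORD_POOL = [
    "mother", "window", "cookie", "jar", "stool", "boy", "girl", "water",
    "sink", "plate", "curtain", "kitchen", "garden", "dish", "cupboard",
    "overflowing", "reaching", "falling", "washing", "drying", "standing",
    "laughing", "outside", "little", "tall", "open", "wet", "full", "busy",
    "quiet", "chair", "floor", "towel", "apron", "shoes", "summer", "tree",
    "path", "fence", "cloud",
]

_TEMPLATES = [
    "the {a} is {v} near the {b}",
    "I see a {a} and a {b}",
    "there is a {a} {v} by the {b}",
    "the {a} looks {adj} today",
    "a {adj} {a} stands beside the {b}",
    "well the {a} keeps {v} the {b}",
]

_ADJ = ["little", "tall", "open", "wet", "full", "busy", "quiet"]
_VERBS = ["falling", "reaching", "washing", "drying", "standing", "laughing",
          "overflowing"]


def _make_utterances(rng: np.random.Generator, severity: float,
                     signal: SignalSpec, n_utterances: int) -> List[str]:
    pool_n = max(6, int(round(len(_WORD_POOL) *
                              (1.0 - signal.vocabulary_shrink * severity))))
    pool = _WORD_POOL[:pool_n]
    utterances = []
    for _ in range(n_utterances):
        tmpl = _TEMPLATES[rng.integers(len(_TEMPLATES))]
        words = {
            "a": pool[rng.integers(len(pool))],
            "b": pool[rng.integers(len(pool))],
            "v": _VERBS[rng.integers(len(_VERBS))],
            "adj": _ADJ[rng.integers(len(_ADJ))],
        }
        text = tmpl.format(**words)
        # retraced repetition of the opening words, more likely when severe
        if rng.random() < 0.6 * severity * (1 if not signal.is_null() else 0):
            lead = " ".join(text.split()[:2])
            text = f"<{lead}> [/] {text}"
        utterances.append(text + " .")
    return utterances


def _synth_audio(rng: np.random.Generator, spec: CorpusSpec,
                 severity: float, n_utterances: int) -> np.ndarray:
    """Harmonic syllable tones grouped into utterances separated by pauses."""
    sr = spec.sample_rate
    sig = spec.signal
    syll_rate = max(4.0 - sig.speech_rate_delta * severity, 1.0)  # syllables/s
    base_pause = 0.35
    extra_pauses = sig.pause_rate_delta * severity
    total = int(spec.duration_s * sr)
    out = np.zeros(total)
    t = 0
    f0_base = rng.uniform(110.0, 220.0)
    while t < total:
        n_syll = int(rng.integers(4, 9))
        for _ in range(n_syll):
            dur = rng.uniform(0.8, 1.2) / syll_rate
            voiced = int(min(dur * 0.7, 0.25) * sr)
            if t + voiced >= total:
                t = total
                break
            tt = np.arange(voiced) / sr
            f0 = f0_base * rng.uniform(0.9, 1.15)
            tone = (np.sin(2 * np.pi * f0 * tt)
                    + 0.5 * np.sin(2 * np.pi * 2 * f0 * tt)
                    + 0.25 * np.sin(2 * np.pi * 3 * f0 * tt))
            env = np.sin(np.pi * np.arange(voiced) / voiced) ** 0.8
            out[t:t + voiced] += 0.3 * tone * env
            t += int(dur * sr)
        # inter-utterance pause, lengthened/multiplied with severity
        n_pauses = 1 + rng.poisson(extra_pauses)
        pause = base_pause * n_pauses * rng.uniform(0.8, 1.3)
        t += int(pause * sr)
    out += 1e-4 * rng.standard_normal(total)          # low noise floor
    peak = np.abs(out).max()
    if peak > 0:
        out = 0.9 * out / peak
    return out


def _write_cha(path: Path, subject_id: str, group: str,
               utterances: List[str]) -> None:
    mmse_role = "Participant"
    lines = [
        "@UTF8",
        "@Begin",
        "@Languages:\teng",
        "@Participants:\tPAR Participant, INV Investigator",
        f"@ID:\teng|synthetic|{subject_id}||{'' if group == 'HC' else ''}|||{mmse_role}|||",
        "@Media:\t" + subject_id + ", audio",
    ]
    lines.append("*INV:\tplease tell me what you see in the picture .")
    for u in utterances:
        lines.append(f"*PAR:\t{u}")
    lines.append("@End")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def generate_corpus(spec: CorpusSpec, out_dir) -> Tuple[List[SyntheticSubject], Path]:
    """Write one WAV + one CHA per subject plus ``metadata.csv``
    (columns ``id,label,mmse``); returns the subjects and the CSV path.

    Deterministic: identical spec -> byte-identical transcripts/metadata and
    identical audio.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    n_ad = int(round(spec.n_subjects * spec.ad_fraction))
    groups = ["AD"] * n_ad + ["HC"] * (spec.n_subjects - n_ad)
    subjects: List[SyntheticSubject] = []
    rows = []
    for i, group in enumerate(groups):
        sid = f"S{i:03d}"
        mmse = _draw_mmse(rng, group)
        severity = _severity(mmse) if not spec.signal.is_null() else 0.0
        n_utts = int(rng.integers(6, 11))
        utterances = _make_utterances(rng, severity, spec.signal, n_utts)
        audio = _synth_audio(rng, spec, severity, n_utts)
        wav_path = out_dir / f"{sid}.wav"
        cha_path = out_dir / f"{sid}.cha"
        wavfile.write(wav_path, spec.sample_rate,
                      (audio * 32767).astype(np.int16))
        _write_cha(cha_path, sid, group, utterances)
        subjects.append(SyntheticSubject(sid, group, mmse, wav_path, cha_path))
        rows.append({"id": sid, "label": 1 if group == "AD" else 0, "mmse": mmse})
    csv_path = out_dir / "metadata.csv"
    pd.DataFrame(rows, columns=["id", "label", "mmse"]).to_csv(csv_path, index=False)
    return subjects, csv_path


def silence_fraction(samples: np.ndarray, sample_rate: int,
                     frame_s: float = 0.025, threshold_db: float = -35.0) -> float:
    """Independent energy-threshold silence detector: fraction of frames
    whose RMS is below `threshold_db` relative to the loudest frame."""
    frame = int(frame_s * sample_rate)
    n = len(samples) // frame
    x = np.asarray(samples[: n * frame], dtype=np.float64).reshape(n, frame)
    rms = np.sqrt((x ** 2).mean(axis=1))
    db = 20 * np.log10(np.maximum(rms, 1e-10) / max(rms.max(), 1e-10))
    return float((db < threshold_db).mean())
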