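"""End-to-end feature preparation: corpus files -> model-ready samples."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .acoustic import extract_acoustic_functionals
from .audio import load_wav, waveform_to_image
from .chat import HashTokenizer, encode_text, parse_chat
from .corpus import SyntheticSubject
from .encoders import EncoderBundle
from .training import Sample


def prepare_sample(subject, n_tokens: int,
                   tokenizer: Optional[HashTokenizer] = None,
                   speakers: Sequence[str] = ("PAR",),
                   n_mels: int = 224) -> Sample:
    """Run both preprocessing front ends for one subject."""
    w = load_wav(subject.wav_path)
    image = waveform_to_image(w, n_mels=n_mels)
    transcript = parse_chat(subject.cha_path, speakers=speakers)
    enc = encode_text(transcript, max_len=n_tokens, tokenizer=tokenizer)
    acoustic = extract_acoustic_functionals(w)
    mmse = getattr(subject, "mmse", None)
    return Sample(subject_id=subject.id, token_ids=enc.token_ids,
                  pad_mask=enc.pad_mask, image=image.channels,
                  acoustic=acoustic, label=subject.label,
                  mmse=None if mmse is None else float(mmse))


def prepare_dataset(subjects: Sequence, bundle: EncoderBundle,
                    tokenizer: Optional[HashTokenizer] = None,
                    speakers: Sequence[str] = ("PAR",)) -> list[Sample]:
    """Preprocess every subject to the token length the bundle expects.
    Preprocessing is deterministic, so samples can be computed once and
    reused across models and repetitions."""
    tokenizer = tokenizer or HashTokenizer()
    return [prepare_sample(s, bundle.N, tokenizer, speakers) for s in subjects]


def load_metadata(csv_path) -> list[SyntheticSubject]:
    """Read a ``metadata.csv`` (columns id,label,mmse) with WAV/CHA files
    expected alongside it."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    root = csv_path.parent
    out = []
    for _, row in df.iterrows():
        mmse = row.get("mmse")
        out.append(SyntheticSubject(
            id=str(row["id"]),
            group="AD" if int(row["label"]) == 1 else "HC",
            mmse=int(mmse) if pd.notna(mmse) else None,
            wav_path=root / f"{row['id']}.wav",
            cha_path=root / f"{row['id']}.cha",
        ))
    return out
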