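"""CHAT (.cha) transcript parsing and fixed-length text encoding.

The parser extracts main-tier utterances (``*PAR:``, ``*INV:`` ...) in
document order, joins continuation lines, and strips CHAT inline annotation
down to plain spoken words: bracketed event/scoping codes (``[/]``,
``[: text]``, ``[* ...]`` ...), retracing angle brackets, pause codes,
fillers/events introduced by ``&``, and special-form suffixes (``word@x``).
Repetitions and word forms actually spoken are kept — disfluencies carry
clinical signal.  Utterance terminators (``.``, ``?``, ``!``) are kept as
tokens.

Encoding uses a deterministic hashing tokenizer (no external vocabulary):
tokens are lower-cased, mapped to ids by a stable digest, wrapped in
start/end specials, tail-truncated and padded to exactly ``max_len``.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np

DEFAULT_MAX_LEN = 512
DEFAULT_SPEAKERS = ("PAR",)


class ChatParseError(ValueError):
    def __init__(self, message: str, line_number: int):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


@dataclass(frozen=True)
class Transcript:
    subject_id: str
    utterances: Tuple[Tuple[str, str], ...]

    def text(self) -> str:
        return " ".join(t for _, t in self.utterances)


@dataclass(frozen=True)
class TextEncoding:
    token_ids: np.ndarray
    pad_mask: np.ndarray  # True = real token

    def __post_init__(self):
        ids = np.asarray(self.token_ids, dtype=np.int64)
        mask = np.asarray(self.pad_mask, dtype=bool)
        if ids.shape != mask.shape or ids.ndim != 1:
            raise ValueError("token_ids and pad_mask must be equal-length vectors")
        object.__setattr__(self, "token_ids", ids)
        object.__setattr__(self, "pad_mask", mask)

    def __len__(self) -> int:
        return int(self.token_ids.size)


_BRACKET_RE = re.compile(r"\[[^\]]*\]")
_PAUSE_RE = re.compile(r"\(\.{1,3}\)")
_TERMINATOR_RE = re.compile(r"(\+\S*|[.?!])\s*$")


def _clean_utterance(raw: str) -> str:
    """Strip CHAT inline annotation, keep spoken words and the terminator."""
    text = raw.strip()
    term_match = _TERMINATOR_RE.search(text)
    terminator = ""
    if term_match:
        tok = term_match.group(1)
        # normalize special terminators (+//. +... etc.) to their final mark
        terminator = tok[-1] if tok[-1] in ".?!" else ""
        text = text[: term_match.start()]
    text = text.replace("\x15", " ")                  # time-alignment bullets
    text = re.sub(r"\x15\d+_\d+\x15", " ", text)
    text = _PAUSE_RE.sub(" ", text)                   # (.) (..) pauses
    text = _BRACKET_RE.sub(" ", text)                 # [/] [: x] [* e] [% com] ...
    text = text.replace("<", " ").replace(">", " ")   # retracing scopes
    words: List[str] = []
    for token in text.split():
        if token.startswith("&"):                     # events &=laughs, fillers &-uh
            continue
        if token in {"xxx", "yyy", "www"}:            # unintelligible material
            continue
        token = re.sub(r"@[a-z:$]+$", "", token)      # special-form markers word@x
        token = token.replace("(", "").replace(")", "")  # shortenings (be)cause
        token = token.strip("“”\"'‡„+^")
        if token:
            words.append(token)
    out = " ".join(words)
    if terminator:
        out = f"{out} {terminator}".strip()
    return out


def parse_chat(path, speakers: Sequence[str] = DEFAULT_SPEAKERS) -> Transcript:
    """Parse a CHAT file, returning utterances of the requested speaker tiers.

    Raises :class:`ChatParseError` (with a line number) for files that do not
    follow the CHAT line grammar or lack the ``@Begin`` header.  A file with
    no utterances for the requested tiers yields an empty transcript.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    speakers = {s.upper() for s in speakers}
    utterances: List[Tuple[str, str]] = []
    subject_id = path.stem
    seen_begin = False
    current: Tuple[str, List[str]] | None = None

    def flush():
        nonlocal current
        if current is not None:
            code, parts = current
            cleaned = _clean_utterance(" ".join(parts))
            if cleaned:
                utterances.append((code, cleaned))
            current = None

    for i, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        head = line[0]
        if head == "@":
            flush()
            if line.startswith("@Begin"):
                seen_begin = True
            elif line.startswith("@ID"):
                # @ID: lang|corpus|code|age|sex|...|role|
                fields = line.split(":", 1)[-1].strip().split("|")
                if len(fields) >= 3 and fields[2]:
                    subject_id = fields[2]
            continue
        if head == "*":
            if not seen_begin:
                raise ChatParseError("utterance before @Begin header", i)
            flush()
            m = re.match(r"\*([A-Z0-9]+):\s*(.*)$", line)
            if m is None:
                raise ChatParseError("malformed main tier line", i)
            code, rest = m.group(1), m.group(2)
            current = (code, [rest]) if code in speakers else None
            continue
        if head == "%":
            flush()
            continue  # dependent tiers (%mor, %gra ...) are ignored
        if head in ("\t", " "):
            if current is not None:
                current[1].append(line.strip())
            continue
        raise ChatParseError(f"unrecognized line start {head!r}", i)
    flush()
    if not seen_begin:
        raise ChatParseError("missing @Begin header", 1)
    return Transcript(subject_id=subject_id, utterances=tuple(utterances))


class HashTokenizer:
    """Deterministic vocabulary-free tokenizer.

    Ids: 0 = [PAD], 1 = [CLS], 2 = [SEP]; words hash into [3, vocab_size).
    The mapping is stable across processes (MD5-based, not `hash()`).
    """

    PAD, CLS, SEP = 0, 1, 2
    _N_SPECIAL = 3

    def __init__(self, vocab_size: int = 2000):
        if vocab_size <= self._N_SPECIAL:
            raise ValueError("vocab_size too small")
        self.vocab_size = vocab_size

    def token_to_id(self, token: str) -> int:
        digest = hashlib.md5(token.lower().encode("utf-8")).digest()
        span = self.vocab_size - self._N_SPECIAL
        return self._N_SPECIAL + int.from_bytes(digest[:8], "big") % span

    def tokenize(self, text: str) -> List[str]:
        return text.split()

    def encode_ids(self, text: str) -> List[int]:
        return [self.token_to_id(t) for t in self.tokenize(text)]


def encode_text(transcript: Transcript, max_len: int = DEFAULT_MAX_LEN,
                tokenizer: HashTokenizer | None = None) -> TextEncoding:
    """Tokenize the concatenated utterance text, wrap in [CLS]/[SEP],
    tail-truncate to and pad to exactly `max_len` tokens."""
    if max_len < 2:
        raise ValueError("max_len must be >= 2 (room for [CLS] and [SEP])")
    tokenizer = tokenizer or HashTokenizer()
    body = tokenizer.encode_ids(transcript.text())
    body = body[: max_len - 2]
    ids = [tokenizer.CLS] + body + [tokenizer.SEP]
    n_real = len(ids)
    ids = ids + [tokenizer.PAD] * (max_len - n_real)
    mask = np.arange(max_len) < n_real
    return TextEncoding(np.asarray(ids, dtype=np.int64), mask)
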