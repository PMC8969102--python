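"""Text and image encoders behind a uniform (N x d / T x d) contract.

The fusion architectures only depend on two facts: the text encoder maps a
length-N token encoding to an N x d matrix of contextual embeddings, and the
image encoder maps a 3-channel square image to T x d patch embeddings whose
row 0 is the class-token summary.  Under full-replication defaults those are
BERT-base and ViT-B/16 (d = 768, N = 512, T = 197 for 224 x 224 images with
16 x 16 patches); for desk-scale work :func:`build_tiny_encoders` provides
small randomly-initialized transformer encoders honoring the same contract,
reproducible from a seed.  Only the tiny grade is constructible offline;
requesting the pretrained grade raises an explicit error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from ._tensor import Tensor, concat
from . import nn
from .audio import SpectrogramImage
from .chat import TextEncoding

DEFAULT_HIDDEN = 768
DEFAULT_N = 512
DEFAULT_T = 197


class TinyTextEncoder(nn.Module):
    """Small transformer over token ids: embeddings + learned positions +
    pre-norm blocks + final layer norm.  Pad keys are masked out of
    attention, so pad content cannot leak into real-token rows."""

    def __init__(self, vocab_size: int, d: int, max_len: int,
                 rng: np.random.Generator, n_layers: int = 2,
                 mask_padding: bool = True):
        super().__init__()
        self.tok = nn.Embedding(vocab_size, d, rng)
        self.pos = nn.Embedding(max_len, d, rng)
        self.blocks = [nn.TransformerBlock(d, 4, rng) for _ in range(n_layers)]
        self.ln = nn.LayerNorm(d)
        self.d = d
        self.max_len = max_len
        self.mask_padding = mask_padding

    def __call__(self, token_ids: np.ndarray,
                 pad_mask: Optional[np.ndarray] = None) -> Tensor:
        token_ids = np.asarray(token_ids)
        if token_ids.shape != (self.max_len,):
            raise ValueError(
                f"expected token sequence of length {self.max_len}, got {token_ids.shape}")
        x = self.tok(token_ids) + self.pos(np.arange(self.max_len))
        return self.forward_embeddings(x, pad_mask)

    def forward_embeddings(self, x: Tensor,
                           pad_mask: Optional[np.ndarray] = None) -> Tensor:
        """Run the blocks on an externally built (N, d) embedding sequence.

        Used when upstream components (e.g. the shifting gate) construct the
        input embeddings themselves; positional information is added here so
        shifted embeddings stay position-aware."""
        key_mask = pad_mask if (self.mask_padding and pad_mask is not None) else None
        for block in self.blocks:
            x = block(x, key_mask)
        return self.ln(x)


class TinyImageEncoder(nn.Module):
    """ViT-style encoder: square patches -> linear projection -> class token
    -> transformer blocks; returns (T, d) with the class token at row 0."""

    def __init__(self, d: int, image_size: int, patch_shape: Tuple[int, int],
                 rng: np.random.Generator, n_channels: int = 3, n_layers: int = 2):
        super().__init__()
        ph, pw = patch_shape
        if image_size % ph != 0 or image_size % pw != 0:
            raise ValueError("image_size must be divisible by both patch sides")
        self.grid_h = image_size // ph
        self.grid_w = image_size // pw
        self.n_patches = self.grid_h * self.grid_w
        self.patch_proj = nn.Linear(n_channels * ph * pw, d, rng)
        self.cls = nn.Parameter(rng.normal(0.0, 0.02, (1, d)))
        self.pos = nn.Embedding(self.n_patches + 1, d, rng)
        self.blocks = [nn.TransformerBlock(d, 4, rng) for _ in range(n_layers)]
        self.ln = nn.LayerNorm(d)
        self.d = d
        self.image_size = image_size
        self.patch_shape = (ph, pw)

    @property
    def seq_len(self) -> int:
        return self.n_patches + 1

    def _patchify(self, channels: np.ndarray) -> np.ndarray:
        c, h, w = channels.shape
        ph, pw = self.patch_shape
        patches = channels.reshape(c, self.grid_h, ph, self.grid_w, pw)
        patches = patches.transpose(1, 3, 0, 2, 4).reshape(self.n_patches, c * ph * pw)
        return patches

    def __call__(self, image: np.ndarray) -> Tensor:
        channels = np.asarray(image, dtype=np.float64)
        if channels.shape[-1] != self.image_size or channels.shape[-2] != self.image_size:
            raise ValueError(
                f"expected {self.image_size}x{self.image_size} image, got {channels.shape}")
        x = self.patch_proj(Tensor(self._patchify(channels)))
        x = concat([self.cls + Tensor(np.zeros((1, self.d))), x], axis=0)
        x = x + self.pos(np.arange(self.seq_len))
        for block in self.blocks:
            x = block(x)
        return self.ln(x)


@dataclass
class EncoderBundle:
    """A matched text/image encoder pair plus the dims downstream code needs."""

    text_encoder: TinyTextEncoder
    image_encoder: TinyImageEncoder
    N: int
    T: int
    d: int
    grade: str = "tiny"
    seed: int = 0

    @property
    def dims(self) -> Tuple[int, int, int]:
        return (self.N, self.T, self.d)


def build_tiny_encoders(d: int = 32, N: int = 64, T: int = 17, seed: int = 0,
                        vocab_size: int = 2000, image_size: int = 224,
                        n_layers: int = 2, mask_padding: bool = True) -> EncoderBundle:
    """Construct seeded tiny encoders with shared hidden size `d`.

    The image encoder emits T-1 patches plus a class token; the patch grid
    is the most-square factorization gh x gw = T-1 whose sides divide
    `image_size`.
    """
    if min(d, N) < 1 or T < 2:
        raise ValueError("d, N must be >= 1 and T >= 2")
    grid = _pick_grid(T - 1, image_size)
    rng = np.random.default_rng(seed)
    text = TinyTextEncoder(vocab_size, d, N, rng, n_layers=n_layers,
                           mask_padding=mask_padding)
    image = TinyImageEncoder(d, image_size,
                             (image_size // grid[0], image_size // grid[1]),
                             rng, n_layers=n_layers)
    return EncoderBundle(text, image, N=N, T=T, d=d, grade="tiny", seed=seed)


def _pick_grid(n_patches: int, image_size: int) -> Tuple[int, int]:
    """Most-square (gh, gw) with gh*gw = n_patches and both dividing image_size."""
    best = None
    for gh in range(1, int(np.sqrt(n_patches)) + 1):
        if n_patches % gh == 0:
            gw = n_patches // gh
            if image_size % gh == 0 and image_size % gw == 0:
                best = (gh, gw)
    if best is None:
        raise ValueError(
            f"no patch grid with {n_patches} patches divides image size {image_size}")
    return best


def build_encoders(grade: str = "tiny", **kwargs) -> EncoderBundle:
    if grade == "tiny":
        return build_tiny_encoders(**kwargs)
    if grade == "pretrained":
        raise NotImplementedError(
            "pretrained encoder checkpoints (BERT base / ViT-B16) require the "
            "torch/transformers stack and network access; use grade='tiny'")
    raise ValueError(f"unknown encoder grade {grade!r}")


def encode_tokens(bundle: EncoderBundle, encoding: TextEncoding) -> np.ndarray:
    """Contextual token embeddings, shape (N, d).  Evaluation mode, no grad."""
    if len(encoding) != bundle.N:
        raise ValueError(f"encoding length {len(encoding)} != N={bundle.N}")
    was_training = bundle.text_encoder.training
    bundle.text_encoder.eval()
    try:
        out = bundle.text_encoder(encoding.token_ids, encoding.pad_mask).data.copy()
    finally:
        bundle.text_encoder.train(was_training)
    return out


def encode_image(bundle: EncoderBundle, image: SpectrogramImage | np.ndarray
                 ) -> Tuple[np.ndarray, np.ndarray]:
    """Patch embeddings (T, d) plus the pooled class vector (row 0)."""
    channels = image.channels if isinstance(image, SpectrogramImage) else np.asarray(image)
    was_training = bundle.image_encoder.training
    bundle.image_encoder.eval()
    try:
        values = bundle.image_encoder(channels).data.copy()
    finally:
        bundle.image_encoder.train(was_training)
    if values.shape[0] != bundle.T:
        raise ValueError(f"image encoder produced {values.shape[0]} tokens, expected {bundle.T}")
    return values, values[0:1].copy()
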