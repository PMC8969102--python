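"""Gated self-attention over the concatenated text+image token sequence.

The text rows X (N x d) and image rows Y (T x d, class token included) are
stacked into Z = [X; Y] (m x d, m = N + T) which serves as query, key and
value simultaneously.  Learned sigmoid masks modulate queries and keys
before the dot product:

    M        = sigmoid(FC_g(FC_qg(Q) * FC_kg(K)))      m x 2, entries in (0,1)
    Mq~, Mk~ = columns of M tiled across the d features
    A_g      = softmax((Q * Mq~)(K * Mk~)^T / sqrt(d))  row-wise over keys
    H        = A_g V

so the layer can attenuate individual positions on both sides of every
intra- and inter-modal interaction.  H is mean-pooled over the m positions,
passed through dropout (0.3), a 128-unit ReLU layer, and the task head.
Pad positions are left in the sequence by default (optional masking flag).
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np

from ._tensor import Tensor, concat
from . import nn
from .encoders import EncoderBundle

DEFAULT_DG = 64


class GatedSelfAttention(nn.Module):
    """The mask-gated scaled dot-product core."""

    def __init__(self, d: int, d_g: int, rng: np.random.Generator):
        super().__init__()
        self.fc_qg = nn.Linear(d, d_g, rng)
        self.fc_kg = nn.Linear(d, d_g, rng)
        self.fc_g = nn.Linear(d_g, 2, rng)
        self.d = d
        self.d_g = d_g

    def masks(self, Q: Tensor, K: Tensor) -> Tuple[Tensor, Tensor, Tensor]:
        M = self.fc_g(self.fc_qg(Q) * self.fc_kg(K)).sigmoid()    # m x 2
        m = M.shape[0]
        ones = Tensor(np.ones((1, self.d)))
        Mq_t = M[:, 0:1] @ ones                                   # m x d
        Mk_t = M[:, 1:2] @ ones
        return M, Mq_t, Mk_t

    def attend(self, Q: Tensor, K: Tensor, V: Tensor,
               Mq_t: Tensor, Mk_t: Tensor,
               key_mask: Optional[np.ndarray] = None) -> Tuple[Tensor, Tensor]:
        scores = ((Q * Mq_t) @ (K * Mk_t).T) * (1.0 / np.sqrt(self.d))
        if key_mask is not None:
            bias = np.where(np.asarray(key_mask, bool), 0.0, -1e9)[None, :]
            scores = scores + Tensor(bias)
        A_g = scores.softmax(axis=-1)
        return A_g, A_g @ V

    def __call__(self, Z: Tensor,
                 key_mask: Optional[np.ndarray] = None) -> Tuple[Tensor, Tensor]:
        Q = K = V = Z
        _, Mq_t, Mk_t = self.masks(Q, K)
        return self.attend(Q, K, V, Mq_t, Mk_t, key_mask)


class GatedSelfAttentionModel(nn.Module):
    """Full architecture: encoders, concatenation, gated self-attention,
    global average pooling, head."""

    def __init__(self, bundle: EncoderBundle, task: str = "classification",
                 d_g: int = DEFAULT_DG, seed: int = 0, mask_pad_tokens: bool = False):
        super().__init__()
        if task not in ("classification", "regression"):
            raise ValueError("task must be 'classification' or 'regression'")
        rng = np.random.default_rng(seed)
        d = bundle.d
        self.text_encoder = bundle.text_encoder
        self.image_encoder = bundle.image_encoder
        self.core = GatedSelfAttention(d, d_g, rng)
        self.drop_pool = nn.Dropout(0.3, rng)
        self.fc = nn.Linear(d, 128, rng)
        self.out = nn.Linear(128, 2 if task == "classification" else 1, rng)
        self.task = task
        self.mask_pad_tokens = mask_pad_tokens
        self.N, self.T = bundle.N, bundle.T

    def __call__(self, token_ids: np.ndarray, pad_mask: np.ndarray,
                 image: np.ndarray, acoustic: Optional[np.ndarray] = None) -> Tensor:
        X = self.text_encoder(token_ids, pad_mask)
        Y = self.image_encoder(image)
        Z = concat([X, Y], axis=0)
        key_mask = None
        if self.mask_pad_tokens:
            key_mask = np.concatenate([np.asarray(pad_mask, bool),
                                       np.ones(self.T, bool)])
        _, H = self.core(Z, key_mask)
        pooled = H.mean(axis=0, keepdims=True)         # 1 x d
        z = self.fc(self.drop_pool(pooled)).relu()
        logits = self.out(z)
        if self.task == "regression":
            logits = logits.relu()
        return logits


# -- functional facade ----------------------------------------------------

def concat_modalities(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Z = [X; Y], text rows first.  Q = K = V = Z."""
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[1] != Y.shape[1]:
        raise ValueError("X and Y must be 2-D with a shared feature dimension")
    if X.shape[0] == 0 or Y.shape[0] == 0:
        raise ValueError("both modalities must contribute at least one row")
    return np.concatenate([X, Y], axis=0)


def compute_masks(Q: np.ndarray, K: np.ndarray,
                  W_qg: np.ndarray, b_qg: np.ndarray,
                  W_kg: np.ndarray, b_kg: np.ndarray,
                  W_g: np.ndarray, b_g: np.ndarray):
    """(M, Mq_t, Mk_t): sigmoid 2-channel masks and their d-wide tilings."""
    Q = np.asarray(Q, dtype=np.float64)
    K = np.asarray(K, dtype=np.float64)
    prod = (Q @ W_qg + b_qg) * (K @ W_kg + b_kg)
    M = 1.0 / (1.0 + np.exp(-(prod @ W_g + b_g)))
    d = Q.shape[1]
    return M, np.tile(M[:, 0:1], (1, d)), np.tile(M[:, 1:2], (1, d))


def gated_attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray,
                    Mq_t: np.ndarray, Mk_t: np.ndarray):
    """(A_g, H) with A_g the row-wise softmax of (Q*Mq~)(K*Mk~)^T / sqrt(d)."""
    Q, K, V = (np.asarray(a, dtype=np.float64) for a in (Q, K, V))
    d = Q.shape[1]
    scores = (Q * Mq_t) @ (K * Mk_t).T / np.sqrt(d)
    A_g = Tensor(scores).softmax(axis=-1).data
    return A_g, A_g @ V
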