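"""Co-attention fusion of text-token and image-patch embeddings.

With text C in R^(d x N) (columns are tokens) and image S in R^(d x T)
(columns are patches, class token included), the mechanism computes

    F   = tanh(C^T W_l S)                    affinity, N x T
    H_s = tanh(W_s S + (W_c C) F)            image attention map, k x T
    H_c = tanh(W_c C + (W_s S) F^T)          text attention map,  k x N
    a_s = softmax(w_hs^T H_s)                image weights, 1 x T
    a_c = softmax(w_hc^T H_c)                text weights,  1 x N
    s_hat = sum_i a_s[i] s_i,  c_hat = sum_j a_c[j] c_j,  p = [s_hat ; c_hat]

so each modality attends over the other through the shared affinity.  The
package stores sequences tokens-by-features (N x d / T x d) everywhere and
transposes at this module's boundary.

The classifier head is: dropout(0.4) on p, dense 128 + ReLU, dropout(0.2),
then 2 logits (detection) or a single ReLU unit (score regression).
Attention is left unmasked over pad positions by default (an optional flag
excludes them from the text softmax).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._tensor import Tensor, concat
from . import nn
from .encoders import EncoderBundle

DEFAULT_K = 40


@dataclass
class CoAttentionOutput:
    F: np.ndarray
    H_s: np.ndarray
    H_c: np.ndarray
    a_s: np.ndarray
    a_c: np.ndarray
    s_hat: np.ndarray
    c_hat: np.ndarray
    p: np.ndarray


class CoAttention(nn.Module):
    """Learnable co-attention core (Ws, Wc, Wl, w_hs, w_hc)."""

    def __init__(self, d: int, k: int, rng: np.random.Generator,
                 mask_pad_tokens: bool = False):
        super().__init__()
        scale = 1.0 / np.sqrt(d)
        self.W_l = nn.Parameter(rng.uniform(-scale, scale, (d, d)))
        self.W_s = nn.Parameter(rng.uniform(-scale, scale, (k, d)))
        self.W_c = nn.Parameter(rng.uniform(-scale, scale, (k, d)))
        ks = 1.0 / np.sqrt(k)
        self.w_hs = nn.Parameter(rng.uniform(-ks, ks, (k, 1)))
        self.w_hc = nn.Parameter(rng.uniform(-ks, ks, (k, 1)))
        self.mask_pad_tokens = mask_pad_tokens

    def __call__(self, C: Tensor, S: Tensor,
                 pad_mask: Optional[np.ndarray] = None) -> tuple[Tensor, ...]:
        """C: (d, N) text, S: (d, T) image -> (F, H_s, H_c, a_s, a_c, s_hat, c_hat, p)."""
        F = (C.T @ self.W_l @ S).tanh()
        WcC = self.W_c @ C
        WsS = self.W_s @ S
        H_s = (WsS + WcC @ F).tanh()
        H_c = (WcC + WsS @ F.T).tanh()
        logit_s = self.w_hs.T @ H_s            # 1 x T
        logit_c = self.w_hc.T @ H_c            # 1 x N
        if self.mask_pad_tokens and pad_mask is not None:
            bias = np.where(np.asarray(pad_mask, bool), 0.0, -1e9)[None, :]
            logit_c = logit_c + Tensor(bias)
        a_s = logit_s.softmax(axis=-1)
        a_c = logit_c.softmax(axis=-1)
        s_hat = a_s @ S.T                      # 1 x d
        c_hat = a_c @ C.T                      # 1 x d
        p = concat([s_hat, c_hat], axis=1)     # 1 x 2d
        return F, H_s, H_c, a_s, a_c, s_hat, c_hat, p


class CoAttentionModel(nn.Module):
    """Full architecture: text encoder + image encoder + co-attention + head."""

    def __init__(self, bundle: EncoderBundle, task: str = "classification",
                 k: int = DEFAULT_K, seed: int = 0,
                 mask_pad_tokens: bool = False):
        super().__init__()
        if task not in ("classification", "regression"):
            raise ValueError("task must be 'classification' or 'regression'")
        rng = np.random.default_rng(seed)
        d = bundle.d
        self.bundle_text = bundle.text_encoder
        self.bundle_image = bundle.image_encoder
        self.core = CoAttention(d, k, rng, mask_pad_tokens=mask_pad_tokens)
        self.drop_fused = nn.Dropout(0.4, rng)
        self.fc = nn.Linear(2 * d, 128, rng)
        self.drop_head = nn.Dropout(0.2, rng)
        self.out = nn.Linear(128, 2 if task == "classification" else 1, rng)
        self.task = task

    def __call__(self, token_ids: np.ndarray, pad_mask: np.ndarray,
                 image: np.ndarray, acoustic: Optional[np.ndarray] = None) -> Tensor:
        X = self.bundle_text(token_ids, pad_mask)      # N x d
        Y = self.bundle_image(image)                   # T x d
        *_, p = self.core(X.T, Y.T, pad_mask)
        h = self.fc(self.drop_fused(p)).relu()
        logits = self.out(self.drop_head(h))
        if self.task == "regression":
            logits = logits.relu()
        return logits


# -- functional facade (numpy in / numpy out) ----------------------------

def compute_affinity(C: np.ndarray, S: np.ndarray, W_l: np.ndarray) -> np.ndarray:
    """F = tanh(C^T W_l S), entries in (-1, 1)."""
    C, S, W_l = (np.asarray(a, dtype=np.float64) for a in (C, S, W_l))
    d = C.shape[0]
    if S.shape[0] != d or W_l.shape != (d, d):
        raise ValueError("dimension mismatch: C is d x N, S is d x T, W_l is d x d")
    return np.tanh(C.T @ W_l @ S)


def compute_attention_distributions(C: np.ndarray, S: np.ndarray, F: np.ndarray,
                                    W_s: np.ndarray, W_c: np.ndarray,
                                    w_hs: np.ndarray, w_hc: np.ndarray):
    """(H_s, H_c, a_s, a_c) for a given affinity F."""
    C, S, F = (np.asarray(a, dtype=np.float64) for a in (C, S, F))
    if F.shape != (C.shape[1], S.shape[1]):
        raise ValueError("F must be N x T, consistent with C and S")
    WcC, WsS = W_c @ C, W_s @ S
    H_s = np.tanh(WsS + WcC @ F)
    H_c = np.tanh(WcC + WsS @ F.T)
    a_s = Tensor(np.asarray(w_hs).reshape(-1, 1).T @ H_s).softmax(-1).data
    a_c = Tensor(np.asarray(w_hc).reshape(-1, 1).T @ H_c).softmax(-1).data
    return H_s, H_c, a_s, a_c


def attend_and_fuse(C: np.ndarray, S: np.ndarray,
                    a_s: np.ndarray, a_c: np.ndarray):
    """(s_hat, c_hat, p): attention-weighted modality vectors and their concat."""
    s_hat = (np.asarray(a_s).reshape(1, -1) @ np.asarray(S).T)
    c_hat = (np.asarray(a_c).reshape(1, -1) @ np.asarray(C).T)
    return s_hat, c_hat, np.concatenate([s_hat, c_hat], axis=1)
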