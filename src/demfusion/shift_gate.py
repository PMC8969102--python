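"""Multimodal shifting gate: inject visual/acoustic information into word
embeddings before a second text-encoder pass.

Per token i, with word embedding e(i) from a frozen text encoder, tiled
image class vector h_v(i) and tiled projected acoustic vector h_a(i):

    w_v(i) = sigmoid(W_hv [h_v(i); e(i)] + b_v)          visual gate, in (0,1)^d
    w_a(i) = sigmoid(W_ha [h_a(i); e(i)] + b_a)          acoustic gate
    h_m(i) = w_v(i) * (W_v h_v(i)) + w_a(i) * (W_a h_a(i)) + b_m
    alpha  = min(beta * ||e(i)||_2 / (||h_m(i)||_2 + eps), 1)
    e_m(i) = e(i) + alpha * h_m(i)

followed by layer normalization and dropout (0.4), after which the shifted
sequence is fed to a second, trainable text encoder; its class-token output
goes through dropout (0.2), a 128-unit ReLU layer, and the task head.

Variants: "acoustic" keeps only the acoustic term, "visual" only the visual
term, "both" keeps both.  beta defaults to 0.01 (acoustic, both) or 0.001
(visual).  Gates live in the d-dimensional shift space (the element-wise
product in the shift equation forces this); b_m is a single bias vector
shared across token positions.
"""

from __future__ import annotations

import copy
from typing import Optional

import numpy as np

from ._tensor import Tensor, concat
from . import nn
from .acoustic import ACOUSTIC_PROJ_DIM, AcousticProjector, tile_rows
from .encoders import EncoderBundle

EPSILON = 1e-9
DEFAULT_BETAS = {"acoustic": 0.01, "visual": 0.001, "both": 0.01}
VARIANTS = tuple(DEFAULT_BETAS)


class ShiftGateConfigError(ValueError):
    """Raised when the chosen variant lacks its modality input."""


class ShiftGate(nn.Module):
    """The gating/shift core operating on (N, d) token rows."""

    def __init__(self, d: int, rng: np.random.Generator,
                 variant: str = "both", beta: Optional[float] = None,
                 acoustic_dim: int = ACOUSTIC_PROJ_DIM, epsilon: float = EPSILON):
        super().__init__()
        if variant not in VARIANTS:
            raise ShiftGateConfigError(f"unknown variant {variant!r}")
        self.variant = variant
        self.beta = DEFAULT_BETAS[variant] if beta is None else float(beta)
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        self.epsilon = float(epsilon)
        scale = 0.05
        if variant in ("visual", "both"):
            self.W_hv = nn.Linear(2 * d, d, rng, scale=scale)
            self.W_v = nn.Linear(d, d, rng, bias=False, scale=scale)
        if variant in ("acoustic", "both"):
            self.W_ha = nn.Linear(acoustic_dim + d, d, rng, scale=scale)
            self.W_a = nn.Linear(acoustic_dim, d, rng, bias=False, scale=scale)
        self.b_m = nn.Parameter(np.zeros(d))

    def __call__(self, e: Tensor, h_v: Optional[Tensor],
                 h_a: Optional[Tensor]) -> tuple[Tensor, Tensor, Tensor]:
        """e: (N, d); h_v: (N, d) or None; h_a: (N, 256) or None.

        Returns (alpha (N,1), h_m (N,d), e_m (N,d))."""
        if self.variant in ("visual", "both") and h_v is None:
            raise ShiftGateConfigError(f"variant {self.variant!r} needs a visual input")
        if self.variant in ("acoustic", "both") and h_a is None:
            raise ShiftGateConfigError(f"variant {self.variant!r} needs an acoustic input")
        h_m = Tensor(np.zeros(e.shape)) + self.b_m  # bias broadcast over tokens
        if self.variant in ("visual", "both"):
            gate_v = self.W_hv(concat([h_v, e], axis=1)).sigmoid()
            h_m = h_m + gate_v * self.W_v(h_v)
        if self.variant in ("acoustic", "both"):
            gate_a = self.W_ha(concat([h_a, e], axis=1)).sigmoid()
            h_m = h_m + gate_a * self.W_a(h_a)
        e_norm = e.norm(axis=1, keepdims=True)
        h_norm = h_m.norm(axis=1, keepdims=True)
        alpha = (e_norm * self.beta / (h_norm + self.epsilon)).clip_max(1.0)
        e_m = e + alpha * h_m
        return alpha, h_m, e_m


class MultimodalShiftModel(nn.Module):
    """Frozen first text encoder -> shifting gate -> trainable second text
    encoder (initialized from the first's weights) -> head."""

    def __init__(self, bundle: EncoderBundle, task: str = "classification",
                 variant: str = "both", beta: Optional[float] = None, seed: int = 0):
        super().__init__()
        if task not in ("classification", "regression"):
            raise ValueError("task must be 'classification' or 'regression'")
        rng = np.random.default_rng(seed)
        d = bundle.d
        self.frozen_encoder = bundle.text_encoder
        self.frozen_encoder.freeze()
        self.second_encoder = copy.deepcopy(bundle.text_encoder)
        for p in self.second_encoder.parameters():
            p.requires_grad = True
        self.image_encoder = bundle.image_encoder
        self.image_encoder.freeze()
        self.acoustic_proj = AcousticProjector(rng) if variant in ("acoustic", "both") else None
        self.gate = ShiftGate(d, rng, variant=variant, beta=beta)
        self.ln = nn.LayerNorm(d)
        self.drop_shift = nn.Dropout(0.4, rng)
        self.drop_cls = nn.Dropout(0.2, rng)
        self.fc = nn.Linear(d, 128, rng)
        self.out = nn.Linear(128, 2 if task == "classification" else 1, rng)
        self.task = task
        self.variant = variant
        self.N = bundle.N

    def __call__(self, token_ids: np.ndarray, pad_mask: np.ndarray,
                 image: Optional[np.ndarray] = None,
                 acoustic: Optional[np.ndarray] = None) -> Tensor:
        e = self.frozen_encoder(token_ids, pad_mask).detach()
        h_v = h_a = None
        if self.gate.variant in ("visual", "both"):
            if image is None:
                raise ShiftGateConfigError("variant needs an image input")
            pooled = self.image_encoder(image)[0:1].detach()  # class token, 1 x d
            h_v = tile_rows(pooled, self.N)
        if self.gate.variant in ("acoustic", "both"):
            if acoustic is None:
                raise ShiftGateConfigError("variant needs an acoustic input")
            row = self.acoustic_proj(Tensor(np.asarray(acoustic).reshape(1, -1)))
            h_a = tile_rows(row, self.N)
        _, _, e_m = self.gate(e, h_v, h_a)
        x = self.drop_shift(self.ln(e_m))
        h = self.second_encoder.forward_embeddings(x, pad_mask)
        cls = h[0:1]                                   # class-token row
        z = self.fc(self.drop_cls(cls)).relu()
        logits = self.out(z)
        if self.task == "regression":
            logits = logits.relu()
        return logits


# -- functional facade ----------------------------------------------------

def compute_gates(h_mod: np.ndarray, e: np.ndarray,
                  W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """sigmoid(W [h_mod; e] + b) for one token; entries strictly in (0, 1)."""
    v = np.concatenate([np.asarray(h_mod, dtype=np.float64).ravel(),
                        np.asarray(e, dtype=np.float64).ravel()])
    W = np.asarray(W, dtype=np.float64)
    if W.shape[1] != v.size:
        raise ValueError(f"gate weight expects input of size {W.shape[1]}, got {v.size}")
    return 1.0 / (1.0 + np.exp(-(W @ v + np.asarray(b, dtype=np.float64))))


def compute_shift_vector(h_v: Optional[np.ndarray], h_a: Optional[np.ndarray],
                         gate_v: Optional[np.ndarray], gate_a: Optional[np.ndarray],
                         W_v: Optional[np.ndarray], W_a: Optional[np.ndarray],
                         b_m: np.ndarray, variant: str = "both") -> np.ndarray:
    """Gated sum of projected modality vectors plus shared bias, per token."""
    if variant not in VARIANTS:
        raise ShiftGateConfigError(f"unknown variant {variant!r}")
    h_m = np.asarray(b_m, dtype=np.float64).copy()
    if variant in ("visual", "both"):
        if h_v is None or W_v is None or gate_v is None:
            raise ShiftGateConfigError("visual term requires h_v, W_v, gate_v")
        h_m = h_m + np.asarray(gate_v) * (np.asarray(W_v) @ np.asarray(h_v))
    if variant in ("acoustic", "both"):
        if h_a is None or W_a is None or gate_a is None:
            raise ShiftGateConfigError("acoustic term requires h_a, W_a, gate_a")
        h_m = h_m + np.asarray(gate_a) * (np.asarray(W_a) @ np.asarray(h_a))
    return h_m


def scale_and_shift(e: np.ndarray, h_m: np.ndarray, beta: float,
                    epsilon: float = EPSILON) -> tuple[float, np.ndarray]:
    """alpha = min(beta*||e||/(||h_m||+eps), 1); e_m = e + alpha*h_m."""
    e = np.asarray(e, dtype=np.float64)
    h_m = np.asarray(h_m, dtype=np.float64)
    if beta <= 0:
        raise ValueError("beta must be positive")
    alpha = min(beta * np.linalg.norm(e) / (np.linalg.norm(h_m) + epsilon), 1.0)
    return float(alpha), e + alpha * h_m
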