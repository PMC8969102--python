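"""Neural-network building blocks on top of the autodiff core.

Layers follow the usual conventions: ``Linear`` stores a (in, out) weight so
``x @ W + b`` maps row vectors; ``LayerNorm`` normalizes the last axis with
learnable gain/offset; ``Dropout`` uses inverted scaling and is a no-op in
evaluation mode.  ``Adam``, ``ReduceLROnPlateau`` and ``EarlyStopping``
implement the optimization protocol used throughout the package.
"""

from __future__ import annotations

import copy
from typing import Dict, Iterator, List, Optional, Sequence

import numpy as np

from ._tensor import Tensor, concat


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class: parameter discovery by attribute traversal, train/eval mode."""

    def __init__(self) -> None:
        self.training = True

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def parameters(self) -> List[Parameter]:
        return [p for _, p in self.named_parameters()]

    def modules(self) -> Iterator["Module"]:
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for name, p in params.items():
            p.data = np.asarray(state[name], dtype=np.float64).copy()

    def freeze(self) -> "Module":
        for p in self.parameters():
            p.requires_grad = False
        return self


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True,
                 scale: Optional[float] = None):
        super().__init__()
        if scale is None:
            scale = 1.0 / np.sqrt(in_features)
        self.weight = Parameter(rng.uniform(-scale, scale, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Embedding(Module):
    def __init__(self, num_embeddings: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(rng.normal(0.0, 0.02, (num_embeddings, dim)))

    def __call__(self, ids: np.ndarray) -> Tensor:
        return self.weight[np.asarray(ids, dtype=np.intp)]


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gain = Parameter(np.ones(dim))
        self.offset = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        normed = centered / (var + self.eps).sqrt()
        return normed * self.gain + self.offset


class Dropout(Module):
    """Inverted dropout; identity when `training` is False or rate is 0."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)


class SelfAttention(Module):
    """Single-head scaled dot-product self-attention over an (L, d) sequence."""

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        self.q = Linear(dim, dim, rng)
        self.k = Linear(dim, dim, rng)
        self.v = Linear(dim, dim, rng)
        self.out = Linear(dim, dim, rng)
        self.dim = dim

    def __call__(self, x: Tensor, key_mask: Optional[np.ndarray] = None) -> Tensor:
        q, k, v = self.q(x), self.k(x), self.v(x)
        scores = (q @ k.T) * (1.0 / np.sqrt(self.dim))
        if key_mask is not None:
            bias = np.where(np.asarray(key_mask, bool), 0.0, -1e9)[None, :]
            scores = scores + Tensor(bias)
        attn = scores.softmax(axis=-1)
        return self.out(attn @ v)


class TransformerBlock(Module):
    """Pre-norm transformer block: LN→attention→residual, LN→MLP→residual."""

    def __init__(self, dim: int, mlp_ratio: int, rng: np.random.Generator):
        super().__init__()
        self.ln1 = LayerNorm(dim)
        self.attn = SelfAttention(dim, rng)
        self.ln2 = LayerNorm(dim)
        self.fc1 = Linear(dim, dim * mlp_ratio, rng)
        self.fc2 = Linear(dim * mlp_ratio, dim, rng)

    def __call__(self, x: Tensor, key_mask: Optional[np.ndarray] = None) -> Tensor:
        x = x + self.attn(self.ln1(x), key_mask)
        x = x + self.fc2(self.fc1(self.ln2(x)).relu())
        return x


# -- losses ---------------------------------------------------------------

def cross_entropy(logits: Tensor, labels: Sequence[int]) -> Tensor:
    """Mean cross-entropy for (B, C) logits and integer labels."""
    logp = (logits.softmax(axis=-1) + 1e-12).log()
    rows = np.arange(logp.shape[0])
    picked = logp[rows, np.asarray(labels, dtype=np.intp)]
    return -picked.mean()


def rmse_loss(preds: Tensor, targets: np.ndarray) -> Tensor:
    """Root-mean-squared error over a batch of scalar predictions."""
    diff = preds.reshape(-1) - Tensor(np.asarray(targets, dtype=np.float64))
    return ((diff * diff).mean() + 1e-12).sqrt()


# -- optimization ---------------------------------------------------------

class Adam:
    def __init__(self, params: Sequence[Parameter], lr: float = 1e-5,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class ReduceLROnPlateau:
    """Multiply the learning rate by `factor` after `patience` consecutive
    epochs without improvement of the monitored loss."""

    def __init__(self, optimizer: Adam, factor: float = 0.1, patience: int = 3,
                 min_delta: float = 0.0):
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.min_delta = min_delta
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, loss: float) -> bool:
        """Record an epoch's monitored loss; returns True if the LR was reduced."""
        if loss < self.best - self.min_delta:
            self.best = loss
            self.bad_epochs = 0
            return False
        self.bad_epochs += 1
        if self.bad_epochs >= self.patience:
            self.optimizer.lr *= self.factor
            self.bad_epochs = 0
            return True
        return False


class EarlyStopping:
    """Signal a stop after `patience` consecutive epochs without improvement."""

    def __init__(self, patience: int = 6, min_delta: float = 0.0):
        self.patience = patience
        self.min_delta = min_delta
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, loss: float) -> bool:
        """Returns True exactly when training should halt at this epoch."""
        if loss < self.best - self.min_delta:
            self.best = loss
            self.bad_epochs = 0
            return False
        self.bad_epochs += 1
        return self.bad_epochs >= self.patience
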