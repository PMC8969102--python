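"""Reproducible desk-scale experiments on synthetic corpora.

These helpers wire the full pipeline together at the problem sizes used for
verification: small corpora (two dozen subjects, a few seconds of audio
each) and tiny encoders (d = 32, N = 64 tokens, T = 17 patches).  They are
the same code paths a full-scale run would use; only the sizes differ.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import MODEL_REGISTRY
from .corpus import CorpusSpec, SignalSpec, generate_corpus
from .encoders import build_tiny_encoders
from .pipeline import prepare_dataset
from .training import (Sample, TrainConfig, evaluate_regression,
                       init_regression_bias, predict, split_dataset,
                       train_model)

SMOKE_DIMS = dict(d=32, N=64, T=17)
SMOKE_LR = {"classification": 2e-3, "regression": 1e-3}
SMOKE_BATCH = {"classification": 8, "regression": 4}


def build_smoke_corpus(out_dir, n_subjects: int = 24, seed: int = 7,
                       duration_s: float = 6.0,
                       null_signal: bool = False) -> List[Sample]:
    """Generate a corpus and preprocess it with the smoke-scale encoders."""
    signal = SignalSpec(0, 0, 0) if null_signal else SignalSpec()
    spec = CorpusSpec(n_subjects=n_subjects, ad_fraction=0.5, seed=seed,
                      signal=signal, duration_s=duration_s)
    subjects, _ = generate_corpus(spec, out_dir)
    bundle = build_tiny_encoders(seed=seed, **SMOKE_DIMS)
    return prepare_dataset(subjects, bundle)


def fit_capability(samples: Sequence[Sample], arch: str, task: str,
                   seed: int = 3, max_epochs: int = 50,
                   dims: Optional[dict] = None) -> float:
    """Train one architecture on the full sample set and measure how well it
    fits its own training data: accuracy (classification) or RMSE
    (regression).  Scheduler/early-stopping are disabled so the measurement
    reflects 50 epochs of optimization, not the validation protocol."""
    dims = dims or SMOKE_DIMS
    cfg = TrainConfig(task=task, learning_rate=SMOKE_LR[task],
                      max_epochs=max_epochs, early_stopping_patience=max_epochs,
                      plateau_patience=max_epochs, batch_size=SMOKE_BATCH[task],
                      seed=seed)
    bundle = build_tiny_encoders(seed=seed, **dims)
    model = MODEL_REGISTRY[arch](bundle, task=task, seed=seed)
    if task == "regression":
        init_regression_bias(model, samples)
    train_model(model, samples, samples, cfg)
    preds = predict(model, samples, task)
    if task == "classification":
        labels = np.array([s.label for s in samples])
        return float((preds == labels).mean() * 100.0)
    return evaluate_regression(preds, [s.mmse for s in samples])


@dataclass
class NullCheckResult:
    n_correct: int
    n_total: int

    @property
    def accuracy(self) -> float:
        return 100.0 * self.n_correct / self.n_total


def null_signal_validation(tmp_dir, n_seeds: int = 5, n_subjects: int = 114,
                           base_seed: int = 100, max_epochs: int = 10,
                           duration_s: float = 4.0) -> NullCheckResult:
    """Validation predictions pooled over corpora with all group effects
    removed from the signals.  A sound pipeline cannot beat chance here;
    the pooled correct-count feeds a binomial test."""
    dims = dict(d=16, N=32, T=5)
    correct = total = 0
    for k in range(n_seeds):
        seed = base_seed + k
        spec = CorpusSpec(n_subjects=n_subjects, ad_fraction=0.5, seed=seed,
                          signal=SignalSpec(0, 0, 0), duration_s=duration_s)
        subjects, _ = generate_corpus(spec, f"{tmp_dir}/null_{seed}")
        bundle = build_tiny_encoders(seed=seed, **dims)
        samples = prepare_dataset(subjects, bundle)
        labels = [s.label for s in samples]
        train_set, val_set = split_dataset(samples, seed=seed, stratify=labels)
        cfg = TrainConfig(task="classification", learning_rate=SMOKE_LR["classification"],
                          max_epochs=max_epochs, batch_size=8, seed=seed)
        model = MODEL_REGISTRY["coattention"](
            build_tiny_encoders(seed=seed, **dims), task="classification", seed=seed)
        train_model(model, train_set, val_set, cfg)
        preds = predict(model, val_set, "classification")
        truth = np.array([s.label for s in val_set])
        correct += int((preds == truth).sum())
        total += len(val_set)
    return NullCheckResult(correct, total)


def dimension_contracts() -> Dict[str, int]:
    """Recompute the published-scale dimension facts from the package:
    padded text length, patch-token count, fused sequence length, acoustic
    feature dimensionality."""
    from .acoustic import N_FEATURES
    from .chat import Transcript, encode_text
    from .encoders import TinyImageEncoder

    enc = encode_text(Transcript("x", (("PAR", "the boy falls ."),)), max_len=512)
    N = len(enc)
    vit = TinyImageEncoder(8, 224, (16, 16), np.random.default_rng(0), n_layers=1)
    T = vit.seq_len
    return {"N": N, "T": T, "m": N + T, "acoustic_dim": N_FEATURES}
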