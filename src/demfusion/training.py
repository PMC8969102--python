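"""Training protocol and evaluation metrics for both tasks.

Protocol: a stratified 65/35 train/validation split; Adam; reduce-on-plateau
(factor 0.1 after 3 non-improving epochs of validation loss); early stopping
after 6 non-improving epochs; best-validation checkpoint returned; repeated
runs differ in model-initialization seed and are aggregated as mean +/-
population standard deviation per metric.

Tasks: binary dementia detection (label 1 = AD, the positive class,
cross-entropy loss, argmax decision) and MMSE score regression (0-30 range,
RMSE loss, single ReLU output unit).  Subjects without an MMSE score are
dropped for the regression task only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.metrics import confusion_matrix

from ._tensor import Tensor, concat
from . import nn


@dataclass(frozen=True)
class Sample:
    """One subject's model-ready features and targets."""

    subject_id: str
    token_ids: np.ndarray
    pad_mask: np.ndarray
    image: np.ndarray
    acoustic: np.ndarray
    label: int
    mmse: Optional[float]

    def target(self, task: str) -> float:
        return float(self.label) if task == "classification" else float(self.mmse)


@dataclass
class TrainConfig:
    """Defaults mirror the published protocol (Adam at 1e-5, plateau decay
    0.1/3 epochs, early stop after 6, 65/35 split, 5 repetitions); tiny
    from-scratch encoders typically need a larger learning rate."""

    task: str = "classification"
    learning_rate: float = 1e-5
    plateau_factor: float = 0.1
    plateau_patience: int = 3
    early_stopping_patience: int = 6
    max_epochs: int = 50
    batch_size: int = 8
    repetitions: int = 5
    seed: int = 0
    split_fractions: Tuple[float, float] = (0.65, 0.35)

    def __post_init__(self):
        if not math.isclose(sum(self.split_fractions), 1.0):
            raise ValueError("split fractions must sum to 1")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.task not in ("classification", "regression"):
            raise ValueError("task must be 'classification' or 'regression'")


@dataclass(frozen=True)
class ClassificationMetrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    specificity: float

    def as_dict(self) -> Dict[str, float]:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1, "specificity": self.specificity}


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_dataset(subjects: Sequence, fractions: Tuple[float, float] = (0.65, 0.35),
                  seed: int = 0, stratify: Optional[Sequence[int]] = None
                  ) -> Tuple[list, list]:
    """Disjoint, exhaustive train/validation split.

    The train size is round-half-up of n*fractions[0].  With `stratify`
    labels, per-stratum train counts are allocated by largest remainder so
    the global train size is exact.  Reproducible from `seed`.
    """
    n = len(subjects)
    if n < 2:
        raise ValueError("need at least 2 subjects to split")
    if not math.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    n_train = _round_half_up(n * fractions[0])
    n_train = min(max(n_train, 1), n - 1)
    indices = np.arange(n)
    if stratify is None:
        perm = rng.permutation(indices)
        train_idx, val_idx = perm[:n_train], perm[n_train:]
    else:
        stratify = np.asarray(stratify)
        strata = [indices[stratify == s] for s in np.unique(stratify)]
        exact = [len(g) * fractions[0] for g in strata]
        counts = [int(math.floor(e)) for e in exact]
        remainders = np.array(exact) - np.array(counts)
        deficit = n_train - sum(counts)
        for j in np.argsort(-remainders)[:max(deficit, 0)]:
            counts[j] += 1
        train_idx_parts, val_idx_parts = [], []
        for g, c in zip(strata, counts):
            perm = rng.permutation(g)
            train_idx_parts.append(perm[:c])
            val_idx_parts.append(perm[c:])
        train_idx = np.concatenate(train_idx_parts)
        val_idx = np.concatenate(val_idx_parts)
        train_idx = train_idx[rng.permutation(train_idx.size)]
        val_idx = val_idx[rng.permutation(val_idx.size)]
    return [subjects[i] for i in train_idx], [subjects[i] for i in val_idx]


def drop_missing_mmse(subjects: Sequence, task: str = "regression") -> list:
    """For the regression task, remove subjects without an MMSE score;
    the classification task keeps everyone."""
    if task != "regression":
        return list(subjects)
    def has_mmse(s) -> bool:
        v = getattr(s, "mmse", None)
        return v is not None and not (isinstance(v, float) and math.isnan(v))
    return [s for s in subjects if has_mmse(s)]


@dataclass
class History:
    train_loss: List[float] = field(default_factory=list)
    val_loss: List[float] = field(default_factory=list)
    lr: List[float] = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


def _batch_loss(model: nn.Module, batch: Sequence[Sample], task: str) -> Tensor:
    outputs = [model(s.token_ids, s.pad_mask, s.image, s.acoustic) for s in batch]
    if task == "classification":
        logits = concat(outputs, axis=0)
        labels = [s.label for s in batch]
        return nn.cross_entropy(logits, labels)
    preds = concat(outputs, axis=0)
    targets = np.array([s.mmse for s in batch], dtype=np.float64)
    return nn.rmse_loss(preds, targets)


def _dataset_loss(model: nn.Module, data: Sequence[Sample], task: str) -> float:
    model.eval()
    loss = _batch_loss(model, data, task)
    model.train()
    return float(loss.data)


def train_model(model: nn.Module, train_data: Sequence[Sample],
                val_data: Sequence[Sample], cfg: TrainConfig
                ) -> Tuple[Dict[str, np.ndarray], History]:
    """Train with the package protocol; returns (best-validation state dict,
    loss history).  Aborts with a diagnostic on non-finite loss."""
    if not train_data or not val_data:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(model.parameters(), lr=cfg.learning_rate)
    scheduler = nn.ReduceLROnPlateau(opt, factor=cfg.plateau_factor,
                                     patience=cfg.plateau_patience)
    stopper = nn.EarlyStopping(patience=cfg.early_stopping_patience)
    history = History()
    best_val = np.inf
    best_state = model.state_dict()
    model.train()
    order = np.arange(len(train_data))
    for _ in range(cfg.max_epochs):
        rng.shuffle(order)
        epoch_losses = []
        for start in range(0, order.size, cfg.batch_size):
            batch = [train_data[i] for i in order[start:start + cfg.batch_size]]
            loss = _batch_loss(model, batch, cfg.task)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"training diverged: non-finite loss at step {opt.t + 1}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        val_loss = _dataset_loss(model, val_data, cfg.task)
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.val_loss.append(val_loss)
        history.lr.append(opt.lr)
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()
        scheduler.step(val_loss)
        if stopper.step(val_loss):
            break
    model.load_state_dict(best_state)
    return best_state, history


def predict(model: nn.Module, data: Sequence[Sample], task: str) -> np.ndarray:
    """Argmax labels (classification) or scalar scores (regression)."""
    model.eval()
    outs = []
    for s in data:
        out = model(s.token_ids, s.pad_mask, s.image, s.acoustic).data
        outs.append(int(np.argmax(out)) if task == "classification"
                    else float(out.ravel()[0]))
    model.train()
    return np.asarray(outs)


def evaluate_classification(pred_labels: Sequence[int],
                            true_labels: Sequence[int]) -> ClassificationMetrics:
    """Accuracy, precision, recall, F1 and specificity (percentages) with the
    dementia class (label 1) as positive.  Undefined ratios (zero
    denominator) are reported as 0 with a warning."""
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if pred.size == 0 or pred.shape != true.shape:
        raise ValueError("predictions and labels must be equal-length and non-empty")
    if not (np.isin(pred, (0, 1)).all() and np.isin(true, (0, 1)).all()):
        raise ValueError("labels must be binary (0 = non-AD, 1 = AD)")
    tn, fp, fn, tp = confusion_matrix(true, pred, labels=[0, 1]).ravel()

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); reporting 0",
                          RuntimeWarning, stacklevel=2)
            return 0.0
        return num / den

    accuracy = (tp + tn) / pred.size
    precision = ratio(tp, tp + fp, "precision")
    recall = ratio(tp, tp + fn, "recall")
    f1 = ratio(2 * precision * recall, precision + recall, "f1") if (precision + recall) else 0.0
    specificity = ratio(tn, tn + fp, "specificity")
    return ClassificationMetrics(*(100.0 * v for v in
                                   (accuracy, precision, recall, f1, specificity)))


def evaluate_regression(preds: Sequence[float], targets: Sequence[float]) -> float:
    """Root-mean-squared error."""
    preds = np.asarray(preds, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    if preds.size == 0 or preds.shape != targets.shape:
        raise ValueError("predictions and targets must be equal-length and non-empty")
    return float(np.sqrt(np.mean((preds - targets) ** 2)))


def aggregate_runs(runs: Sequence[Dict[str, float]]) -> Dict[str, Tuple[float, float]]:
    """Per-metric mean and population standard deviation over repetitions."""
    if not runs:
        raise ValueError("need at least one run")
    keys = runs[0].keys()
    out = {}
    for k in keys:
        vals = np.array([r[k] for r in runs], dtype=np.float64)
        out[k] = (float(vals.mean()), float(vals.std()))  # population std
    return out


def save_checkpoint(path, model: nn.Module, **metadata) -> None:
    """Write all model parameters (plus optional metadata) as an NPZ archive."""
    state = model.state_dict()
    meta = {f"__meta_{k}": np.asarray(v) for k, v in metadata.items()}
    np.savez(path, **state, **meta)


def load_checkpoint(path, model: nn.Module) -> Dict[str, np.ndarray]:
    """Restore parameters saved by :func:`save_checkpoint`; returns metadata."""
    with np.load(path, allow_pickle=False) as archive:
        state = {k: archive[k] for k in archive.files if not k.startswith("__meta_")}
        meta = {k[len("__meta_"):]: archive[k] for k in archive.files
                if k.startswith("__meta_")}
    model.load_state_dict(state)
    return meta


def init_regression_bias(model: nn.Module, train_data: Sequence[Sample]) -> None:
    """Set the output unit's bias to the mean training target (standard
    regression-head initialization so early epochs are not spent learning
    the score offset)."""
    mean_target = float(np.mean([s.mmse for s in train_data]))
    model.out.bias.data[:] = mean_target


def run_repetitions(model_factory: Callable[[int], nn.Module],
                    train_data: Sequence[Sample], val_data: Sequence[Sample],
                    cfg: TrainConfig) -> Tuple[Dict[str, Tuple[float, float]], list]:
    """Train `cfg.repetitions` models differing only in initialization seed,
    evaluate each on the validation set, and aggregate."""
    per_run = []
    histories = []
    for rep in range(cfg.repetitions):
        model = model_factory(cfg.seed + rep)
        if cfg.task == "regression":
            init_regression_bias(model, train_data)
        _, hist = train_model(model, train_data, val_data,
                              replace(cfg, seed=cfg.seed + rep))
        histories.append(hist)
        preds = predict(model, val_data, cfg.task)
        if cfg.task == "classification":
            truth = [s.label for s in val_data]
            per_run.append(evaluate_classification(preds, truth).as_dict())
        else:
            truth = [s.mmse for s in val_data]
            per_run.append({"rmse": evaluate_regression(preds, truth)})
    return aggregate_runs(per_run), histories
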