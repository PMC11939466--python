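"""Weighted cross-entropy training with four-fold cross-validation.

The loss for a sample n with target class c is

    l_n = -w_c * log softmax(x_n)_c

computed through the log-sum-exp of the unnormalized logits for numerical
stability.  The class weights w_c are inversely proportional to the class
counts n_c (rescaled so they sum to the number of classes), which lets the
minority bulbous class pull on the gradients as hard as the majority.

The learning rate starts at 1e-3 and halves every 50 epochs.  Training can
run at full 32-bit precision or with the forward and backward passes at
half precision and gradients converted back to single precision for the
optimizer step ("mixed_16_32"); the two are contractually accuracy-neutral.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .imaging import rgb_to_ycbcr
from .network import LABELS, ArchitectureConfig, Network, build_network
from .signatures import Signature, SignatureLibrary, kfold_split


@dataclasses.dataclass(frozen=True)
class ClassWeights:
    w: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "w", np.asarray(self.w, dtype=np.float64))
        if self.w.ndim != 1 or (self.w <= 0).any():
            raise ValueError("weights must be a vector of positive reals")


@dataclasses.dataclass(frozen=True)
class TrainingConfig:
    initial_lr: float = 1e-3
    lr_halving_period: int = 50
    epochs: int = 200
    batch_size: int = 32
    seed: int = 0
    precision: str = "full_32"  # or "mixed_16_32"
    optimizer_name: str = "adam"
    standardize_inputs: bool = True

    def __post_init__(self) -> None:
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be positive")
        if self.lr_halving_period < 1:
            raise ValueError("lr_halving_period must be >= 1")
        if self.precision not in ("full_32", "mixed_16_32"):
            raise ValueError("precision must be 'full_32' or 'mixed_16_32'")
        if self.optimizer_name != "adam":
            raise ValueError("only the 'adam' optimizer is implemented")


@dataclasses.dataclass
class FoldMetrics:
    """Support-weighted classification metrics of one cross-validation fold,
    all as percentages; ``confusion`` has true classes on rows."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    confusion: np.ndarray


def compute_class_weights(class_counts: Sequence[int],
                          normalization: str = "sum_to_c") -> ClassWeights:
    """w_c proportional to 1/n_c; by default rescaled so sum(w) = C."""
    counts = np.asarray(class_counts, dtype=np.float64)
    if (counts < 1).any():
        raise ValueError("all class counts must be >= 1")
    inv = 1.0 / counts
    if normalization == "sum_to_c":
        inv = inv * (len(counts) / inv.sum())
    elif normalization != "none":
        raise ValueError(f"unknown normalization {normalization!r}")
    return ClassWeights(inv)


def weighted_cross_entropy(logits: np.ndarray, targets: np.ndarray,
                           weights: ClassWeights) -> np.ndarray:
    """Per-sample losses -w_y * (x_y - logsumexp(x)), max-shift stabilized."""
    logits = np.asarray(logits, dtype=np.float64)
    if logits.ndim == 1:
        logits = logits[None, :]
    if not np.isfinite(logits).all():
        raise ValueError("logits must be finite")
    targets = np.atleast_1d(np.asarray(targets, dtype=int))
    m = logits.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(logits - m).sum(axis=1))
    idx = np.arange(len(targets))
    return -weights.w[targets] * (logits[idx, targets] - lse)


def lr_at_epoch(epoch: int, config: TrainingConfig) -> float:
    """initial_lr * 0.5^floor(epoch / halving_period)."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return config.initial_lr * 0.5 ** (epoch // config.lr_halving_period)


def evaluate_metrics(confusion: np.ndarray) -> FoldMetrics:
    """Accuracy plus support-weighted precision/recall/F1 from a confusion
    table (rows = true class, columns = predicted).

    Support weighting makes the weighted recall equal the accuracy exactly:
    sum_c (n_c/N) * (TP_c/n_c) = trace/N.
    """
    confusion = np.asarray(confusion)
    if confusion.ndim != 2 or confusion.shape[0] != confusion.shape[1] \
            or confusion.size == 0:
        raise ValueError("confusion must be a non-empty square table")
    if (confusion < 0).any():
        raise ValueError("confusion entries must be non-negative")
    total = confusion.sum()
    if total == 0:
        raise ValueError("confusion table is empty")
    tp = np.diag(confusion).astype(np.float64)
    support = confusion.sum(axis=1).astype(np.float64)
    predicted = confusion.sum(axis=0).astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        prec_c = np.where(predicted > 0, tp / predicted, 0.0)
        rec_c = np.where(support > 0, tp / support, 0.0)
        f1_c = np.where(prec_c + rec_c > 0,
                        2 * prec_c * rec_c / (prec_c + rec_c), 0.0)
    weights = support / total
    return FoldMetrics(
        accuracy=100.0 * tp.sum() / total,
        precision=100.0 * float(weights @ prec_c),
        recall=100.0 * float(weights @ rec_c),
        f1=100.0 * float(weights @ f1_c),
        confusion=confusion.astype(int),
    )


# ---------------------------------------------------------------------------
# Data preparation and the optimizer
# ---------------------------------------------------------------------------

def signatures_to_arrays(signatures: Sequence[Signature],
                         color_space: str) -> tuple[np.ndarray, np.ndarray]:
    """Stack patches as (N, S, S, 3) in the model's color space, labels as
    integer indices into :data:`oednet.network.LABELS`."""
    patches = np.stack([
        rgb_to_ycbcr(s.patch) if color_space == "YCbCr"
        else np.asarray(s.patch, dtype=np.float64)
        for s in signatures
    ]).astype(np.float32)
    labels = np.array([LABELS.index(s.label) for s in signatures])
    return patches, labels


class Adam:
    """Adaptive-moment gradient descent on the float32 master weights."""

    def __init__(self, params, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = list(params)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m += (1 - self.beta1) * (g - m)
            v += (1 - self.beta2) * (g * g - v)
            p.data -= lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)


def _forward_batches(net: Network, x: np.ndarray, batch: int) -> np.ndarray:
    probs = [net.predict_proba(x[i:i + batch]) for i in range(0, len(x), batch)]
    return np.concatenate(probs, axis=0)


def train_network(
    train_signatures: Sequence[Signature],
    arch: ArchitectureConfig,
    config: TrainingConfig,
    val_signatures: Optional[Sequence[Signature]] = None,
    net: Optional[Network] = None,
) -> tuple[Network, pd.DataFrame]:
    """Fit one model on a signature collection.

    Returns the trained network and a per-epoch log with columns
    (epoch, lr, train_loss, val_accuracy).
    """
    x, y = signatures_to_arrays(train_signatures, arch.color_space)
    if net is None:
        net = build_network(arch, seed=config.seed)
    if config.standardize_inputs:
        flat = x.reshape(-1, 3)
        net.input_mean = flat.mean(axis=0).astype(np.float32)
        net.input_sd = np.maximum(flat.std(axis=0), 1e-6).astype(np.float32)
    if config.precision == "mixed_16_32":
        net.set_compute_dtype(np.float16)
    xn = net.preprocess(x)
    counts = np.bincount(y, minlength=arch.num_classes)
    weights = compute_class_weights(np.maximum(counts, 1))
    if val_signatures is not None:
        xv, yv = signatures_to_arrays(val_signatures, arch.color_space)
        xvn = net.preprocess(xv)
    rng = np.random.default_rng(config.seed + 1)
    opt = Adam(net.params())
    n = len(xn)
    log_rows = []
    for epoch in range(config.epochs):
        lr = lr_at_epoch(epoch, config)
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = xn[idx], y[idx]
            net.zero_grad()
            logits = np.asarray(net.forward(xb, training=True),
                                dtype=np.float64)
            losses = weighted_cross_entropy(logits, yb, weights)
            epoch_loss += losses.sum()
            # gradient of the mean weighted CE w.r.t. the logits
            m = logits.max(axis=1, keepdims=True)
            p = np.exp(logits - m)
            p /= p.sum(axis=1, keepdims=True)
            onehot = np.eye(arch.num_classes)[yb]
            g = weights.w[yb][:, None] * (p - onehot) / len(yb)
            net.backward(g.astype(np.float32))
            opt.step(lr)
        val_acc = np.nan
        if val_signatures is not None:
            pred = _forward_batches(net, xvn, config.batch_size).argmax(axis=1)
            val_acc = 100.0 * float((pred == yv).mean())
        log_rows.append({"epoch": epoch, "lr": lr,
                         "train_loss": epoch_loss / n,
                         "val_accuracy": val_acc})
    net.set_compute_dtype(np.float32)
    return net, pd.DataFrame(log_rows)


def predict_signatures(net: Network, signatures: Sequence[Signature],
                       batch_size: int = 32) -> np.ndarray:
    """Predicted label indices for a signature collection."""
    x, _ = signatures_to_arrays(signatures, net.config.color_space)
    probs = _forward_batches(net, net.preprocess(x), batch_size)
    return probs.argmax(axis=1)


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray,
                     num_classes: int = 3) -> np.ndarray:
    cm = np.zeros((num_classes, num_classes), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


@dataclasses.dataclass
class CrossValidationResult:
    fold_metrics: list[FoldMetrics]
    mean_accuracy: float
    sd_accuracy: float
    models: list[Network]
    logs: list[pd.DataFrame]

    def metrics_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"Fold": i + 1, "Accuracy (%)": fm.accuracy,
             "F1 Score (%)": fm.f1, "Precision (%)": fm.precision,
             "Recall (%)": fm.recall}
            for i, fm in enumerate(self.fold_metrics)
        ])


def cross_validate(
    library: SignatureLibrary,
    arch: ArchitectureConfig,
    train_cfg: TrainingConfig,
    K: int = 4,
    keep_models: bool = True,
) -> CrossValidationResult:
    """Train K models on stratified folds of the training signatures, each
    evaluated on its held-out chunk; the summary statistic is the mean and
    standard deviation of the fold accuracies."""
    folds = kfold_split(library, K, seed=train_cfg.seed)
    fold_metrics: list[FoldMetrics] = []
    models: list[Network] = []
    logs: list[pd.DataFrame] = []
    for k, (train_part, test_part) in enumerate(folds):
        test_labels = {s.label for s in test_part}
        if len(test_labels) < len(LABELS):
            raise ValueError(f"fold {k} is missing a class: has {test_labels}")
        cfg_k = dataclasses.replace(train_cfg, seed=train_cfg.seed + 1000 * k)
        net, log = train_network(train_part, arch, cfg_k)
        y_true = np.array([LABELS.index(s.label) for s in test_part])
        y_pred = predict_signatures(net, test_part, train_cfg.batch_size)
        fold_metrics.append(
            evaluate_metrics(confusion_matrix(y_true, y_pred, len(LABELS))))
        logs.append(log)
        if keep_models:
            models.append(net)
    accs = np.array([fm.accuracy for fm in fold_metrics])
    return CrossValidationResult(
        fold_metrics=fold_metrics,
        mean_accuracy=float(accs.mean()),
        sd_accuracy=float(accs.std(ddof=1)),
        models=models,
        logs=logs,
    )
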