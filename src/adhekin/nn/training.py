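"""Training loop, prediction and stratified cross-validation."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..dataset import oversample, stratified_folds, welford_stats, standardize
from .layers import Parameter, softmax
from .models import Classifier, ModelConfig, build_model


@dataclass
class TrainConfig:
    max_epochs: int = 250
    lr: float = 1e-4
    weight_decay: float = 1e-5
    batch_size: int = 32
    patience: int = 25  # early stop on validation loss
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.max_epochs, self.batch_size, self.n_folds) < 1:
            raise ValueError("epochs, batch size and fold count must be positive")
        if self.lr < 0 or self.weight_decay < 0:
            raise ValueError("learning rate and weight decay must be non-negative")


class Adam:
    """Adam with L2 weight decay folded into the gradient."""

    def __init__(self, params: list[Parameter], lr: float, weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad + self.weight_decay * p.value
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    return float(-np.mean(np.log(probs[np.arange(len(y)), y] + eps)))


def predict(model: Classifier, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Per-class probability matrix; rows sum to 1."""
    model.train_mode(False)
    out = []
    for i in range(0, len(X), batch_size):
        out.append(model.forward(X[i : i + batch_size]))
    return np.concatenate(out, axis=0)


def train(
    model: Classifier,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: TrainConfig,
    verbose: bool = False,
) -> dict:
    """Optimize cross-entropy with Adam; restore best-validation weights.

    Returns a history dict with per-epoch train/validation loss and
    accuracy. Raises on NaN loss with the epoch in the message.
    """
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.lr, weight_decay=config.weight_decay)
    history: dict = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}
    if len(X_train) == 0 or len(X_val) == 0:
        raise ValueError("training and validation sets must be non-empty")
    best_loss = np.inf
    best_weights = model.get_weights()
    best_epoch = 0
    n = len(X_train)
    for epoch in range(config.max_epochs):
        model.train_mode(True)
        order = rng.permutation(n)
        losses, hits = [], 0
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            xb, yb = X_train[idx], y_train[idx]
            model.zero_grad()
            logits = model.logits(xb)
            probs = softmax(logits)
            loss = cross_entropy(probs, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}; reduce lr or check inputs"
                )
            onehot = np.zeros_like(probs)
            onehot[np.arange(len(yb)), yb] = 1.0
            model.backward((probs - onehot) / len(yb))
            opt.step()
            losses.append(loss * len(yb))
            hits += int((probs.argmax(axis=1) == yb).sum())
        history["train_loss"].append(float(np.sum(losses) / n))
        history["train_acc"].append(hits / n)

        val_probs = predict(model, X_val, config.batch_size)
        val_loss = cross_entropy(val_probs, y_val)
        val_acc = float(np.mean(val_probs.argmax(axis=1) == y_val))
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)
        if verbose:
            print(f"epoch {epoch:3d} train {history['train_loss'][-1]:.4f} "
                  f"val {val_loss:.4f} acc {val_acc:.3f}")
        if val_loss < best_loss - 1e-6:
            best_loss = val_loss
            best_weights = model.get_weights()
            best_epoch = epoch
        elif epoch - best_epoch >= config.patience:
            break
    model.set_weights(best_weights)
    history["best_epoch"] = best_epoch
    return history


def fit_classifier(
    model_config: ModelConfig,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    train_config: TrainConfig,
) -> tuple[Classifier, dict]:
    model = build_model(model_config)
    history = train(model, X_train, y_train, X_val, y_val, train_config)
    return model, history


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    model_config: ModelConfig,
    train_config: TrainConfig,
    X_test: np.ndarray | None = None,
    y_test: np.ndarray | None = None,
    standardize_per_fold: bool = True,
    oversample_train: bool = True,
) -> dict:
    """Stratified k-fold cross-validation over a train+validation pool.

    Each fold trains on the other folds (optionally oversampled and
    standardized by that training portion's Welford statistics) and
    validates on the held-in fold; a fixed external test set, if given, is
    scored by every fold's model. Returns per-fold metrics and their
    mean/sd summary.
    """
    folds = stratified_folds(y, n_folds=train_config.n_folds, seed=train_config.seed)
    results: dict = {"folds": []}
    test_accs, val_accs = [], []
    for k, val_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(y)), val_idx)
        if oversample_train:
            train_idx = oversample(train_idx, y, seed=train_config.seed + k)
        if standardize_per_fold:
            stats = welford_stats(X[i] for i in np.unique(train_idx))
            Xtr = standardize(X[train_idx], stats)
            Xva = standardize(X[val_idx], stats)
            Xte = standardize(X_test, stats) if X_test is not None else None
        else:
            stats = None
            Xtr, Xva = X[train_idx], X[val_idx]
            Xte = X_test
        cfg = ModelConfig(**{**model_config.__dict__, "seed": model_config.seed + k})
        model, history = fit_classifier(cfg, Xtr, y[train_idx], Xva, y[val_idx], train_config)
        fold_result = {
            "fold": k,
            "val_indices": val_idx,
            "val_acc": float(np.mean(predict(model, Xva).argmax(1) == y[val_idx])),
            "history": history,
        }
        val_accs.append(fold_result["val_acc"])
        if Xte is not None:
            probs = predict(model, Xte)
            fold_result["test_acc"] = float(np.mean(probs.argmax(1) == y_test))
            fold_result["test_probs"] = probs
            test_accs.append(fold_result["test_acc"])
        results["folds"].append(fold_result)
    results["val_acc_mean"] = float(np.mean(val_accs))
    results["val_acc_sd"] = float(np.std(val_accs))
    if test_accs:
        results["test_acc_mean"] = float(np.mean(test_accs))
        results["test_acc_sd"] = float(np.std(test_accs))
    return results
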