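"""Train/validation/test assembly, class balancing and standardization.

Samples are split 64-16.5-16.5% stratified by cell type (largest-remainder
rounding per class), the training set is balanced by oversampling minority
classes with replacement up to the majority count, and per-pixel
standardization statistics are computed over the training split with
Welford's one-pass algorithm:

    x_s[t, w, h] = (x[t, w, h] - mu[t, w, h]) / sigma[t, w, h]

Validation and test samples are always standardized with training-set
statistics only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

DEFAULT_RATIOS = (0.64, 0.165, 0.165)


@dataclass
class DatasetSplit:
    """Index-based train/validation/test partition of a labelled set."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    ratios: tuple[float, float, float]
    seed: int


def _largest_remainder(n: int, ratios: Sequence[float]) -> list[int]:
    """Integer apportionment of n items by largest remainder."""
    exact = np.asarray(ratios, dtype=float) * n
    base = np.floor(exact).astype(int)
    short = n - base.sum()
    order = np.argsort(-(exact - base))
    for i in order[:short]:
        base[i] += 1
    return base.tolist()


def split_dataset(
    labels: Sequence,
    ratios: tuple[float, float, float] = DEFAULT_RATIOS,
    seed: int = 0,
) -> DatasetSplit:
    """Stratified split into train/validation/test index arrays.

    Each class is shuffled and apportioned by largest remainder, so per-
    class fractions are within one sample of the requested ratios.
    Ratios may sum to less than 1 (the conventional 64-16.5-16.5 split
    does); the shortfall is assigned to the test set. Deterministic for a
    fixed seed.
    """
    labels = np.asarray(labels)
    total = sum(ratios)
    if total > 1.0 + 1e-9 or ratios[0] + ratios[1] >= 1.0:
        raise ValueError(f"invalid split ratios {ratios}")
    effective = (ratios[0], ratios[1], 1.0 - ratios[0] - ratios[1])
    rng = np.random.default_rng(seed)
    parts: list[list[int]] = [[], [], []]
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 3:
            raise ValueError(f"class {cls!r} has {idx.size} samples; cannot stratify")
        idx = rng.permutation(idx)
        n_tr, n_va, n_te = _largest_remainder(idx.size, effective)
        parts[0].extend(idx[:n_tr])
        parts[1].extend(idx[n_tr : n_tr + n_va])
        parts[2].extend(idx[n_tr + n_va :])
    return DatasetSplit(
        train=np.sort(parts[0]),
        validation=np.sort(parts[1]),
        test=np.sort(parts[2]),
        ratios=ratios,
        seed=seed,
    )


def oversample(indices: np.ndarray, labels: Sequence, seed: int = 0) -> np.ndarray:
    """Balance classes by repeating minority-class items with replacement.

    Every class in the returned index list has exactly the majority-class
    count; all original items are retained.
    """
    indices = np.asarray(indices)
    labels = np.asarray(labels)
    sub = labels[indices]
    classes, counts = np.unique(sub, return_counts=True)
    if np.any(counts == 0) or classes.size == 0:
        raise ValueError("every class must have at least one sample")
    target = counts.max()
    rng = np.random.default_rng(seed)
    out = [indices]
    for cls, count in zip(classes, counts):
        deficit = target - count
        if deficit:
            pool = indices[sub == cls]
            out.append(rng.choice(pool, size=deficit, replace=True))
    result = np.concatenate(out)
    return rng.permutation(result)


@dataclass
class StandardizationStats:
    """Per-pixel-per-frame mean and std from a training stream."""

    mean: np.ndarray  # (t, 8, 8)
    std: np.ndarray  # (t, 8, 8), sample (n-1) convention
    n: int


def welford_stats(samples: Iterable[np.ndarray]) -> StandardizationStats:
    """One streaming pass of Welford's algorithm over (t, 8, 8) samples.

    Matches the two-pass mean/std to ~1e-10 relative and is invariant to
    stream order up to that tolerance. Uses the sample (n-1) variance.
    """
    mean = None
    m2 = None
    n = 0
    for x in samples:
        x = np.asarray(x, dtype=np.float64)
        if mean is None:
            mean = np.zeros_like(x)
            m2 = np.zeros_like(x)
        elif x.shape != mean.shape:
            raise ValueError(f"sample shape {x.shape} != {mean.shape}")
        n += 1
        delta = x - mean
        mean = mean + delta / n
        m2 = m2 + delta * (x - mean)
    if n < 2:
        raise ValueError("need at least two samples for standardization stats")
    return StandardizationStats(mean=mean, std=np.sqrt(m2 / (n - 1)), n=n)


def standardize(
    x: np.ndarray, stats: StandardizationStats, eps: float = 1e-6
) -> np.ndarray:
    """Pixel-wise z-score with an ``eps`` floor on sigma.

    Accepts a single (t, 8, 8) sample or a batch (N, t, 8, 8).
    """
    x = np.asarray(x, dtype=np.float64)
    denom = np.maximum(stats.std, eps)
    return (x - stats.mean) / denom


def truncate_frames(x: np.ndarray, timeline_s: np.ndarray, timespan_min: float) -> np.ndarray:
    """Keep the frames of the first ``timespan_min`` minutes.

    Applied before statistics, so each timespan variant gets its own
    mean/std.
    """
    t_end = int(np.searchsorted(np.asarray(timeline_s), timespan_min * 60.0, side="right"))
    if t_end == 0:
        raise ValueError("timespan shorter than one frame")
    return x[..., :t_end, :, :]


def stratified_folds(labels: Sequence, n_folds: int = 5, seed: int = 0) -> list[np.ndarray]:
    """Stratified k-fold partition; per-class fold sizes differ by <= 1."""
    labels = np.asarray(labels)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [val for _, val in skf.split(np.zeros(len(labels)), labels)]


def build_arrays(
    X: np.ndarray,
    y: np.ndarray,
    split: DatasetSplit,
    oversample_seed: int = 0,
    eps: float = 1e-6,
) -> dict:
    """Assemble standardized, oversampled arrays for training.

    Statistics come from the (pre-oversampling) training split only; the
    oversampled index list is applied afterwards.
    """
    stats = welford_stats(X[i] for i in split.train)
    aug = oversample(split.train, y, seed=oversample_seed)
    return {
        "X_train": standardize(X[aug], stats, eps),
        "y_train": y[aug],
        "X_val": standardize(X[split.validation], stats, eps),
        "y_val": y[split.validation],
        "X_test": standardize(X[split.test], stats, eps),
        "y_test": y[split.test],
        "stats": stats,
    }
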