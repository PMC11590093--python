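"""Segmentation and classification metrics.

Segmentation results are scored against ground truth with:

* **Detection Error (DE)** — the fraction of ground-truth cells without
  an accepted match (greedy one-to-one matching by intersection, accepted
  when intersection-over-union >= ``min_overlap``);
* **DS** — a Dice-based dissimilarity, 1 - mean Dice over matched pairs,
  so 0 is perfect overlap and lower is better. DS_m is measured on the
  microscope plane, DS_b on the biosensor plane. The raw mean Dice
  similarity is reported alongside so either convention is recoverable.

Classification is scored with accuracy, macro F1, macro one-vs-rest AUC
and macro average precision (AUC-PR), plus a row-normalized confusion
matrix and a 2D t-SNE embedding of the probability vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (
    average_precision_score,
    confusion_matrix,
    f1_score,
    roc_auc_score,
)


# ---------------------------------------------------------------- segmentation


@dataclass
class MatchTable:
    """One row per greedy match plus the unmatched cells of both sides."""

    pairs: list[tuple[int, int, float, float]]  # (truth_id, pred_id, intersection, dice)
    unmatched_truth: list[int]
    unmatched_pred: list[int]
    n_truth: int
    n_pred: int


def _as_sets(cells: dict[int, np.ndarray]) -> dict[int, set[tuple[int, int]]]:
    return {
        int(k): {(int(r), int(c)) for r, c in np.asarray(v).reshape(-1, 2)}
        for k, v in cells.items()
    }


def match_cells(
    predicted: dict[int, np.ndarray],
    truth: dict[int, np.ndarray],
    min_overlap: float = 0.3,
) -> MatchTable:
    """Greedy one-to-one matching by descending pixel intersection.

    A truth cell counts as detected iff its match's intersection-over-
    union reaches ``min_overlap``. Inputs are cell_id -> (n, 2) pixel
    arrays on a common plane.
    """
    pred_sets = _as_sets(predicted)
    truth_sets = _as_sets(truth)
    overlaps = []
    for tid, tset in truth_sets.items():
        for pid, pset in pred_sets.items():
            inter = len(tset & pset)
            if inter:
                iou = inter / len(tset | pset)
                overlaps.append((inter, iou, tid, pid))
    overlaps.sort(key=lambda r: (-r[0], r[2], r[3]))
    used_t: set[int] = set()
    used_p: set[int] = set()
    pairs = []
    for inter, iou, tid, pid in overlaps:
        if tid in used_t or pid in used_p or iou < min_overlap:
            continue
        dice = 2 * inter / (len(truth_sets[tid]) + len(pred_sets[pid]))
        pairs.append((tid, pid, float(inter), float(dice)))
        used_t.add(tid)
        used_p.add(pid)
    return MatchTable(
        pairs=pairs,
        unmatched_truth=sorted(set(truth_sets) - used_t),
        unmatched_pred=sorted(set(pred_sets) - used_p),
        n_truth=len(truth_sets),
        n_pred=len(pred_sets),
    )


def detection_error(table: MatchTable) -> float:
    """Fraction of ground-truth cells lost by the segmentation."""
    if table.n_truth == 0:
        raise ValueError("no ground-truth cells")
    return len(table.unmatched_truth) / table.n_truth


def dice_scores(table: MatchTable) -> dict:
    """Mean Dice over matched pairs, reported as DS = 1 - mean Dice."""
    if not table.pairs:
        raise ValueError("no matched pairs to score")
    dices = np.array([p[3] for p in table.pairs])
    return {
        "mean_dice": float(dices.mean()),
        "DS": float(1.0 - dices.mean()),
        "per_pair": dices,
    }


@dataclass
class SegmentationEval:
    DE: float
    DS: float
    mean_dice: float
    table: MatchTable


def evaluate_segmentation(
    predicted: dict[int, np.ndarray],
    truth: dict[int, np.ndarray],
    min_overlap: float = 0.3,
) -> SegmentationEval:
    table = match_cells(predicted, truth, min_overlap=min_overlap)
    de = detection_error(table)
    if table.pairs:
        ds = dice_scores(table)
        return SegmentationEval(DE=de, DS=ds["DS"], mean_dice=ds["mean_dice"], table=table)
    return SegmentationEval(DE=de, DS=float("nan"), mean_dice=float("nan"), table=table)


# -------------------------------------------------------------- classification


@dataclass
class ClassificationReport:
    accuracy: float
    f1: float  # macro
    auc: float  # macro one-vs-rest
    auc_pr: float  # macro average precision
    confusion: np.ndarray  # rows = truth, row-normalized
    per_class: pd.DataFrame
    n_classes: int


def classification_report(
    probabilities: np.ndarray,
    truth: np.ndarray,
    class_names: list[str] | None = None,
) -> ClassificationReport:
    """Accuracy, macro F1 / AUC / AUC-PR and a normalized confusion matrix.

    Classes absent from the truth vector are skipped in the macro
    averages with a warning.
    """
    import warnings

    probs = np.asarray(probabilities, dtype=float)
    truth = np.asarray(truth)
    n_classes = probs.shape[1]
    pred = probs.argmax(axis=1)
    accuracy = float(np.mean(pred == truth))
    present = np.unique(truth)
    if len(present) < n_classes:
        warnings.warn(
            f"{n_classes - len(present)} class(es) absent from truth; "
            "skipped in macro averages"
        )
    f1_vals, auc_vals, pr_vals, rows = [], [], [], []
    for c in range(n_classes):
        name = class_names[c] if class_names else str(c)
        if c not in present:
            rows.append({"class": name, "f1": np.nan, "auc": np.nan, "auc_pr": np.nan})
            continue
        y_bin = (truth == c).astype(int)
        f1_c = f1_score(truth, pred, labels=[c], average="macro", zero_division=0)
        if y_bin.all():  # single-class truth: AUC undefined
            auc_c = pr_c = np.nan
        else:
            auc_c = roc_auc_score(y_bin, probs[:, c])
            pr_c = average_precision_score(y_bin, probs[:, c])
            auc_vals.append(auc_c)
            pr_vals.append(pr_c)
        f1_vals.append(f1_c)
        rows.append({"class": name, "f1": f1_c, "auc": auc_c, "auc_pr": pr_c})
    conf = confusion_matrix(truth, pred, labels=np.arange(n_classes)).astype(float)
    row_sums = conf.sum(axis=1, keepdims=True)
    conf = np.divide(conf, row_sums, out=np.zeros_like(conf), where=row_sums > 0)
    return ClassificationReport(
        accuracy=accuracy,
        f1=float(np.mean(f1_vals)),
        auc=float(np.mean(auc_vals)) if auc_vals else float("nan"),
        auc_pr=float(np.mean(pr_vals)) if pr_vals else float("nan"),
        confusion=conf,
        per_class=pd.DataFrame(rows),
        n_classes=n_classes,
    )


def embed_probabilities(
    probabilities: np.ndarray, seed: int = 0, perplexity: float | None = None
) -> np.ndarray:
    """2D t-SNE embedding of per-sample probability vectors."""
    from sklearn.manifold import TSNE

    probs = np.asarray(probabilities, dtype=float)
    if perplexity is None:
        perplexity = min(30.0, max(2.0, (len(probs) - 1) / 3.0))
    if len(probs) <= perplexity or len(probs) < 8:
        raise ValueError(
            f"need at least 8 samples and more than perplexity={perplexity:.0f} "
            "rows for t-SNE"
        )
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed, init="pca")
    return tsne.fit_transform(probs)


def plot_report(report: ClassificationReport, embedding: np.ndarray | None = None,
                labels: np.ndarray | None = None, out_prefix: str | None = None):
    """Confusion-matrix heatmap and optional embedding scatter (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_panels = 2 if embedding is not None else 1
    fig, axes = plt.subplots(1, n_panels, figsize=(5 * n_panels, 4))
    axes = np.atleast_1d(axes)
    im = axes[0].imshow(report.confusion, vmin=0, vmax=1, cmap="viridis")
    axes[0].set_xlabel("predicted")
    axes[0].set_ylabel("true")
    axes[0].set_title(f"acc={report.accuracy:.3f} F1={report.f1:.3f}")
    fig.colorbar(im, ax=axes[0])
    if embedding is not None:
        color = labels if labels is not None else "k"
        axes[1].scatter(embedding[:, 0], embedding[:, 1], c=color, s=8, cmap="tab10")
        axes[1].set_title("t-SNE of probability vectors")
    fig.tight_layout()
    if out_prefix:
        fig.savefig(f"{out_prefix}_report.png", dpi=120)
        plt.close(fig)
    return fig
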