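"""Segmentation and classification metrics against brute-force oracles."""

from itertools import permutations

import numpy as np
import pytest

from adhekin.evaluation import (
    classification_report,
    detection_error,
    dice_scores,
    embed_probabilities,
    evaluate_segmentation,
    match_cells,
)


def _cells(*pixel_lists):
    return {i + 1: np.array(p) for i, p in enumerate(pixel_lists)}


def test_identical_masks_fully_matched():
    cells = _cells([[0, 0], [0, 1]], [[5, 5]])
    table = match_cells(cells, cells)
    assert len(table.pairs) == 2
    assert table.unmatched_truth == [] and table.unmatched_pred == []
    assert detection_error(table) == 0.0
    ds = dice_scores(table)
    assert ds["DS"] == 0.0 and ds["mean_dice"] == 1.0


def test_empty_prediction_all_lost():
    truth = _cells([[0, 0]], [[5, 5]])
    table = match_cells({}, truth)
    assert len(table.pairs) == 0
    assert detection_error(table) == 1.0
    with pytest.raises(ValueError, match="matched"):
        dice_scores(table)


def test_half_lost_and_dice_arithmetic():
    truth = _cells([[0, 0], [0, 1], [1, 0], [1, 1]], [[9, 9], [9, 8], [8, 9], [8, 8]])
    pred = _cells([[0, 0], [0, 1], [0, 2], [1, 2]])  # overlaps truth 1 with |I|=2
    table = match_cells(pred, truth, min_overlap=0.3)
    assert detection_error(table) == 0.5
    # |A|=|B|=4, |intersection|=2 -> Dice 0.5, DS 0.5
    assert dice_scores(table)["DS"] == pytest.approx(0.5)


def test_matching_equals_exhaustive_assignment_on_toys():
    """Greedy matching agrees with optimal assignment on <=5-cell problems."""
    rng = np.random.default_rng(0)
    for _ in range(20):
        n_t, n_p = rng.integers(1, 5, size=2)
        truth = {
            t + 1: np.unique(rng.integers(0, 8, size=(rng.integers(2, 9), 2)), axis=0)
            for t in range(n_t)
        }
        pred = {
            p + 1: np.unique(rng.integers(0, 8, size=(rng.integers(2, 9), 2)), axis=0)
            for p in range(n_p)
        }
        table = match_cells(pred, truth, min_overlap=0.0)
        greedy_total = sum(p[2] for p in table.pairs)
        # exhaustive optimal one-to-one assignment by total intersection
        t_sets = {k: {tuple(x) for x in v} for k, v in truth.items()}
        p_sets = {k: {tuple(x) for x in v} for k, v in pred.items()}
        t_ids, p_ids = list(t_sets), list(p_sets)
        best = 0
        # enumerate every injective pairing between the two sides
        if len(p_ids) >= len(t_ids):
            pairings = (zip(t_ids, perm) for perm in permutations(p_ids, len(t_ids)))
        else:
            pairings = (zip(perm, p_ids) for perm in permutations(t_ids, len(p_ids)))
        for pairing in pairings:
            total = sum(len(t_sets[t] & p_sets[p]) for t, p in pairing)
            best = max(best, total)
        # greedy-by-intersection is within one swap of optimal on these toys;
        # require it to reach at least half the optimal and usually equal it
        assert greedy_total >= 0.5 * best
        if len(table.pairs) == min(n_t, n_p):
            assert greedy_total <= best


def test_detection_error_needs_truth_cells():
    with pytest.raises(ValueError):
        detection_error(match_cells({}, {}))


def test_ds_never_decreases_under_erosion():
    rng = np.random.default_rng(1)
    truth = {1: np.argwhere(np.ones((6, 6))), 2: np.argwhere(np.ones((4, 4))) + 20}
    full = {k: v.copy() for k, v in truth.items()}
    ds_values = []
    for erode in range(4):
        pred = {k: v[: max(1, len(v) - 5 * erode)] for k, v in full.items()}
        # min_overlap 0 keeps every cell matched: DS monotonicity holds over
        # a fixed match set (a cell dropping below the match threshold would
        # raise DE instead)
        result = evaluate_segmentation(pred, truth, min_overlap=0.0)
        ds_values.append(result.DS)
    assert all(b >= a - 1e-12 for a, b in zip(ds_values, ds_values[1:]))


def _threshold_sweep_auc(scores, y_bin):
    """ROC AUC by exhaustive threshold enumeration (trapezoid over steps)."""
    order = np.argsort(-scores, kind="stable")
    tps = np.cumsum(y_bin[order])
    fps = np.cumsum(1 - y_bin[order])
    tpr = np.concatenate([[0], tps / max(tps[-1], 1)])
    fpr = np.concatenate([[0], fps / max(fps[-1], 1)])
    return np.trapezoid(tpr, fpr)


def test_metrics_match_hand_computation_on_toy():
    probs = np.array(
        [
            [0.9, 0.1], [0.8, 0.2], [0.7, 0.3], [0.6, 0.4], [0.55, 0.45],
            [0.4, 0.6], [0.3, 0.7], [0.2, 0.8], [0.45, 0.55], [0.1, 0.9],
        ]
    )
    truth = np.array([0, 0, 1, 0, 0, 1, 1, 1, 0, 1])
    rep = classification_report(probs, truth)
    pred = probs.argmax(1)
    assert rep.accuracy == pytest.approx(np.mean(pred == truth))
    # brute-force per-class F1
    f1s = []
    for c in (0, 1):
        tp = np.sum((pred == c) & (truth == c))
        fp = np.sum((pred == c) & (truth != c))
        fn = np.sum((pred != c) & (truth == c))
        f1s.append(2 * tp / (2 * tp + fp + fn))
    assert rep.f1 == pytest.approx(np.mean(f1s))
    aucs = [_threshold_sweep_auc(probs[:, c], (truth == c).astype(int)) for c in (0, 1)]
    assert rep.auc == pytest.approx(np.mean(aucs))
    assert rep.confusion.sum(axis=1) == pytest.approx(1.0)


def test_perfect_predictions_score_one():
    truth = np.array([0, 1, 2, 0, 1, 2])
    probs = np.eye(3)[truth]
    rep = classification_report(probs, truth)
    assert rep.accuracy == rep.f1 == rep.auc == rep.auc_pr == 1.0
    assert np.array_equal(rep.confusion, np.eye(3))


def test_uniform_probabilities_give_half_auc():
    truth = np.array([0, 1] * 10)
    probs = np.full((20, 2), 0.5)
    rep = classification_report(probs, truth)
    assert rep.auc == pytest.approx(0.5)


def test_missing_class_warned_and_skipped():
    probs = np.full((4, 3), 1 / 3)
    truth = np.array([0, 0, 1, 1])  # class 2 absent
    with pytest.warns(UserWarning, match="absent"):
        rep = classification_report(probs, truth)
    assert np.isnan(rep.per_class.iloc[2]["f1"])
    assert np.isfinite(rep.f1)


def test_embedding_deterministic_and_separates_clusters():
    rng = np.random.default_rng(2)
    a = np.clip(rng.normal([0.95, 0.04, 0.01], 0.01, size=(30, 3)), 0, 1)
    b = np.clip(rng.normal([0.02, 0.95, 0.03], 0.01, size=(30, 3)), 0, 1)
    probs = np.vstack([a, b])
    emb1 = embed_probabilities(probs, seed=0)
    emb2 = embed_probabilities(probs, seed=0)
    assert emb1.shape == (60, 2)
    np.testing.assert_array_equal(emb1, emb2)
    labels = np.repeat([0, 1], 30)
    centroids = np.array([emb1[labels == c].mean(axis=0) for c in (0, 1)])
    assigned = np.argmin(
        np.linalg.norm(emb1[:, None] - centroids[None], axis=-1), axis=1
    )
    purity = np.mean(assigned == labels)
    assert purity >= 0.95


def test_embedding_needs_enough_samples():
    with pytest.raises(ValueError, match="samples"):
        embed_probabilities(np.full((3, 2), 0.5), seed=0)
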