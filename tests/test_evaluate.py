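"""Confusion matrices, precision/recall/F1, ROC/AUC and OVR averaging.

AUC values are cross-checked against an independent Mann-Whitney
pair-counting oracle; per-class metrics are checked against the published
reference tables shipped with the package.
"""

import numpy as np
import pytest

from behavframe.evaluate import (
    ConfusionMatrix,
    confusion_matrix,
    optimal_threshold,
    ovr_auc,
    per_class_metrics,
    roc_curve,
    weighted_metrics,
)
from behavframe.reference import REFERENCE_TAXONOMIES, load_reference_confusion

# Published per-class values for the three reference matrices
# (precision, recall, F1 at two decimals).
REFERENCE_PER_CLASS = {
    "T1_sedentary": {
        "sedentary": (0.92, 0.82, 0.87),
        "active": (0.84, 0.93, 0.88),
    },
    "T2_activity_type": {
        "sedentary": (0.65, 0.89, 0.75),
        "mixed_movement": (0.53, 0.52, 0.53),
        "walking": (0.34, 0.56, 0.42),
        "running": (0.99, 0.56, 0.72),
    },
    "T3_intensity": {
        "sedentary": (0.90, 0.72, 0.80),
        "light": (0.11, 0.74, 0.20),
        "moderate": (0.92, 0.63, 0.75),
        "vigorous": (0.43, 0.27, 0.33),
    },
}

REFERENCE_ACCURACY = {
    "T1_sedentary": 0.874,
    "T2_activity_type": 0.631,
    "T3_intensity": 0.686,
}


def mann_whitney_auc(scores, labels):
    """Independent AUC oracle: fraction of (positive, negative) pairs ranked
    correctly, ties counting one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos, neg = scores[labels], scores[~labels]
    wins = ties = 0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1
            elif p == n:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


# ------------------------------------------------------- confusion matrix

def test_perfect_predictions_are_diagonal():
    cm = confusion_matrix(list("aabbc"), list("aabbc"), ["a", "b", "c"])
    assert np.array_equal(cm.counts, np.diag([2, 2, 1]))


def test_retally_of_expanded_reference_stream():
    """Expanding the published two-class count matrix into a label stream
    and re-tallying reproduces it exactly."""
    ref = load_reference_confusion("T1")
    true, pred = [], []
    for i, t in enumerate(ref.classes):
        for j, p in enumerate(ref.classes):
            true += [t] * ref.counts[i, j]
            pred += [p] * ref.counts[i, j]
    cm = confusion_matrix(true, pred, ref.classes)
    assert np.array_equal(cm.counts, ref.counts)


def test_never_predicted_class_column_allowed():
    cm = confusion_matrix(["a", "b"], ["a", "a"], ["a", "b"])
    assert cm.counts[:, 1].sum() == 0
    per = per_class_metrics(cm)
    assert per.loc["b", "precision"] == 0.0 and bool(per.loc["b", "never_predicted"])


def test_labels_outside_classes_rejected():
    with pytest.raises(ValueError, match="outside"):
        confusion_matrix(["a"], ["z"], ["a", "b"])


def test_conservation():
    cm = load_reference_confusion("T2")
    assert np.trace(cm.counts) + (cm.counts.sum() - np.trace(cm.counts)) == cm.total


# ---------------------------------------------------------- class metrics

@pytest.mark.parametrize("taxonomy", REFERENCE_TAXONOMIES)
def test_reference_per_class_metrics(taxonomy):
    per = per_class_metrics(load_reference_confusion(taxonomy))
    for cls, (p, r, f) in REFERENCE_PER_CLASS[taxonomy].items():
        assert round(per.loc[cls, "precision"], 2) == p
        assert round(per.loc[cls, "recall"], 2) == r
        assert round(per.loc[cls, "f1"], 2) == f


@pytest.mark.parametrize("taxonomy", REFERENCE_TAXONOMIES)
def test_reference_accuracies(taxonomy):
    w = weighted_metrics(load_reference_confusion(taxonomy))
    assert w["accuracy"] == pytest.approx(REFERENCE_ACCURACY[taxonomy], abs=5e-4)
    # support-weighted recall is identically the accuracy
    assert w["recall"] == pytest.approx(w["accuracy"])


def test_identity_matrix_metrics_are_one():
    cm = ConfusionMatrix(("a", "b", "c"), np.diag([3, 4, 5]))
    per = per_class_metrics(cm)
    assert (per[["precision", "recall", "f1"]] == 1.0).all().all()
    assert weighted_metrics(cm)["accuracy"] == 1.0


def test_one_class_matrix_collapses():
    cm = ConfusionMatrix(("a",), np.array([[9]]))
    w = weighted_metrics(cm)
    assert w["accuracy"] == w["recall"] == w["precision"] == 1.0


# -------------------------------------------------------------------- ROC

def test_perfect_separation_auc_one():
    roc = roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    assert roc.auc == pytest.approx(1.0)
    assert roc.fpr[0] == 0.0 and roc.tpr[-1] == 1.0


def test_constant_scores_auc_half():
    roc = roc_curve([0.5] * 10, [1, 0] * 5)
    assert roc.auc == pytest.approx(0.5)


def test_four_point_example():
    roc = roc_curve([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0])
    # brute force over all positive-negative pairs: 3 of 4 ranked correctly
    assert roc.auc == pytest.approx(0.75)
    assert roc.auc == pytest.approx(mann_whitney_auc([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0]))


def test_single_class_labels_rejected():
    with pytest.raises(ValueError):
        roc_curve([0.1, 0.2], [1, 1])


def test_roc_monotone_with_counts():
    rng = np.random.default_rng(11)
    scores = rng.random(200)
    labels = rng.random(200) < 0.4
    roc = roc_curve(scores, labels)
    assert np.all(np.diff(roc.fpr) >= 0) and np.all(np.diff(roc.tpr) >= 0)
    np.testing.assert_array_equal(roc.tp + roc.fn, labels.sum())
    np.testing.assert_array_equal(roc.fp + roc.tn, (~labels).sum())


def test_trapezoid_auc_equals_pair_counting_oracle():
    rng = np.random.default_rng(123)
    for _ in range(100):
        n = int(rng.integers(10, 1000))
        # discretized scores force ties to exercise the tie handling
        scores = np.round(rng.random(n), 2)
        labels = rng.random(n) < rng.uniform(0.2, 0.8)
        if labels.all() or not labels.any():
            continue
        assert roc_curve(scores, labels).auc == pytest.approx(
            mann_whitney_auc(scores, labels), abs=1e-12
        )


# -------------------------------------------------------- threshold choice

def test_optimal_threshold_perfect_separation():
    roc = roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    thr = optimal_threshold(roc)
    i = int(np.flatnonzero(roc.thresholds == thr)[0])
    assert roc.fp[i] + roc.fn[i] == 0


def test_optimal_threshold_constant_scores():
    labels = [1, 1, 0, 0, 0]
    roc = roc_curve([0.5] * 5, labels)
    thr = optimal_threshold(roc)
    i = int(np.flatnonzero(roc.thresholds == thr)[0])
    # enumeration over the two effective operating points: min(#pos, #neg)
    assert roc.fp[i] + roc.fn[i] == min(2, 3)


def test_optimal_threshold_four_point_example():
    roc = roc_curve([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0])
    thr = optimal_threshold(roc)
    i = int(np.flatnonzero(roc.thresholds == thr)[0])
    assert roc.fp[i] + roc.fn[i] == 1
    # cost 1 is attained at operating points 0.9 and 0.4; ties break high
    assert thr == pytest.approx(0.9)


# ---------------------------------------------------------------- OVR AUC

def _two_class_scores(n=40, seed=0):
    rng = np.random.default_rng(seed)
    labels = np.array(["a", "b"] * (n // 2))
    s_a = np.where(labels == "a", rng.normal(0.7, 0.1, n), rng.normal(0.3, 0.1, n))
    scores = np.stack([s_a, 1 - s_a], axis=1)
    return scores, labels


def test_two_class_symmetry():
    scores, labels = _two_class_scores()
    res = ovr_auc(scores, labels, ("a", "b"))
    assert res["per_class"]["a"] == pytest.approx(res["per_class"]["b"])
    assert res["average"] == pytest.approx(res["per_class"]["a"])


def test_weight_scaling_invariance():
    scores, labels = _two_class_scores(seed=3)
    base = ovr_auc(scores, labels, ("a", "b"), {"a": 1.0, "b": 0.25})
    scaled = ovr_auc(scores, labels, ("a", "b"), {"a": 8.0, "b": 2.0})
    assert base["average"] == pytest.approx(scaled["average"])


def test_suppression_is_a_weighted_mean():
    """94 percent weight suppression of one class shifts the average per the
    hand-computed weighted-mean formula."""
    rng = np.random.default_rng(9)
    n = 120
    labels = np.array(["a"] * 40 + ["b"] * 40 + ["c"] * 40)
    scores = rng.random((n, 3))
    scores[labels == "a", 0] += 0.8
    scores[labels == "b", 1] += 0.4
    res = ovr_auc(scores, labels, ("a", "b", "c"), {"a": 1, "b": 1, "c": 0.06})
    per = res["per_class"]
    expected = (per["a"] + per["b"] + 0.06 * per["c"]) / 2.06
    assert res["average"] == pytest.approx(expected)


def test_substitution_isolates_other_classes():
    scores, labels = _two_class_scores(seed=5)
    alt_scores, alt_labels = _two_class_scores(seed=6)
    # primary data has no 'b'? simulate a class absent from evaluation:
    labels_eval = np.array(["a"] * len(labels))
    scores_eval = scores.copy()
    res = ovr_auc(
        scores_eval,
        labels_eval,
        ("a", "b"),
        substitutions={"b": (alt_scores, alt_labels)},
    )
    # class b scored on substitute data, flagged as such
    assert res["sources"]["b"] == "substitute"
    assert res["per_class"]["b"] == pytest.approx(
        mann_whitney_auc(alt_scores[:, 1], alt_labels == "b")
    )
    # class a itself has single-class primary data -> excluded with warning
    assert "a" in res["excluded"]


def test_all_zero_weights_rejected():
    scores, labels = _two_class_scores()
    with pytest.raises(ValueError):
        ovr_auc(scores, labels, ("a", "b"), {"a": 0.0, "b": 0.0})
    with pytest.raises(ValueError):
        ovr_auc(scores, labels, ("a", "b"), {"a": -1.0})
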