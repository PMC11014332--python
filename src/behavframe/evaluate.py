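"""Statistical evaluation: confusion matrices, precision/recall/F1,
one-vs-rest ROC/AUC with class substitution and weight suppression.

Conventions
-----------
* Confusion-matrix rows are true labels, columns predictions; a perfect
  model is diagonal.
* precision = TP / (TP + FP), recall = TP / (TP + FN),
  F1 = 2 * precision * recall / (precision + recall).  A class that is
  never predicted gets precision 0 and is flagged.
* Weighted aggregates are support-weighted (weights = true-class counts),
  which makes weighted recall identically equal to overall accuracy
  (= trace / total).
* Multiclass AUC is one-vs-rest: each class in turn is the positive class,
  all others pooled as negative; the per-class AUCs are averaged with
  optional class weights.  A class may *substitute* scores and labels from
  another fold (used when a rare class has no evaluation-fold instances,
  e.g. a running class present in too few videos), and its weight may be
  suppressed; both are annotated in the report.  OVR makes each class's
  evaluation independent, so a substitution touches no other class.
* The optimal decision point of a ROC curve is the threshold minimizing
  FP + FN, ties broken toward the higher threshold.

ROC curves are rank-based, so non-probabilistic scores (raw margins) are
fine.  Reports print ratios to 2 decimals and percentages to 1 decimal;
full precision is kept in the JSON payload.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc

__all__ = [
    "ConfusionMatrix",
    "ROCCurve",
    "MetricsReport",
    "confusion_matrix",
    "per_class_metrics",
    "weighted_metrics",
    "roc_curve",
    "ovr_auc",
    "optimal_threshold",
    "build_report",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K counts; rows true, columns predicted."""

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if counts.shape != (k, k):
            raise ValueError(f"counts shape {counts.shape} != ({k}, {k})")
        if (counts < 0).any():
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def supports(self) -> np.ndarray:
        """True-class counts (row sums)."""
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)

    @classmethod
    def from_counts(cls, classes, counts) -> "ConfusionMatrix":
        return cls(tuple(classes), np.asarray(counts))


def confusion_matrix(true_labels, predicted_labels, classes) -> ConfusionMatrix:
    """Tally per-frame (true, predicted) label pairs.

    Both label streams must be drawn from ``classes``; a never-predicted
    class simply yields an empty column.
    """
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("true and predicted label streams differ in length")
    classes = tuple(classes)
    known = set(classes)
    stray = {l for l in true_labels + predicted_labels if l not in known}
    if stray:
        raise ValueError(f"labels outside the class list: {sorted(stray)}")
    counts = _sk_confusion(true_labels, predicted_labels, labels=list(classes))
    return ConfusionMatrix(classes, counts)


def per_class_metrics(cm: ConfusionMatrix) -> pd.DataFrame:
    """Precision, recall, F1 and support per class.

    Never-predicted classes get precision 0 (and F1 0) with
    ``never_predicted`` flagged; classes with zero support get recall 0.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    counts = cm.counts.astype(float)
    tp = np.diag(counts)
    pred_totals = counts.sum(axis=0)
    supports = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred_totals > 0, tp / pred_totals, 0.0)
        recall = np.where(supports > 0, tp / supports, 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2 * precision * recall / pr, 0.0)
    return pd.DataFrame(
        {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "support": supports.astype(int),
            "never_predicted": pred_totals == 0,
        },
        index=list(cm.classes),
    )


def weighted_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Support-weighted precision/recall/F1 plus overall accuracy."""
    per = per_class_metrics(cm)
    w = per["support"].to_numpy(dtype=float)
    w = w / w.sum()
    return {
        "precision": float(per["precision"] @ w),
        "recall": float(per["recall"] @ w),
        "f1": float(per["f1"] @ w),
        "accuracy": float(np.trace(cm.counts) / cm.total),
    }


@dataclass(frozen=True)
class ROCCurve:
    """Threshold sweep with per-threshold confusion counts.

    Thresholds are descending (the leading +inf row is the predict-nothing
    operating point); FPR and TPR are nondecreasing and span (0,0)..(1,1).
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray

    @property
    def auc(self) -> float:
        return float(_trapezoid_auc(self.fpr, self.tpr))


def roc_curve(scores, binary_labels) -> ROCCurve:
    """Standard ROC over the unique scores, with trapezoidal AUC.

    ``binary_labels`` are truthy for the positive class; both classes must
    be present.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(binary_labels).astype(bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative")
    fpr, tpr, thr = _sk_roc(y.astype(int), scores, drop_intermediate=False)
    tp = np.rint(tpr * n_pos).astype(np.int64)
    fp = np.rint(fpr * n_neg).astype(np.int64)
    return ROCCurve(
        thresholds=thr,
        fpr=fpr,
        tpr=tpr,
        tp=tp,
        fp=fp,
        tn=n_neg - fp,
        fn=n_pos - tp,
    )


def optimal_threshold(roc: ROCCurve) -> float:
    """Decision point with the fewest cumulative false positives plus false
    negatives; ties go to the higher threshold."""
    costs = roc.fp + roc.fn
    # thresholds are descending, so the first argmin is the highest one
    return float(roc.thresholds[int(np.argmin(costs))])


def ovr_auc(
    scores,
    labels,
    classes,
    class_weights: dict[str, float] | None = None,
    substitutions: dict[str, tuple] | None = None,
) -> dict:
    """One-vs-rest AUC per class plus the weighted average.

    Parameters
    ----------
    scores : (n, K) array or DataFrame with one column per class
        Per-frame class scores (probabilities or raw margins).
    labels : length-n sequence of class names
        Ground truth.
    classes : ordered class names matching the score columns.
    class_weights : dict, optional
        Nonnegative per-class weights for the average (default uniform).
        Weights are renormalized, so scaling them all leaves the average
        unchanged.  Suppressing a class is weighting it down (e.g. 0.06 for
        a 94 percent suppression).
    substitutions : dict class -> (alt_scores, alt_labels), optional
        Per-class replacement data (typically the testing fold for a class
        absent from the evaluation fold).  OVR evaluation is independent
        per class, so other classes are unaffected.

    Returns
    -------
    dict with ``average``, ``per_class`` (class -> AUC), ``weights`` as
    used (normalized over included classes), and ``excluded`` / ``sources``
    annotations.
    """
    if isinstance(scores, pd.DataFrame):
        scores = scores[list(classes)].to_numpy()
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(list(labels))
    classes = tuple(classes)
    substitutions = substitutions or {}
    weights_in = {c: 1.0 for c in classes}
    if class_weights:
        if any(w < 0 for w in class_weights.values()):
            raise ValueError("class weights must be nonnegative")
        weights_in.update(class_weights)
    if sum(weights_in.values()) <= 0:
        raise ValueError("class weights must not all be zero")

    per_class: dict[str, float] = {}
    sources: dict[str, str] = {}
    excluded: list[str] = []
    for j, c in enumerate(classes):
        if c in substitutions:
            alt_scores, alt_labels = substitutions[c]
            if isinstance(alt_scores, pd.DataFrame):
                alt_scores = alt_scores[list(classes)].to_numpy()
            s = np.asarray(alt_scores, dtype=float)[:, j]
            y = np.asarray(list(alt_labels)) == c
            sources[c] = "substitute"
        else:
            s = scores[:, j]
            y = labels == c
            sources[c] = "primary"
        if y.all() or not y.any():
            warnings.warn(
                f"class {c!r} has no positive/negative split in its data; "
                "excluded from the averaged AUC",
                stacklevel=2,
            )
            excluded.append(c)
            continue
        per_class[c] = roc_curve(s, y).auc

    if not per_class:
        raise ValueError("no class had computable OVR AUC")
    wsum = sum(weights_in[c] for c in per_class)
    weights = {c: weights_in[c] / wsum for c in per_class}
    average = sum(per_class[c] * weights[c] for c in per_class)
    return {
        "average": float(average),
        "per_class": per_class,
        "weights": weights,
        "excluded": excluded,
        "sources": sources,
    }


@dataclass
class MetricsReport:
    """Full evaluation bundle for one taxonomy."""

    taxonomy: str
    cm: ConfusionMatrix
    per_class: pd.DataFrame
    weighted: dict[str, float]
    auc: dict | None = None
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        payload = {
            "taxonomy": self.taxonomy,
            "classes": list(self.cm.classes),
            "confusion_matrix": self.cm.counts.tolist(),
            "per_class": {
                c: {
                    "precision": float(r["precision"]),
                    "recall": float(r["recall"]),
                    "f1": float(r["f1"]),
                    "support": int(r["support"]),
                }
                for c, r in self.per_class.iterrows()
            },
            "weighted": self.weighted,
            "notes": self.notes,
        }
        if self.auc is not None:
            payload["auc"] = {
                "average": self.auc["average"],
                "per_class": self.auc["per_class"],
                "weights": self.auc["weights"],
                "excluded": self.auc["excluded"],
                "sources": self.auc["sources"],
            }
        return payload

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_markdown(self) -> str:
        """Tables shaped like a published evaluation report: the count
        matrix with per-class precision/recall/F1, then weighted rows."""
        lines = [f"### {self.taxonomy}", ""]
        header = (
            "| True \\ Predicted | "
            + " | ".join(self.cm.classes)
            + " | Precision | Recall | F1 |"
        )
        lines.append(header)
        lines.append("|" + "---|" * (len(self.cm.classes) + 4))
        for i, c in enumerate(self.cm.classes):
            row = self.per_class.loc[c]
            cells = " | ".join(f"{n:,}" for n in self.cm.counts[i])
            lines.append(
                f"| {c} | {cells} | {row['precision']:.2f} | "
                f"{row['recall']:.2f} | {row['f1']:.2f} |"
            )
        w = self.weighted
        lines += [
            "",
            "| Weighted precision | Weighted recall | Weighted F1 | Accuracy |",
            "|---|---|---|---|",
            f"| {w['precision']:.2f} | {w['recall']:.2f} | {w['f1']:.2f} "
            f"| {100 * w['accuracy']:.1f}% |",
        ]
        if self.auc is not None:
            lines.append("")
            lines.append(f"Averaged OVR AUC: {100 * self.auc['average']:.1f}")
            subs = [c for c, s in self.auc["sources"].items() if s == "substitute"]
            if subs:
                lines.append(f"Classes scored on substitute data: {', '.join(subs)}")
        for note in self.notes:
            lines.append(f"\nNote: {note}")
        return "\n".join(lines)


def build_report(
    taxonomy: str,
    true_labels,
    predicted_labels,
    classes,
    scores=None,
    class_weights: dict[str, float] | None = None,
    substitutions: dict[str, tuple] | None = None,
) -> MetricsReport:
    """Assemble the full metrics report from prediction streams."""
    cm = confusion_matrix(true_labels, predicted_labels, classes)
    per = per_class_metrics(cm)
    weighted = weighted_metrics(cm)
    auc_block = None
    notes: list[str] = []
    if scores is not None:
        auc_block = ovr_auc(scores, true_labels, classes, class_weights, substitutions)
        for c in auc_block["excluded"]:
            notes.append(f"class {c!r} excluded from AUC (single-class data)")
        for c, s in auc_block["sources"].items():
            if s == "substitute":
                notes.append(f"class {c!r} AUC computed on substitute-fold data")
    return MetricsReport(taxonomy, cm, per, weighted, auc_block, notes)
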