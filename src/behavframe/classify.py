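"""Per-frame behavior classification with a pluggable backend registry.

The reference backend is gradient-boosted trees (XGBoost) over tabular
pose-keypoint features — fast to train on a desk-scale CPU and independent
of any pre-trained weights.  Deep image backbones (ResNet-family, ViT, CvT)
slot in behind the same interface as adapter stubs: they require GPU
fine-tuning of pre-trained weights, so only the contract is declared here.

Training follows the test-fold early-stopping protocol: fit on the training
fold only, record the testing-fold selection metric (averaged one-vs-rest
AUC by default, accuracy optionally) after every boosting round, stop once
10 consecutive rounds bring no improvement, and revert the model to the
best round.  Boosting is additive, so fitting ``max_rounds`` trees once and
truncating at the best round is identical to halting the loop in place;
the recorded history keeps every round actually scanned.

A leakage audit is built in: training rows are selected strictly by the
video-fold map, and :func:`audit_no_leakage` proves no evaluation-fold
video contributed a training row.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xgboost as xgb

from .evaluate import ovr_auc
from .folds import FoldAssignment

__all__ = [
    "ClassifierConfig",
    "TrainedModel",
    "PredictionSet",
    "LeakageError",
    "BackendUnavailableError",
    "train_classifier",
    "predict",
    "audit_no_leakage",
    "save_model",
    "load_model",
    "BACKENDS",
]


class LeakageError(RuntimeError):
    """A training row came from a video outside the training fold."""


class BackendUnavailableError(NotImplementedError):
    """A declared backend has no desk-scale implementation."""


def _deep_stub(name: str):
    def fail(*_a, **_k):
        raise BackendUnavailableError(
            f"backend {name!r} is a declared adapter for a pre-trained deep "
            "model and requires external weights plus GPU fine-tuning; use "
            "the 'xgboost' pose-feature backend or register your own"
        )

    return fail


#: backend id -> trainer; deep image backbones are declared stubs.
BACKENDS = {
    "xgboost": None,  # bound below, after train_classifier is defined
    "resnetst": _deep_stub("resnetst"),
    "vit": _deep_stub("vit"),
    "cvt": _deep_stub("cvt"),
}


@dataclass(frozen=True)
class ClassifierConfig:
    """Boosted-trees training knobs.

    ``max_rounds`` bounds the boosting rounds scanned; ``patience`` is the
    number of rounds without testing-fold improvement before stopping;
    ``metric`` selects the early-stopping criterion (``ovr_auc`` or
    ``accuracy``); ``xgb_params`` are passed through to the booster on top
    of the library defaults (single thread, fixed seed for
    reproducibility).
    """

    max_rounds: int = 200
    patience: int = 10
    metric: str = "ovr_auc"
    xgb_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.metric not in ("ovr_auc", "accuracy"):
            raise ValueError(f"unknown selection metric {self.metric!r}")


@dataclass
class TrainedModel:
    """Fitted backend plus the metadata needed to reproduce it."""

    backend: str
    taxonomy: str
    classes: tuple[str, ...]
    feature_names: tuple[str, ...]
    booster: xgb.Booster
    seed: int
    best_iteration: int  # 1-based round count of the selected model
    rounds_scanned: int
    history: list[float]  # testing-fold metric per boosting round

    def __post_init__(self) -> None:
        if self.best_iteration > self.rounds_scanned:
            raise ValueError("best iteration cannot exceed rounds scanned")


@dataclass(frozen=True)
class PredictionSet:
    """Per-frame class-score vectors with argmax labels attached."""

    classes: tuple[str, ...]
    scores: pd.DataFrame  # columns: video_id, second_index, one per class
    predicted: pd.Series

    def score_matrix(self) -> np.ndarray:
        return self.scores[list(self.classes)].to_numpy()


def _fold_of(assignment: FoldAssignment | dict) -> dict[str, str]:
    return assignment.mapping if isinstance(assignment, FoldAssignment) else dict(assignment)


def audit_no_leakage(
    train_video_ids, assignment: FoldAssignment | dict, forbidden=("evaluation", "testing")
) -> dict:
    """Prove no testing/evaluation-fold video contributed a training row.

    Returns an audit record (counts per fold of origin); raises
    :class:`LeakageError` if any training row's video sits in a forbidden
    fold.
    """
    mapping = _fold_of(assignment)
    tally: dict[str, int] = {}
    offenders: set[str] = set()
    for vid in train_video_ids:
        fold = mapping.get(str(vid), "unassigned")
        tally[fold] = tally.get(fold, 0) + 1
        if fold in forbidden:
            offenders.add(str(vid))
    if offenders:
        raise LeakageError(
            f"training rows drawn from non-training-fold videos: {sorted(offenders)}"
        )
    return {"rows_by_fold": tally, "forbidden": list(forbidden), "clean": True}


def _select_rows(features: pd.DataFrame, mapping: dict[str, str], fold: str) -> pd.Index:
    return features.index[features["video_id"].astype(str).map(mapping) == fold]


def _metric_value(metric, y_true_idx, proba, classes):
    present = np.unique(y_true_idx)
    if metric == "accuracy":
        return float((proba.argmax(axis=1) == y_true_idx).mean())
    labels = np.asarray(classes)[y_true_idx]
    sub = [classes[i] for i in present]
    cols = [classes.index(c) for c in sub]
    return ovr_auc(proba[:, cols], labels, sub)["average"]


def train_classifier(
    features: pd.DataFrame,
    labels: pd.Series,
    assignment: FoldAssignment | dict,
    taxonomy: str = "",
    config: ClassifierConfig | None = None,
    seed: int = 0,
) -> TrainedModel:
    """Fit the boosted-trees backend with test-fold early stopping.

    Parameters
    ----------
    features : DataFrame
        Must carry ``video_id``, ``second_index`` and the keypoint feature
        columns (``k00_x`` ...).  Rows align positionally with ``labels``.
    labels : sequence of class names aligned to ``features`` rows.
    assignment : FoldAssignment or dict
        Video -> fold map; only training-fold rows are fit, testing-fold
        rows drive round selection.
    seed : int
        Fixed booster seed; identical data + seed give identical models.
    """
    config = config or ClassifierConfig()
    mapping = _fold_of(assignment)
    labels = pd.Series(np.asarray(labels), index=features.index)
    classes = tuple(sorted(labels.unique()))
    class_index = {c: i for i, c in enumerate(classes)}

    train_idx = _select_rows(features, mapping, "training")
    test_idx = _select_rows(features, mapping, "testing")
    if len(train_idx) == 0 or len(test_idx) == 0:
        raise ValueError("training and testing folds must both be nonempty")
    audit_no_leakage(features.loc[train_idx, "video_id"], mapping)

    feat_cols = [c for c in features.columns if c not in ("video_id", "second_index", "person_found")]
    x_train = features.loc[train_idx, feat_cols].to_numpy(dtype=float)
    x_test = features.loc[test_idx, feat_cols].to_numpy(dtype=float)
    y_train = labels.loc[train_idx].map(class_index).to_numpy()
    y_test = labels.loc[test_idx].map(class_index).to_numpy()

    missing_in_test = set(np.unique(y_train)) - set(np.unique(y_test))
    if missing_in_test:
        warnings.warn(
            "classes present in training but absent from testing fold: "
            f"{sorted(classes[i] for i in missing_in_test)}; the selection "
            "metric is computed on the classes present",
            stacklevel=2,
        )

    params = {
        "objective": "multi:softprob",
        "num_class": len(classes),
        "seed": int(seed),
        "nthread": 1,
        "max_depth": 6,
        "eta": 0.3,
    }
    params.update(config.xgb_params)
    dtrain = xgb.DMatrix(x_train, label=y_train, feature_names=feat_cols)
    dtest = xgb.DMatrix(x_test, label=y_test, feature_names=feat_cols)
    booster = xgb.train(params, dtrain, num_boost_round=config.max_rounds)

    # Scan the testing-fold metric round by round; additivity of boosting
    # makes truncation at the best round equivalent to stopping in place.
    history: list[float] = []
    best_score, best_round = -np.inf, 0
    rounds = 0
    for r in range(1, config.max_rounds + 1):
        proba = booster.predict(dtest, iteration_range=(0, r))
        score = _metric_value(config.metric, y_test, proba, list(classes))
        history.append(score)
        rounds = r
        if score > best_score + 1e-12:
            best_score, best_round = score, r
        elif r - best_round >= config.patience:
            break

    best = booster[: best_round]  # slice keeps the first best_round trees
    best.set_attr(best_iteration=str(best_round - 1))
    return TrainedModel(
        backend="xgboost",
        taxonomy=taxonomy,
        classes=classes,
        feature_names=tuple(feat_cols),
        booster=best,
        seed=int(seed),
        best_iteration=best_round,
        rounds_scanned=rounds,
        history=history,
    )


BACKENDS["xgboost"] = train_classifier


def predict(model: TrainedModel, features: pd.DataFrame) -> PredictionSet:
    """Score frames with a trained model.

    Deterministic; one probability vector per row (each sums to 1), argmax
    as the predicted class.  All-zero feature rows (no person detected) are
    scored like any other row.
    """
    missing = [c for c in model.feature_names if c not in features.columns]
    if missing:
        raise ValueError(f"feature table missing model columns {missing[:5]}")
    x = features[list(model.feature_names)].to_numpy(dtype=float)
    dmat = xgb.DMatrix(x, feature_names=list(model.feature_names))
    proba = model.booster.predict(dmat)
    proba = np.atleast_2d(proba)
    out = pd.DataFrame(proba, columns=list(model.classes), index=features.index)
    for key in ("video_id", "second_index"):
        if key in features.columns:
            out.insert(0, key, features[key])
    predicted = pd.Series(
        [model.classes[i] for i in proba.argmax(axis=1)],
        index=features.index,
        name="predicted",
    )
    return PredictionSet(model.classes, out, predicted)


def save_model(model: TrainedModel, directory) -> None:
    """Persist booster + metadata as a two-file archive (JSON both)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    model.booster.save_model(directory / "booster.json")
    meta = {
        "backend": model.backend,
        "taxonomy": model.taxonomy,
        "classes": list(model.classes),
        "feature_names": list(model.feature_names),
        "seed": model.seed,
        "best_iteration": model.best_iteration,
        "rounds_scanned": model.rounds_scanned,
        "history": model.history,
    }
    (directory / "metadata.json").write_text(json.dumps(meta, indent=2))


def load_model(directory) -> TrainedModel:
    directory = Path(directory)
    meta = json.loads((directory / "metadata.json").read_text())
    booster = xgb.Booster()
    booster.load_model(directory / "booster.json")
    return TrainedModel(
        backend=meta["backend"],
        taxonomy=meta["taxonomy"],
        classes=tuple(meta["classes"]),
        feature_names=tuple(meta["feature_names"]),
        booster=booster,
        seed=meta["seed"],
        best_iteration=meta["best_iteration"],
        rounds_scanned=meta["rounds_scanned"],
        history=meta["history"],
    )
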