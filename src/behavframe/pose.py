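"""Pose-keypoint features and the pluggable skeletal-extractor interface.

The tabular classification backend consumes per-frame body-landmark
features: K landmark triples (x, y, confidence) with coordinates normalized
to the unit square, flattened to a 3K vector (default K = 17, the COCO
keypoint convention).  Frames where no person is detected carry an all-zero
vector and ``person_found = False``.

Real skeletal extractors (AlphaPose and friends) run as external models and
are out of scope here; they plug in through :func:`register_extractor`, or
their output is ingested from a feature CSV.  A lightweight ``blob``
extractor ships for synthetic stick-figure frames: it thresholds the
foreground, takes the bounding box, and lays the K landmarks out at fixed
relative positions along the figure's principal axis — enough to exercise
the full feature path end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "N_KEYPOINTS",
    "PoseFeatures",
    "feature_columns",
    "register_extractor",
    "get_extractor",
    "extract_pose_features",
    "read_features",
    "write_features",
    "ExtractorUnavailableError",
]

#: Default landmark count (COCO keypoint layout).
N_KEYPOINTS = 17

KEY_COLUMNS = ("video_id", "second_index")


class ExtractorUnavailableError(RuntimeError):
    """Raised when a requested extractor backend is not registered."""


@dataclass(frozen=True)
class PoseFeatures:
    """Flattened keypoint vector for one frame."""

    video_id: str
    second_index: int
    keypoints: np.ndarray  # length 3K: (x, y, confidence) per landmark
    person_found: bool

    def __post_init__(self) -> None:
        kp = np.asarray(self.keypoints, dtype=float)
        if kp.ndim != 1 or kp.size % 3 != 0:
            raise ValueError("keypoints must be a flat 3K vector")
        if not self.person_found and np.any(kp != 0):
            raise ValueError("person_found=False requires an all-zero vector")
        object.__setattr__(self, "keypoints", kp)


def feature_columns(n_keypoints: int = N_KEYPOINTS) -> list[str]:
    """Column names k00_x, k00_y, k00_c, ... for the feature CSV dialect."""
    cols = []
    for k in range(n_keypoints):
        cols += [f"k{k:02d}_x", f"k{k:02d}_y", f"k{k:02d}_c"]
    return cols


_EXTRACTORS: dict[str, object] = {}


def register_extractor(name: str):
    """Decorator registering a callable ``frame -> (keypoints|None)``.

    The callable receives an (H, W, 3) uint8 RGB array and returns either a
    (K, 3) array of unit-square (x, y, confidence) rows, or ``None`` when no
    person is found.
    """

    def wrap(fn):
        _EXTRACTORS[name] = fn
        return fn

    return wrap


def get_extractor(name: str):
    try:
        return _EXTRACTORS[name]
    except KeyError:
        raise ExtractorUnavailableError(
            f"extractor backend {name!r} is not registered "
            f"(available: {sorted(_EXTRACTORS)}); external skeletal "
            "extractors must be run separately and their output supplied as "
            "a precomputed feature CSV via read_features()"
        ) from None


def extract_pose_features(
    frame, video_id: str = "", second_index: int = 0, extractor: str = "blob"
) -> PoseFeatures:
    """Run a registered extractor on one frame.

    Deterministic for a fixed frame; ``person_found=False`` yields the
    all-zero vector.
    """
    px = frame.pixels if hasattr(frame, "pixels") else np.asarray(frame)
    fn = get_extractor(extractor)
    kps = fn(px)
    if kps is None:
        return PoseFeatures(
            video_id, second_index, np.zeros(3 * N_KEYPOINTS), False
        )
    kps = np.asarray(kps, dtype=float)
    if kps.shape != (N_KEYPOINTS, 3):
        raise ValueError(
            f"extractor returned shape {kps.shape}, expected ({N_KEYPOINTS}, 3)"
        )
    return PoseFeatures(video_id, second_index, kps.reshape(-1), True)


# Relative landmark layout inside a detected figure's bounding box:
# head at the top-center, shoulders/hips symmetric, limbs toward corners.
_REL_LAYOUT = np.array(
    [
        [0.50, 0.05], [0.45, 0.08], [0.55, 0.08], [0.40, 0.10], [0.60, 0.10],
        [0.35, 0.25], [0.65, 0.25], [0.25, 0.40], [0.75, 0.40],
        [0.20, 0.55], [0.80, 0.55],
        [0.42, 0.55], [0.58, 0.55], [0.38, 0.75], [0.62, 0.75],
        [0.35, 0.95], [0.65, 0.95],
    ]
)


@register_extractor("blob")
def _blob_extractor(px: np.ndarray):
    """Bounding-box landmark layout for synthetic stick-figure frames."""
    mask = np.asarray(px).max(axis=2) > 10
    if not mask.any():
        return None
    h, w = mask.shape
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    top, bottom = rows[0], rows[-1] + 1
    left, right = cols[0], cols[-1] + 1
    xs = (left + _REL_LAYOUT[:, 0] * (right - left)) / w
    ys = (top + _REL_LAYOUT[:, 1] * (bottom - top)) / h
    conf = np.full(N_KEYPOINTS, 1.0)
    return np.stack([xs, ys, conf], axis=1)


def write_features(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_features(path, n_keypoints: int = N_KEYPOINTS) -> pd.DataFrame:
    """Load a feature CSV and validate its schema.

    Expected columns: video_id, second_index, then k00_x..k{K-1}_c, and
    optionally person_found (reconstructed from all-zero rows if absent).
    """
    df = pd.read_csv(path)
    needed = list(KEY_COLUMNS) + feature_columns(n_keypoints)
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"feature CSV {path} missing columns {missing[:6]}...")
    if "person_found" not in df.columns:
        vals = df[feature_columns(n_keypoints)].to_numpy()
        df["person_found"] = (vals != 0).any(axis=1)
    return df


def features_to_frame(features: list[PoseFeatures]) -> pd.DataFrame:
    """Tabulate PoseFeatures objects in the feature CSV dialect."""
    n_kp = features[0].keypoints.size // 3 if features else N_KEYPOINTS
    rows = []
    for f in features:
        row = {"video_id": f.video_id, "second_index": f.second_index}
        row.update(dict(zip(feature_columns(n_kp), f.keypoints)))
        row["person_found"] = f.person_found
        rows.append(row)
    return pd.DataFrame(rows)
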