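"""Leakage-aware assignment of whole videos to train/test/evaluation folds.

Frames of one video are visually near-duplicates, so splitting at the frame
level lets a model memorize its way to optimistic evaluation scores.  Folds
are therefore built from whole videos.  Because videos differ in length and
class mix, the assignment is chosen to make each fold's class distribution
match the pooled distribution of the whole dataset: candidates are scored
by a fold-weighted histogram chi-square distance and the feasible minimum
is kept, subject to two constraints — every class that appears in at least
three videos must appear in every fold, and fold frame shares must stay
within a tolerance of the 80/10/10 train/test/evaluation targets.

For small collections every one of the 3^N video-fold assignments is
enumerated; beyond a configurable cap a seeded random search draws
candidates biased toward the target fold sizes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .taxonomy import ClassDistribution, TaxonomyMap, class_distribution

__all__ = [
    "FOLDS",
    "VideoProfile",
    "FoldTargets",
    "FoldAssignment",
    "InfeasibleError",
    "chi2_distance",
    "pearson_chi2_distance",
    "score_assignment",
    "check_constraints",
    "build_assignment",
    "assign_folds",
    "profiles_from_seconds",
]

#: Canonical fold order; weights and target fractions follow this order.
FOLDS: tuple[str, ...] = ("training", "testing", "evaluation")


class InfeasibleError(RuntimeError):
    """No candidate assignment satisfies the constraints."""


@dataclass(frozen=True)
class VideoProfile:
    """One video's class distribution under the chosen taxonomy."""

    video_id: str
    distribution: ClassDistribution

    @property
    def n_frames(self) -> int:
        return self.distribution.total


@dataclass(frozen=True)
class FoldTargets:
    """Fold fractions, share tolerance and score weights.

    ``fractions`` are target frame shares per fold (default 80/10/10);
    ``tolerance`` is the allowed absolute deviation of a fold's realized
    frame share; ``weights`` multiply each fold's chi-square distance in the
    assignment score and default to the fractions themselves, so larger
    folds matter more.
    """

    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    tolerance: float = 0.05
    weights: tuple[float, float, float] | None = None
    min_videos_for_presence: int = 3

    def fold_weights(self) -> dict[str, float]:
        w = self.weights if self.weights is not None else self.fractions
        return dict(zip(FOLDS, w))

    def fold_fractions(self) -> dict[str, float]:
        return dict(zip(FOLDS, self.fractions))


@dataclass(frozen=True)
class FoldAssignment:
    """A video -> fold map with its distributions, score and feasibility."""

    mapping: dict[str, str] = field(hash=False)
    fold_distributions: dict[str, ClassDistribution] = field(hash=False)
    score: float
    feasible: bool
    violations: tuple[str, ...] = ()

    def videos_in(self, fold: str) -> list[str]:
        return sorted(v for v, f in self.mapping.items() if f == fold)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.mapping.items()), columns=["video_id", "fold"]
        )


def chi2_distance(p: ClassDistribution, q: ClassDistribution) -> float:
    """Histogram chi-square distance between two class distributions.

    Both distributions are normalized to proportions, then

        D(p, q) = 1/2 * sum_i (p_i - q_i)^2 / (p_i + q_i)

    over classes with ``p_i + q_i > 0``.  Symmetric, zero iff the
    proportions agree, and at most 1 (attained by disjoint supports).
    """
    pp, qq = p.proportions(), q.proportions()
    if tuple(pp) != tuple(qq):
        raise ValueError("distributions are over different class sets")
    d = 0.0
    for c in pp:
        s = pp[c] + qq[c]
        if s > 0:
            d += (pp[c] - qq[c]) ** 2 / s
    return 0.5 * d


def pearson_chi2_distance(p: ClassDistribution, q: ClassDistribution) -> float:
    """Pearson goodness-of-fit form, sum (p_i - q_i)^2 / q_i, with q as the
    reference; asymmetric alternative to :func:`chi2_distance`."""
    pp, qq = p.proportions(), q.proportions()
    return sum(
        (pp[c] - qq[c]) ** 2 / qq[c] for c in pp if qq[c] > 0
    )


def _fold_distributions(
    mapping: dict[str, str], profiles: dict[str, VideoProfile], classes: tuple[str, ...]
) -> dict[str, ClassDistribution]:
    sums = {f: {c: 0 for c in classes} for f in FOLDS}
    for vid, fold in mapping.items():
        for c, n in profiles[vid].distribution.counts.items():
            sums[fold][c] += n
    return {
        f: ClassDistribution(cnt, sum(cnt.values())) for f, cnt in sums.items()
    }


def score_assignment(
    fold_distributions: dict[str, ClassDistribution],
    pooled: ClassDistribution,
    fold_weights: dict[str, float] | None = None,
) -> float:
    """Weighted sum of per-fold chi-square distances to the pooled
    distribution; ``inf`` if any fold is empty (infeasible)."""
    if fold_weights is None:
        fold_weights = FoldTargets().fold_weights()
    total = 0.0
    for fold in FOLDS:
        dist = fold_distributions[fold]
        if dist.total == 0:
            return float("inf")
        total += fold_weights[fold] * chi2_distance(dist, pooled)
    return total


def check_constraints(
    mapping: dict[str, str],
    fold_distributions: dict[str, ClassDistribution],
    profiles: dict[str, VideoProfile],
    targets: FoldTargets,
) -> tuple[bool, tuple[str, ...]]:
    """Evaluate the feasibility constraints for one candidate assignment.

    Violations reported:

    * ``empty_fold:<fold>`` — a fold holds no frames;
    * ``class_absent:<class>:<fold>`` — a class present in at least
      ``targets.min_videos_for_presence`` videos is missing from a fold
      (classes in fewer videos are exempt: covering every fold is not
      possible for them);
    * ``fold_share:<fold>`` — the fold's frame share deviates from its
      target fraction by more than ``targets.tolerance``.
    """
    violations: list[str] = []
    grand_total = sum(p.n_frames for p in profiles.values())

    for fold in FOLDS:
        if fold_distributions[fold].total == 0:
            violations.append(f"empty_fold:{fold}")

    classes = next(iter(profiles.values())).distribution.classes
    videos_with = {
        c: sum(1 for p in profiles.values() if p.distribution.counts[c] > 0)
        for c in classes
    }
    for c in classes:
        if videos_with[c] < targets.min_videos_for_presence:
            continue
        for fold in FOLDS:
            if fold_distributions[fold].counts[c] == 0:
                violations.append(f"class_absent:{c}:{fold}")

    fractions = targets.fold_fractions()
    for fold in FOLDS:
        share = fold_distributions[fold].total / grand_total
        if abs(share - fractions[fold]) > targets.tolerance + 1e-12:
            violations.append(f"fold_share:{fold}")

    return (not violations), tuple(violations)


def build_assignment(
    mapping: dict[str, str],
    profiles: list[VideoProfile] | dict[str, VideoProfile],
    targets: FoldTargets | None = None,
) -> FoldAssignment:
    """Materialize distributions, score and feasibility for a given map."""
    targets = targets or FoldTargets()
    prof = {p.video_id: p for p in profiles} if not isinstance(profiles, dict) else profiles
    missing = set(prof) - set(mapping)
    if missing:
        raise ValueError(f"videos not assigned to any fold: {sorted(missing)}")
    classes = next(iter(prof.values())).distribution.classes
    dists = _fold_distributions(mapping, prof, classes)
    pooled = _pooled(prof, classes)
    feasible, violations = check_constraints(mapping, dists, prof, targets)
    score = score_assignment(dists, pooled, targets.fold_weights())
    return FoldAssignment(dict(mapping), dists, score, feasible, violations)


def _pooled(profiles: dict[str, VideoProfile], classes) -> ClassDistribution:
    counts = {c: 0 for c in classes}
    for p in profiles.values():
        for c, n in p.distribution.counts.items():
            counts[c] += n
    return ClassDistribution(counts, sum(counts.values()))


def _lex_key(mapping: dict[str, str], order: list[str]) -> tuple[str, ...]:
    return tuple(mapping[v] for v in order)


def assign_folds(
    profiles: list[VideoProfile],
    targets: FoldTargets | None = None,
    mode: str = "exhaustive",
    seed: int = 0,
    n_candidates: int = 5000,
    cap: int = 3**12,
) -> FoldAssignment:
    """Find the minimal-score feasible video-fold assignment.

    ``exhaustive`` mode enumerates all 3^N assignments (N videos), which is
    exact; it refuses to run past ``cap`` candidates.  ``random_search``
    draws ``n_candidates`` assignments from a seeded generator that places
    each video independently with probabilities equal to the target fold
    fractions, and keeps the best feasible draw — reproducible for a fixed
    seed, and never better than the exhaustive optimum.

    Ties on score are broken by the lexicographically smallest fold tuple
    over videos sorted by id.

    Raises
    ------
    InfeasibleError
        No candidate satisfied the constraints; the message tallies which
        constraints were binding.
    """
    targets = targets or FoldTargets()
    if len(profiles) < 3:
        raise ValueError("need at least 3 videos to populate three folds")
    prof = {p.video_id: p for p in profiles}
    order = sorted(prof)
    classes = next(iter(prof.values())).distribution.classes
    pooled = _pooled(prof, classes)
    weights = targets.fold_weights()

    if mode == "exhaustive":
        n_total = 3 ** len(order)
        if n_total > cap:
            raise ValueError(
                f"exhaustive enumeration of {n_total} candidates exceeds the "
                f"cap ({cap}); use mode='random_search'"
            )
        candidates = (
            dict(zip(order, combo))
            for combo in itertools.product(FOLDS, repeat=len(order))
        )
    elif mode == "random_search":
        rng = np.random.default_rng(seed)
        fracs = list(targets.fractions)
        draws = rng.choice(len(FOLDS), size=(n_candidates, len(order)), p=fracs)
        candidates = (
            {v: FOLDS[k] for v, k in zip(order, row)} for row in draws
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")

    best: FoldAssignment | None = None
    best_key: tuple[str, ...] | None = None
    violation_tally: dict[str, int] = {}
    for mapping in candidates:
        dists = _fold_distributions(mapping, prof, classes)
        feasible, violations = check_constraints(mapping, dists, prof, targets)
        if not feasible:
            for v in violations:
                kind = v.split(":", 1)[0]
                violation_tally[kind] = violation_tally.get(kind, 0) + 1
            continue
        score = score_assignment(dists, pooled, weights)
        key = _lex_key(mapping, order)
        if (
            best is None
            or score < best.score - 1e-15
            or (abs(score - best.score) <= 1e-15 and key < best_key)
        ):
            best = FoldAssignment(mapping, dists, score, True, ())
            best_key = key

    if best is None:
        raise InfeasibleError(
            "no feasible video-fold assignment; binding constraints "
            f"(violation counts over candidates): {violation_tally}"
        )
    return best


def profiles_from_seconds(
    seconds: pd.DataFrame, tax: TaxonomyMap, label_column: str | None = None
) -> list[VideoProfile]:
    """Build per-video class profiles from a rasterized seconds table.

    One frame per labeled second, so fold bookkeeping is in frames.  The
    label column defaults to the taxonomy's short column (t1/t2/t3).
    """
    col = label_column or tax.name.split("_")[0].lower()
    if col not in seconds.columns:
        raise KeyError(f"seconds table has no column {col!r}")
    profiles = []
    for vid, grp in seconds.groupby("video_id", sort=True):
        profiles.append(
            VideoProfile(str(vid), class_distribution(grp[col], tax))
        )
    return profiles
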