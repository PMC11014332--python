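"""Chi-square distance and the video-fold assignment optimizer.

The exhaustive optimizer is checked against an independent brute-force
enumeration written here with plain loops and its own chi-square formula.
"""

import itertools

import numpy as np
import pytest

from behavframe.folds import (
    FOLDS,
    FoldTargets,
    InfeasibleError,
    VideoProfile,
    assign_folds,
    build_assignment,
    chi2_distance,
    pearson_chi2_distance,
    score_assignment,
)
from behavframe.taxonomy import ClassDistribution


def dist(**counts):
    return ClassDistribution(dict(counts), sum(counts.values()))


# ------------------------------------------------------------- chi-square

def test_chi2_identity_is_zero():
    d = dist(a=30, b=70)
    assert chi2_distance(d, d) == 0.0
    # equal proportions at different totals are also distance zero
    assert chi2_distance(dist(a=3, b=7), dist(a=30, b=70)) == pytest.approx(0.0)


def test_chi2_disjoint_one_hot_is_one():
    # hand evaluation: 1/2 * (1^2/1 + 1^2/1) = 1
    assert chi2_distance(dist(a=5, b=0), dist(a=0, b=7)) == pytest.approx(1.0)


def test_chi2_symmetry_on_random_pairs():
    rng = np.random.default_rng(0)
    for _ in range(1000):
        p = dist(a=int(rng.integers(0, 50)), b=int(rng.integers(1, 50)),
                 c=int(rng.integers(0, 50)))
        q = dist(a=int(rng.integers(1, 50)), b=int(rng.integers(0, 50)),
                 c=int(rng.integers(0, 50)))
        assert chi2_distance(p, q) == pytest.approx(chi2_distance(q, p))
        assert 0.0 <= chi2_distance(p, q) <= 1.0


def test_chi2_rejects_empty_and_mismatched():
    with pytest.raises(ValueError):
        chi2_distance(dist(a=0, b=0), dist(a=1, b=1))
    with pytest.raises(ValueError):
        chi2_distance(dist(a=1, b=1), dist(a=1, c=1))


def test_pearson_alternative_form():
    p, q = dist(a=1, b=1), dist(a=1, b=3)
    # ((0.5-0.25)^2/0.25 + (0.5-0.75)^2/0.75)
    assert pearson_chi2_distance(p, q) == pytest.approx(0.25 + 0.25 / 3)


# ---------------------------------------------------------------- scoring

def _profiles(spec):
    """spec: {vid: {class: count}} -> list of VideoProfile over a common
    class set."""
    classes = sorted({c for counts in spec.values() for c in counts})
    out = []
    for vid, counts in spec.items():
        full = {c: counts.get(c, 0) for c in classes}
        out.append(VideoProfile(vid, ClassDistribution(full, sum(full.values()))))
    return out


TOY4 = _profiles(
    {
        "a": {"x": 40, "y": 0},
        "b": {"x": 0, "y": 40},
        "c": {"x": 5, "y": 5},
        "d": {"x": 5, "y": 5},
    }
)


def test_score_zero_when_folds_match_pooled():
    profiles = _profiles({"a": {"x": 8, "y": 2}, "b": {"x": 8, "y": 2}, "c": {"x": 8, "y": 2}})
    a = build_assignment({"a": "training", "b": "testing", "c": "evaluation"}, profiles)
    assert a.score == pytest.approx(0.0)


def test_score_prefers_even_class_spread():
    # mixing the one-hot videos across train leaves balanced small folds;
    # putting both one-hots in train starves the others of one class
    even = build_assignment(
        {"a": "training", "b": "training", "c": "testing", "d": "evaluation"}, TOY4
    )
    skewed = build_assignment(
        {"a": "training", "c": "training", "b": "testing", "d": "evaluation"}, TOY4
    )
    assert even.score < skewed.score


def test_weight_collapse_to_training_fold():
    profiles = TOY4
    mapping = {"a": "training", "b": "training", "c": "testing", "d": "evaluation"}
    a = build_assignment(mapping, profiles)
    pooled = ClassDistribution({"x": 50, "y": 50}, 100)
    only_train = score_assignment(
        a.fold_distributions, pooled, {"training": 1.0, "testing": 0.0, "evaluation": 0.0}
    )
    assert only_train == pytest.approx(
        chi2_distance(a.fold_distributions["training"], pooled)
    )


def test_empty_fold_scores_infinite_and_violates():
    mapping = {"a": "training", "b": "training", "c": "training", "d": "testing"}
    a = build_assignment(mapping, TOY4)
    assert not a.feasible
    assert any(v.startswith("empty_fold:evaluation") for v in a.violations)
    assert a.score == float("inf")


# ------------------------------------------------------------ constraints

def test_rare_class_exempt_from_presence_constraint():
    # class y present in only 2 videos: absence from a fold is not a violation
    profiles = _profiles(
        {
            "a": {"x": 80, "y": 1},
            "b": {"x": 10, "y": 1},
            "c": {"x": 10},
        }
    )
    a = build_assignment(
        {"a": "training", "b": "testing", "c": "evaluation"}, profiles,
        FoldTargets(tolerance=0.2),
    )
    assert all(not v.startswith("class_absent") for v in a.violations)


def test_common_class_absence_is_a_violation():
    profiles = _profiles(
        {
            "a": {"x": 70, "y": 10},
            "b": {"x": 8, "y": 2},
            "c": {"x": 8, "y": 2},
            "d": {"x": 10},
            "e": {"x": 10, "y": 5},
        }
    )
    mapping = {"a": "training", "b": "training", "c": "testing", "e": "testing",
               "d": "evaluation"}
    a = build_assignment(mapping, profiles, FoldTargets(tolerance=0.5))
    assert "class_absent:y:evaluation" in a.violations


def test_fold_share_tolerance():
    profiles = _profiles(
        {"a": {"x": 78}, "b": {"x": 11}, "c": {"x": 11}}
    )
    mapping = {"a": "training", "b": "testing", "c": "evaluation"}
    a = build_assignment(mapping, profiles, FoldTargets(tolerance=0.05))
    assert a.feasible  # shares (0.78, 0.11, 0.11) inside +/-0.05
    tight = build_assignment(mapping, profiles, FoldTargets(tolerance=0.005))
    assert any(v.startswith("fold_share") for v in tight.violations)


# -------------------------------------------------------------- optimizer

def _oracle_chi2(p_counts, q_counts):
    pt, qt = sum(p_counts), sum(q_counts)
    d = 0.0
    for pc, qc in zip(p_counts, q_counts):
        p, q = pc / pt, qc / qt
        if p + q > 0:
            d += (p - q) ** 2 / (p + q)
    return d / 2.0


def brute_force_optimum(profiles, targets):
    """Independent enumeration of all 3^N assignments with plain loops."""
    vids = sorted(p.video_id for p in profiles)
    counts = {p.video_id: [p.distribution.counts[c] for c in p.distribution.classes]
              for p in profiles}
    classes = list(profiles[0].distribution.classes)
    n_class = len(classes)
    pooled = [sum(counts[v][j] for v in vids) for j in range(n_class)]
    grand = sum(pooled)
    videos_with = [sum(1 for v in vids if counts[v][j] > 0) for j in range(n_class)]
    weights = dict(zip(FOLDS, targets.weights or targets.fractions))
    fracs = dict(zip(FOLDS, targets.fractions))
    best = None
    for combo in itertools.product(FOLDS, repeat=len(vids)):
        fold_counts = {f: [0] * n_class for f in FOLDS}
        for v, f in zip(vids, combo):
            for j in range(n_class):
                fold_counts[f][j] += counts[v][j]
        totals = {f: sum(fold_counts[f]) for f in FOLDS}
        if any(t == 0 for t in totals.values()):
            continue
        ok = True
        for j in range(n_class):
            if videos_with[j] >= targets.min_videos_for_presence:
                if any(fold_counts[f][j] == 0 for f in FOLDS):
                    ok = False
                    break
        if ok:
            for f in FOLDS:
                if abs(totals[f] / grand - fracs[f]) > targets.tolerance + 1e-12:
                    ok = False
                    break
        if not ok:
            continue
        score = sum(
            weights[f] * _oracle_chi2(fold_counts[f], pooled) for f in FOLDS
        )
        if best is None or score < best:
            best = score
    return best


def test_exhaustive_matches_brute_force_on_benchmark(benchmark_profiles):
    targets = FoldTargets()
    optimum = assign_folds(benchmark_profiles, targets, mode="exhaustive")
    oracle = brute_force_optimum(benchmark_profiles, targets)
    assert optimum.feasible
    assert optimum.score == pytest.approx(oracle, abs=1e-12)


@pytest.mark.parametrize("seed", [0, 1, 7, 99])
def test_random_search_never_beats_exhaustive(benchmark_profiles, seed):
    targets = FoldTargets()
    optimum = assign_folds(benchmark_profiles, targets, mode="exhaustive")
    rnd = assign_folds(
        benchmark_profiles, targets, mode="random_search", seed=seed, n_candidates=500
    )
    assert rnd.score >= optimum.score - 1e-12
    again = assign_folds(
        benchmark_profiles, targets, mode="random_search", seed=seed, n_candidates=500
    )
    assert again.mapping == rnd.mapping  # seed determinism


def test_symmetric_videos_tie_break_lexicographic():
    profiles = _profiles(
        {"a": {"x": 6, "y": 4}, "b": {"x": 6, "y": 4}, "c": {"x": 6, "y": 4}}
    )
    targets = FoldTargets(fractions=(1 / 3, 1 / 3, 1 / 3), tolerance=0.05)
    a = assign_folds(profiles, targets)
    assert a.score == pytest.approx(0.0)
    # all 6 one-per-fold assignments tie at 0; the lexicographically smallest
    # fold tuple over (a, b, c) is (evaluation, testing, training)
    assert a.mapping == {"a": "evaluation", "b": "testing", "c": "training"}


def test_added_constraint_never_improves_score(benchmark_profiles):
    loose = assign_folds(benchmark_profiles, FoldTargets(tolerance=0.10))
    tight = assign_folds(benchmark_profiles, FoldTargets(tolerance=0.05))
    assert tight.score >= loose.score - 1e-12


def test_infeasible_raises_listing_constraints():
    profiles = _profiles({"a": {"x": 98}, "b": {"x": 1}, "c": {"x": 1}})
    with pytest.raises(InfeasibleError, match="fold_share"):
        assign_folds(profiles, FoldTargets(tolerance=0.01))


def test_exhaustive_cap_and_minimum_videos():
    profiles = _profiles({f"v{i}": {"x": 10} for i in range(14)})
    with pytest.raises(ValueError, match="cap"):
        assign_folds(profiles, FoldTargets())
    with pytest.raises(ValueError, match="at least 3"):
        assign_folds(profiles[:2], FoldTargets())
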