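"""Behavior taxonomies and class distributions.

Raw direct-observation codes live on two annotation channels: a posture /
whole-body-movement channel (14 codes, from "lying down" to "sport movement")
and an intensity channel ("sedentary", "light", "moderate", "vigorous" —
the MET-based intensity categories: light < 3 METs, moderate 3–5.99,
vigorous ≥ 6; these cutoffs govern the human annotation, not any computation
here).  A :class:`TaxonomyMap` consolidates the raw vocabulary of one channel
into a small fixed class set:

* ``T1_sedentary`` — sedentary (sitting or lying) vs. active, posture channel;
* ``T2_activity_type`` — sedentary / mixed_movement / walking / running,
  posture channel;
* ``T3_intensity`` — the four intensity codes verbatim, intensity channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

__all__ = [
    "POSTURE_CODES",
    "INTENSITY_CODES",
    "UNLABELED",
    "TaxonomyMap",
    "ClassDistribution",
    "MappingError",
    "get_taxonomy",
    "TAXONOMY_NAMES",
    "apply_taxonomy",
    "class_distribution",
]

#: Raw posture / whole-body-movement vocabulary (second annotation pass).
POSTURE_CODES: tuple[str, ...] = (
    "lying down",
    "sitting/reclining",
    "kneeling/squatting",
    "stretching",
    "standing",
    "stand and move",
    "walk",
    "walk with load",
    "running",
    "biking",
    "ascending stairs",
    "descending stairs",
    "muscle strengthening activities",
    "sport movement",
)

#: Raw intensity vocabulary (MET-based annotation categories).
INTENSITY_CODES: tuple[str, ...] = ("sedentary", "light", "moderate", "vigorous")

#: Sentinel for seconds with no annotation coverage.
UNLABELED = "unlabeled"


class MappingError(KeyError):
    """A raw code has no class under the requested taxonomy."""


@dataclass(frozen=True)
class TaxonomyMap:
    """Total mapping from one channel's raw codes to a fixed class list.

    Parameters
    ----------
    name : str
        Taxonomy identifier (``T1_sedentary``, ``T2_activity_type``,
        ``T3_intensity``, or any user-defined name).
    classes : tuple of str
        Ordered class names; the order fixes confusion-matrix axes.
    rule : dict
        Raw code -> class.  Must cover every code that will be mapped.
    channel : str
        Which annotation channel the taxonomy reads (``posture`` or
        ``intensity``).
    """

    name: str
    classes: tuple[str, ...]
    rule: dict[str, str] = field(hash=False)
    channel: str = "posture"

    def __post_init__(self) -> None:
        bad = {c for c in self.rule.values() if c not in self.classes}
        if bad:
            raise ValueError(f"rule maps to unknown classes: {sorted(bad)}")

    def apply(self, raw_code: str) -> str:
        """Map one raw code to its class; the ``unlabeled`` sentinel passes
        through unchanged."""
        if raw_code == UNLABELED:
            return UNLABELED
        try:
            return self.rule[raw_code]
        except KeyError:
            raise MappingError(
                f"raw code {raw_code!r} has no class under taxonomy {self.name!r}"
            ) from None

    # -- YAML round trip ---------------------------------------------------
    def to_yaml(self, path) -> None:
        payload = {
            "name": self.name,
            "channel": self.channel,
            "classes": list(self.classes),
            "rule": dict(self.rule),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TaxonomyMap":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(
            name=payload["name"],
            classes=tuple(payload["classes"]),
            rule=dict(payload["rule"]),
            channel=payload.get("channel", "posture"),
        )


def _t1() -> TaxonomyMap:
    sedentary = {"lying down", "sitting/reclining"}
    rule = {c: ("sedentary" if c in sedentary else "active") for c in POSTURE_CODES}
    return TaxonomyMap("T1_sedentary", ("sedentary", "active"), rule, "posture")


def _t2() -> TaxonomyMap:
    rule = {}
    for code in POSTURE_CODES:
        if code in ("lying down", "sitting/reclining"):
            rule[code] = "sedentary"
        elif code in ("walk", "walk with load"):
            rule[code] = "walking"
        elif code == "running":
            rule[code] = "running"
        else:
            rule[code] = "mixed_movement"
    return TaxonomyMap(
        "T2_activity_type",
        ("sedentary", "mixed_movement", "walking", "running"),
        rule,
        "posture",
    )


def _t3() -> TaxonomyMap:
    # Intensity codes map 1:1; MET cutoffs are applied by the annotator.
    return TaxonomyMap(
        "T3_intensity",
        INTENSITY_CODES,
        {c: c for c in INTENSITY_CODES},
        "intensity",
    )


_BUILTIN = {"T1_sedentary": _t1, "T2_activity_type": _t2, "T3_intensity": _t3}
TAXONOMY_NAMES: tuple[str, ...] = tuple(_BUILTIN)


def get_taxonomy(name: str) -> TaxonomyMap:
    """Return one of the three built-in taxonomies by name.

    Accepts the full name or the short aliases ``T1``/``T2``/``T3``.
    """
    aliases = {"T1": "T1_sedentary", "T2": "T2_activity_type", "T3": "T3_intensity"}
    name = aliases.get(name, name)
    try:
        return _BUILTIN[name]()
    except KeyError:
        raise KeyError(
            f"unknown taxonomy {name!r}; built-ins: {sorted(_BUILTIN)}"
        ) from None


def apply_taxonomy(raw_code: str, tax: TaxonomyMap) -> str:
    """Functional form of :meth:`TaxonomyMap.apply`."""
    return tax.apply(raw_code)


@dataclass(frozen=True)
class ClassDistribution:
    """Per-class counts over a fixed class list.

    ``counts`` always contains every class of the originating taxonomy,
    zero-count classes included, so distributions over the same taxonomy are
    always comparable.
    """

    counts: dict[str, int] = field(hash=False)
    total: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("class counts must be nonnegative")
        if self.total != sum(self.counts.values()):
            raise ValueError("total must equal the sum of counts")

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(self.counts)

    def proportions(self) -> dict[str, float]:
        """Normalized class shares; errors on an empty distribution."""
        if self.total == 0:
            raise ValueError("cannot normalize an empty class distribution")
        return {c: n / self.total for c, n in self.counts.items()}

    def __add__(self, other: "ClassDistribution") -> "ClassDistribution":
        if tuple(self.counts) != tuple(other.counts):
            raise ValueError("distributions are over different class sets")
        merged = {c: self.counts[c] + other.counts[c] for c in self.counts}
        return ClassDistribution(merged, self.total + other.total)


def class_distribution(labels, tax: TaxonomyMap, *, skip_unlabeled: bool = True) -> ClassDistribution:
    """Tally class labels into a :class:`ClassDistribution`.

    Every taxonomy class appears in the result, zero counts included.
    ``unlabeled`` sentinels are skipped by default; any other label outside
    the taxonomy's classes raises :class:`MappingError`.
    """
    counts = {c: 0 for c in tax.classes}
    total = 0
    for lab in labels:
        if lab == UNLABELED and skip_unlabeled:
            continue
        if lab not in counts:
            raise MappingError(f"label {lab!r} not in taxonomy {tax.name!r} classes")
        counts[lab] += 1
        total += 1
    return ClassDistribution(counts, total)
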