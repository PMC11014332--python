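"""Event-based annotation logs and their rasterization to per-second labels.

Direct-observation software exports annotations as *events*: labeled time
intervals on a channel (posture or intensity) of one video.  Downstream
frame classification needs one label per second, so events are rasterized
onto a 0-based half-open second grid ``[i, i+1)``: each second takes the
code covering the largest fraction of it (the ">50 percent" primary-behavior
rule), seconds touched by more than one code are flagged as transitions, and
seconds with no coverage get the ``unlabeled`` sentinel.

The on-disk dialect is a plain CSV with header
``video_id,channel,label,start_s,end_s``, times in decimal seconds from
video start — deliberately minimal so any annotation tool's export can be
converted to it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .taxonomy import UNLABELED, TaxonomyMap

__all__ = [
    "AnnotationEvent",
    "SecondRecord",
    "SchemaError",
    "ValidationError",
    "OverlapWarning",
    "parse_events",
    "write_events",
    "rasterize",
    "seconds_to_frame",
    "write_seconds",
]

REQUIRED_COLUMNS = ("video_id", "channel", "label", "start_s", "end_s")
CHANNELS = ("posture", "intensity", "domain")

#: Interval arithmetic tolerance, seconds.
TOL = 1e-9


class SchemaError(ValueError):
    """The events file is missing required columns."""


class ValidationError(ValueError):
    """A row violates an event invariant (e.g. a degenerate interval)."""


class OverlapWarning(UserWarning):
    """Two events on the same channel of the same video overlap."""


@dataclass(frozen=True, order=True)
class AnnotationEvent:
    """One labeled interval on one channel of one video."""

    video_id: str
    channel: str
    start_s: float
    end_s: float
    label: str

    def __post_init__(self) -> None:
        if not self.label:
            raise ValidationError("event label must be nonempty")
        if self.start_s < 0:
            raise ValidationError(f"start_s must be >= 0, got {self.start_s}")
        if not self.end_s > self.start_s:
            raise ValidationError(
                f"end_s must exceed start_s, got [{self.start_s}, {self.end_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class SecondRecord:
    """Consolidated labels for one half-open second ``[i, i+1)`` of a video.

    ``is_transition`` is true when more than one distinct code intersects
    the second on either channel.
    """

    video_id: str
    second_index: int
    posture: str
    intensity: str
    is_transition: bool

    def __post_init__(self) -> None:
        if self.second_index < 0:
            raise ValidationError("second_index must be >= 0")


def parse_events(path, dialect: dict | None = None) -> list[AnnotationEvent]:
    """Read an events CSV into validated :class:`AnnotationEvent` objects.

    Parameters
    ----------
    path : path-like
        CSV with the columns named by ``dialect`` (defaults to
        ``video_id,channel,label,start_s,end_s``).
    dialect : dict, optional
        Maps the canonical column names to the file's column names, for
        ingesting foreign exports without rewriting them.

    Returns
    -------
    list of AnnotationEvent sorted by ``(video_id, channel, start_s)``.

    Raises
    ------
    SchemaError
        A required column is absent.
    ValidationError
        A row has ``end_s <= start_s``, an empty label, or a negative start;
        the message names the offending row (1-based, header excluded).

    Warns
    -----
    OverlapWarning
        Two same-channel events of one video overlap by more than the
        floating tolerance; the warning lists both row numbers.
    """
    colmap = {c: c for c in REQUIRED_COLUMNS}
    if dialect:
        colmap.update(dialect)
    df = pd.read_csv(path)
    missing = [c for c, src in colmap.items() if src not in df.columns]
    if missing:
        raise SchemaError(
            f"events file {path} is missing columns {missing} "
            f"(found {list(df.columns)})"
        )

    events: list[tuple[int, AnnotationEvent]] = []
    for idx, row in df.iterrows():
        rownum = int(idx) + 1
        try:
            ev = AnnotationEvent(
                video_id=str(row[colmap["video_id"]]),
                channel=str(row[colmap["channel"]]),
                start_s=float(row[colmap["start_s"]]),
                end_s=float(row[colmap["end_s"]]),
                label=str(row[colmap["label"]]),
            )
        except ValidationError as err:
            raise ValidationError(f"row {rownum}: {err}") from None
        events.append((rownum, ev))

    _warn_overlaps(events)
    events.sort(key=lambda t: (t[1].video_id, t[1].channel, t[1].start_s, t[0]))
    return [ev for _, ev in events]


def _warn_overlaps(numbered: list[tuple[int, AnnotationEvent]]) -> None:
    by_key: dict[tuple[str, str], list[tuple[int, AnnotationEvent]]] = {}
    for rownum, ev in numbered:
        by_key.setdefault((ev.video_id, ev.channel), []).append((rownum, ev))
    for (vid, chan), group in by_key.items():
        group = sorted(group, key=lambda t: (t[1].start_s, t[0]))
        for (ra, a), (rb, b) in zip(group, group[1:]):
            overlap = a.end_s - b.start_s
            if overlap > TOL:
                warnings.warn(
                    f"events overlap by {overlap:g}s on channel {chan!r} of "
                    f"video {vid!r}: rows {ra} and {rb}",
                    OverlapWarning,
                    stacklevel=3,
                )


def write_events(events: list[AnnotationEvent], path) -> None:
    """Write events back out in the canonical CSV dialect."""
    df = pd.DataFrame(
        [
            {
                "video_id": e.video_id,
                "channel": e.channel,
                "label": e.label,
                "start_s": e.start_s,
                "end_s": e.end_s,
            }
            for e in events
        ],
        columns=list(REQUIRED_COLUMNS),
    )
    df.to_csv(path, index=False)


def _rasterize_channel(
    events: list[AnnotationEvent], duration_s: int
) -> tuple[list[str], list[bool]]:
    """Per-second (label, multi-code flag) for one channel's events.

    The label is the code with the strictly largest coverage of the second;
    an exact coverage tie goes to the code whose earliest contributing event
    starts first (and then alphabetically, for full determinism).
    """
    labels = [UNLABELED] * duration_s
    multi = [False] * duration_s
    # coverage[i]: code -> (summed overlap, earliest contributing start)
    coverage: list[dict[str, list[float]]] = [dict() for _ in range(duration_s)]
    for ev in events:
        lo = max(0, int(ev.start_s))
        hi = min(duration_s, int(-(-ev.end_s // 1)))  # ceil
        for i in range(lo, hi):
            ov = min(ev.end_s, i + 1) - max(ev.start_s, i)
            if ov <= TOL:
                continue
            slot = coverage[i].setdefault(ev.label, [0.0, ev.start_s])
            slot[0] += ov
            slot[1] = min(slot[1], ev.start_s)
    for i, cov in enumerate(coverage):
        if not cov:
            continue
        multi[i] = len(cov) > 1
        labels[i] = min(cov, key=lambda c: (-cov[c][0], cov[c][1], c))
    return labels, multi


def rasterize(
    events: list[AnnotationEvent],
    duration_s: int,
    channels: tuple[str, str] = ("posture", "intensity"),
) -> list[SecondRecord]:
    """Convert one video's events into per-second :class:`SecondRecord`\\ s.

    Returns exactly ``duration_s`` records.  For each second and channel the
    primary code is the one covering the largest fraction of ``[i, i+1)``;
    ``is_transition`` is true when more than one code intersects the second
    on either channel; uncovered seconds get the ``unlabeled`` sentinel.

    All events must belong to a single video.
    """
    if duration_s < 1:
        raise ValueError("duration_s must be >= 1")
    vids = {e.video_id for e in events}
    if len(vids) > 1:
        raise ValueError(f"events span multiple videos: {sorted(vids)}")
    video_id = vids.pop() if vids else ""

    post_ch, int_ch = channels
    posture, p_multi = _rasterize_channel(
        [e for e in events if e.channel == post_ch], duration_s
    )
    intensity, i_multi = _rasterize_channel(
        [e for e in events if e.channel == int_ch], duration_s
    )
    return [
        SecondRecord(video_id, i, posture[i], intensity[i], p_multi[i] or i_multi[i])
        for i in range(duration_s)
    ]


def seconds_to_frame(
    records: list[SecondRecord], taxonomies: list[TaxonomyMap] | None = None
) -> pd.DataFrame:
    """Tabulate SecondRecords, optionally adding one column per taxonomy.

    Taxonomy columns are named t1/t2/t3 for the built-ins (lower-cased short
    name), or the full taxonomy name otherwise.
    """
    df = pd.DataFrame(
        {
            "video_id": [r.video_id for r in records],
            "second_index": [r.second_index for r in records],
            "posture": [r.posture for r in records],
            "intensity": [r.intensity for r in records],
            "is_transition": [r.is_transition for r in records],
        }
    )
    for tax in taxonomies or []:
        col = tax.name.split("_")[0].lower() if tax.name.startswith("T") else tax.name
        src = df["posture"] if tax.channel == "posture" else df["intensity"]
        df[col] = src.map(tax.apply)
    return df


def write_seconds(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
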