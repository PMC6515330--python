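"""Domain types and I/O for breathing-phase annotations.

A breathing-phase annotation marks one inspiration or expiration event as a
time interval within a lung-sound recording.  Human annotators produce
non-overlapping intervals; automatic detectors emit scored ("confidence")
intervals that may overlap until post-processed.

Two on-disk formats are supported: Praat TextGrid interval tiers (the tool
annotators of respiratory sound commonly use) and a flat CSV table.
Intervals use the closed-open convention [start, end) in seconds, so abutting
phases are measure-disjoint.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "INSPIRATION",
    "EXPIRATION",
    "PHASES",
    "DEFAULT_LABEL_MAP",
    "PhaseInterval",
    "AnnotationSet",
    "read_textgrid",
    "write_textgrid",
    "read_csv_annotations",
    "write_csv_annotations",
]

INSPIRATION = "inspiration"
EXPIRATION = "expiration"
PHASES = (INSPIRATION, EXPIRATION)

#: Case-insensitive mapping from tier/CSV labels to the two phase classes.
DEFAULT_LABEL_MAP = {
    "inspiration": INSPIRATION,
    "i": INSPIRATION,
    "insp": INSPIRATION,
    "expiration": EXPIRATION,
    "e": EXPIRATION,
    "exp": EXPIRATION,
}

CSV_HEADER = [
    "recording_id",
    "source_id",
    "start_s",
    "end_s",
    "phase",
    "confidence",
    "duration_s",
]


@dataclass(frozen=True)
class PhaseInterval:
    """One breathing-phase event: [start, end) seconds, phase class,
    and an optional detector confidence in [0, 1]."""

    start: float
    end: float
    phase: str
    confidence: float | None = None

    def __lt__(self, other: "PhaseInterval") -> bool:
        return (self.start, self.end) < (other.start, other.end)

    def __post_init__(self) -> None:
        if not (0.0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}; expected one of {PHASES}")
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")

    @property
    def length(self) -> float:
        return self.end - self.start

    def overlaps(self, other: "PhaseInterval") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class AnnotationSet:
    """All phase intervals for one recording from one source.

    ``source_id`` names the annotator or detector.  Human-style sets (no
    confidences) must be pairwise non-overlapping; detector output may
    overlap until post-processed.
    """

    recording_id: str
    duration: float
    source_id: str
    intervals: tuple[PhaseInterval, ...] = ()

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        ivs = tuple(sorted(self.intervals))
        object.__setattr__(self, "intervals", ivs)
        for iv in ivs:
            if iv.end > self.duration + 1e-9:
                raise ValueError(
                    f"interval [{iv.start}, {iv.end}) exceeds duration {self.duration}"
                )
        if all(iv.confidence is None for iv in ivs):
            for a, b in zip(ivs, ivs[1:]):
                if a.overlaps(b):
                    raise ValueError(
                        "human-sourced annotation sets may not overlap: "
                        f"[{a.start}, {a.end}) vs [{b.start}, {b.end})"
                    )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def of_phase(self, phase: str) -> tuple[PhaseInterval, ...]:
        return tuple(iv for iv in self.intervals if iv.phase == phase)

    def with_intervals(self, intervals: Iterable[PhaseInterval]) -> "AnnotationSet":
        return replace(self, intervals=tuple(intervals))


# ---------------------------------------------------------------------------
# Praat TextGrid

_NUM_RE = re.compile(r"-?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?")
_STR_RE = re.compile(r'"((?:[^"]|"")*)"')


_INDEX_RE = re.compile(r"\b(?:item|intervals|points)\s*\[\d*\]\s*:")


def _tokenize_textgrid(text: str):
    """Yield numbers and quoted strings in file order.

    Both the long (``xmin = 0``) and short (bare values) dialects reduce to
    the same token stream, which is how Praat itself reads them.  Bracketed
    item indices in the long dialect (``item [1]:``) are decoration, not
    data, and are stripped first.
    """
    text = _INDEX_RE.sub("", text)
    pos = 0
    while pos < len(text):
        ch = text[pos]
        if ch == '"':
            m = _STR_RE.match(text, pos)
            if m is None:
                raise ValueError(f"unterminated string at offset {pos}")
            yield m.group(1).replace('""', '"')
            pos = m.end()
        elif ch.isdigit() or (ch == "-" and pos + 1 < len(text) and text[pos + 1].isdigit()):
            m = _NUM_RE.match(text, pos)
            yield float(m.group(0))
            pos = m.end()
        else:
            pos += 1


def read_textgrid(
    path: str | Path,
    tier_name: str,
    duration_override: float | None = None,
    *,
    recording_id: str | None = None,
    source_id: str = "",
    label_map: dict[str, str] | None = None,
) -> AnnotationSet:
    """Read one interval tier of a Praat TextGrid as an :class:`AnnotationSet`.

    Non-empty interval labels are mapped to phase classes through
    ``label_map`` (case-insensitive; default :data:`DEFAULT_LABEL_MAP`);
    empty labels are background and dropped; any other label is an error.
    Recording duration is the tier's ``xmax`` unless ``duration_override``
    is given.
    """
    path = Path(path)
    label_map = {k.lower(): v for k, v in (label_map or DEFAULT_LABEL_MAP).items()}
    tokens = list(_tokenize_textgrid(path.read_text(encoding="utf-8")))
    # layout after the "ooTextFile"/"TextGrid" header strings:
    # xmin xmax n_tiers, then per tier: class name xmin xmax n, then items
    i = 0
    while i < len(tokens) and isinstance(tokens[i], str):
        i += 1
    if len(tokens) < i + 3:
        raise ValueError(f"{path}: not a TextGrid")
    i += 2  # skip global xmin/xmax
    n_tiers = int(tokens[i])
    i += 1
    for _ in range(n_tiers):
        tier_class = tokens[i]
        name = tokens[i + 1]
        if not isinstance(tier_class, str) or not isinstance(name, str):
            raise ValueError(f"{path}: malformed tier header")
        t_xmin, t_xmax = float(tokens[i + 2]), float(tokens[i + 3])
        n_items = int(tokens[i + 4])
        i += 5
        is_interval = tier_class == "IntervalTier"
        per_item = 3 if is_interval else 2
        if name != tier_name:
            i += n_items * per_item
            continue
        if not is_interval:
            raise ValueError(f"{path}: tier {tier_name!r} is not an interval tier")
        intervals: list[PhaseInterval] = []
        bad: list[str] = []
        for _ in range(n_items):
            xmin, xmax, label = tokens[i], tokens[i + 1], tokens[i + 2]
            i += 3
            label = str(label).strip()
            if not label:
                continue
            phase = label_map.get(label.lower())
            if phase is None:
                bad.append(label)
                continue
            intervals.append(PhaseInterval(float(xmin), float(xmax), phase))
        if bad:
            raise ValueError(
                f"{path}: tier {tier_name!r} has labels outside the phase mapping: "
                + ", ".join(sorted(set(bad)))
            )
        duration = duration_override if duration_override is not None else t_xmax
        return AnnotationSet(
            recording_id=recording_id or path.stem,
            duration=duration,
            source_id=source_id or tier_name,
            intervals=tuple(intervals),
        )
    raise ValueError(f"{path}: no tier named {tier_name!r}")


def write_textgrid(
    ann: AnnotationSet,
    path: str | Path,
    *,
    tier_name: str = "phase",
) -> None:
    """Write ``ann`` as a long-dialect TextGrid with one interval tier.

    Gaps between phases are emitted as empty-label intervals so the tier
    covers [0, duration] contiguously, as Praat requires.  Overlapping
    intervals cannot be represented; post-process first.
    """
    for a, b in zip(ann.intervals, ann.intervals[1:]):
        if a.overlaps(b):
            raise ValueError(
                "cannot write overlapping intervals to a TextGrid tier: "
                f"[{a.start}, {a.end}) vs [{b.start}, {b.end})"
            )
    pieces: list[tuple[float, float, str]] = []
    cursor = 0.0
    for iv in ann.intervals:
        if iv.start > cursor:
            pieces.append((cursor, iv.start, ""))
        pieces.append((iv.start, iv.end, iv.phase))
        cursor = iv.end
    if cursor < ann.duration:
        pieces.append((cursor, ann.duration, ""))
    if not pieces:
        pieces.append((0.0, ann.duration, ""))

    lines = [
        'File type = "ooTextFile"',
        'Object class = "TextGrid"',
        "",
        "xmin = 0",
        f"xmax = {ann.duration!r}",
        "tiers? <exists>",
        "size = 1",
        "item []:",
        "    item [1]:",
        '        class = "IntervalTier"',
        f'        name = "{tier_name}"',
        "        xmin = 0",
        f"        xmax = {ann.duration!r}",
        f"        intervals: size = {len(pieces)}",
    ]
    for k, (x0, x1, label) in enumerate(pieces, start=1):
        lines += [
            f"        intervals [{k}]:",
            f"            xmin = {x0!r}",
            f"            xmax = {x1!r}",
            f'            text = "{label}"',
        ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# CSV

def read_csv_annotations(path: str | Path) -> list[AnnotationSet]:
    """Read a CSV annotation table into one AnnotationSet per
    (recording_id, source_id) pair, in first-appearance order."""
    path = Path(path)
    groups: dict[tuple[str, str], dict] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [c.strip() for c in reader.fieldnames] != CSV_HEADER:
            raise ValueError(
                f"{path}: expected header {','.join(CSV_HEADER)}, "
                f"got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                phase = row["phase"].strip().lower()
                if phase not in PHASES:
                    raise ValueError(f"unknown phase label {row['phase']!r}")
                conf_field = (row["confidence"] or "").strip()
                iv = PhaseInterval(
                    start=float(row["start_s"]),
                    end=float(row["end_s"]),
                    phase=phase,
                    confidence=float(conf_field) if conf_field else None,
                )
                duration = float(row["duration_s"])
                if iv.end > duration + 1e-9:
                    raise ValueError(
                        f"end_s {iv.end} exceeds duration_s {duration}"
                    )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}: row {lineno}: {exc}") from exc
            key = (row["recording_id"], row["source_id"])
            grp = groups.setdefault(key, {"duration": duration, "intervals": []})
            grp["intervals"].append(iv)
    return [
        AnnotationSet(
            recording_id=rec,
            duration=grp["duration"],
            source_id=src,
            intervals=tuple(grp["intervals"]),
        )
        for (rec, src), grp in groups.items()
    ]


def write_csv_annotations(sets: Sequence[AnnotationSet], path: str | Path) -> None:
    """Inverse of :func:`read_csv_annotations`; rows sorted by
    (recording_id, source_id, start).  Absent confidence → empty field."""
    rows = []
    for ann in sets:
        for iv in ann.intervals:
            rows.append(
                (
                    ann.recording_id,
                    ann.source_id,
                    repr(iv.start),
                    repr(iv.end),
                    iv.phase,
                    "" if iv.confidence is None else repr(iv.confidence),
                    repr(ann.duration),
                )
            )
    rows.sort(key=lambda r: (r[0], r[1], float(r[2])))
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        writer.writerows(rows)
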