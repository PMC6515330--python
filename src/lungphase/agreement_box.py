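"""Discrete per-box agreement between two annotation sources.

Each breathing phase is a "box" (a time interval with a class).  Two
sources agree on a phase when they drew same-class boxes with Jaccard
index (intersection over union of durations) above 0.5.  Matching is
one-to-one within each class: candidate pairs above the threshold are
accepted greedily in descending Jaccard, each box used at most once.
Percentage agreement is matched pairs over a box-count denominator,
by default the mean count of the two sources (symmetric, and equal to
the intuitive matched fraction when the counts coincide).
"""

from __future__ import annotations

from dataclasses import dataclass

from .annotations import EXPIRATION, INSPIRATION, AnnotationSet, PhaseInterval

__all__ = [
    "ClassCounts",
    "BoxAgreementResult",
    "jaccard",
    "match_boxes",
    "percent_agreement",
    "corpus_percent_agreement",
]

_DENOMINATORS = ("mean", "reference", "max")


@dataclass(frozen=True)
class ClassCounts:
    matched_pairs: int
    boxes_a: int
    boxes_b: int
    percent_agreement: float

    def __post_init__(self) -> None:
        if self.matched_pairs > min(self.boxes_a, self.boxes_b):
            raise ValueError("more matches than boxes on one side")


@dataclass(frozen=True)
class BoxAgreementResult:
    inspiration: ClassCounts
    expiration: ClassCounts
    pooled: ClassCounts

    def as_dict(self) -> dict:
        return {
            scope: vars(cc)
            for scope, cc in (
                ("inspiration", self.inspiration),
                ("expiration", self.expiration),
                ("both", self.pooled),
            )
        }


def jaccard(a: PhaseInterval, b: PhaseInterval) -> float:
    """Intersection length over union length of the two time spans
    (class-blind); 0 when disjoint, 1 iff identical."""
    inter = min(a.end, b.end) - max(a.start, b.start)
    if inter <= 0:
        return 0.0
    union = max(a.end, b.end) - min(a.start, b.start)
    return inter / union


def match_boxes(
    a: AnnotationSet, b: AnnotationSet, threshold: float = 0.5
) -> list[tuple[PhaseInterval, PhaseInterval]]:
    """One-to-one greedy matching of same-class boxes with Jaccard >
    threshold, in descending Jaccard order; ties broken by earlier start
    in a, then in b."""
    if a.recording_id != b.recording_id:
        raise ValueError(
            f"recording mismatch: {a.recording_id!r} vs {b.recording_id!r}"
        )
    candidates = []
    for i, ia in enumerate(a.intervals):
        for j, ib in enumerate(b.intervals):
            if ia.phase != ib.phase:
                continue
            jc = jaccard(ia, ib)
            if jc > threshold:
                candidates.append((jc, ia.start, ib.start, i, j))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches = []
    for _, _, _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matches.append((a.intervals[i], b.intervals[j]))
    return matches


def _percent(matched: int, na: int, nb: int, denominator: str) -> float:
    if denominator not in _DENOMINATORS:
        raise ValueError(f"denominator must be one of {_DENOMINATORS}")
    if na == 0 and nb == 0:
        return 100.0  # vacuous agreement
    denom = {
        "mean": (na + nb) / 2,
        "reference": na,
        "max": max(na, nb),
    }[denominator]
    return 100.0 * matched / denom if denom else 0.0


def percent_agreement(
    a: AnnotationSet,
    b: AnnotationSet,
    threshold: float = 0.5,
    denominator: str = "mean",
) -> BoxAgreementResult:
    """Per-class and pooled percentage agreement for one recording.

    ``denominator`` selects the normalizer: "mean" (default, symmetric),
    "reference" (a's count), or "max".
    """
    matches = match_boxes(a, b, threshold)
    counts = {}
    for scope, phases in (
        ("inspiration", (INSPIRATION,)),
        ("expiration", (EXPIRATION,)),
        ("pooled", (INSPIRATION, EXPIRATION)),
    ):
        m = sum(1 for ia, _ in matches if ia.phase in phases)
        na = sum(1 for iv in a.intervals if iv.phase in phases)
        nb = sum(1 for iv in b.intervals if iv.phase in phases)
        counts[scope] = ClassCounts(m, na, nb, _percent(m, na, nb, denominator))
    return BoxAgreementResult(**counts)


def corpus_percent_agreement(
    pairs: list[tuple[AnnotationSet, AnnotationSet]],
    threshold: float = 0.5,
    denominator: str = "mean",
    per_file_average: bool = False,
) -> dict:
    """Aggregate box agreement over a corpus of paired recordings.

    By default box counts are pooled over all files before taking the
    percentage; ``per_file_average=True`` instead averages the per-file
    percentages (unweighted).
    """
    per_file = [
        percent_agreement(a, b, threshold, denominator) for a, b in pairs
    ]
    out: dict = {}
    for scope in ("inspiration", "expiration", "both"):
        key = "pooled" if scope == "both" else scope
        counts = [getattr(r, key) for r in per_file]
        matched = sum(c.matched_pairs for c in counts)
        na = sum(c.boxes_a for c in counts)
        nb = sum(c.boxes_b for c in counts)
        if per_file_average:
            pct = (
                sum(c.percent_agreement for c in counts) / len(counts)
                if counts
                else 100.0
            )
        else:
            pct = _percent(matched, na, nb, denominator)
        out[scope] = {
            "matched_pairs": matched,
            "boxes_a": na,
            "boxes_b": nb,
            "percent_agreement": pct,
        }
    return out
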