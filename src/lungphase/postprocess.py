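"""Post-processing of scored breathing-phase detections.

A detector emits many overlapping scored boxes.  Three cleanup steps turn
them into a non-overlapping human-style annotation:

1. prune boxes below the confidence threshold (strictly below: a box at
   exactly the threshold survives);
2. suppress duplicates — among same-class boxes overlapping by more than
   the Jaccard threshold, keep the highest-confidence one (a continuous
   analogue of non-maximum suppression);
3. resolve the small residual overlaps between successive phases by
   shrinking both members of each overlapping pair by half the overlap,
   so they abut.

The duplicate criterion defaults to the Jaccard index; ``overlap="min"``
instead measures overlap as a fraction of the smaller box.
"""

from __future__ import annotations

from dataclasses import dataclass

from .annotations import AnnotationSet, PhaseInterval
from .agreement_box import jaccard

__all__ = [
    "PostprocessConfig",
    "PostprocessReport",
    "prune_low_confidence",
    "remove_duplicates",
    "shrink_overlaps",
    "postprocess",
]


@dataclass(frozen=True)
class PostprocessConfig:
    confidence_threshold: float = 0.50
    duplicate_jaccard_threshold: float = 0.50
    overlap: str = "jaccard"  # or "min": fraction of the smaller box

    def __post_init__(self) -> None:
        for name in ("confidence_threshold", "duplicate_jaccard_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.overlap not in ("jaccard", "min"):
            raise ValueError("overlap must be 'jaccard' or 'min'")


@dataclass(frozen=True)
class PostprocessReport:
    result: AnnotationSet
    n_input: int
    n_pruned: int
    n_suppressed: int

    @property
    def n_output(self) -> int:
        return len(self.result)


def _require_confidences(boxes: AnnotationSet) -> None:
    for iv in boxes.intervals:
        if iv.confidence is None:
            raise ValueError(
                f"interval [{iv.start}, {iv.end}) has no confidence; "
                "post-processing applies to detector output only"
            )


def _overlap_score(a: PhaseInterval, b: PhaseInterval, mode: str) -> float:
    if mode == "jaccard":
        return jaccard(a, b)
    inter = min(a.end, b.end) - max(a.start, b.start)
    return max(inter, 0.0) / min(a.length, b.length)


def prune_low_confidence(
    boxes: AnnotationSet, cfg: PostprocessConfig | None = None
) -> AnnotationSet:
    """Drop boxes strictly below the confidence threshold."""
    cfg = cfg or PostprocessConfig()
    _require_confidences(boxes)
    return boxes.with_intervals(
        iv for iv in boxes.intervals if iv.confidence >= cfg.confidence_threshold
    )


def remove_duplicates(
    boxes: AnnotationSet, cfg: PostprocessConfig | None = None
) -> AnnotationSet:
    """Greedy same-class duplicate suppression in descending confidence.

    Each surviving box suppresses every later (lower-confidence) same-class
    box whose overlap with it exceeds the threshold; ties in confidence
    are broken by earlier start, then earlier end, for determinism.
    """
    cfg = cfg or PostprocessConfig()
    _require_confidences(boxes)
    order = sorted(
        boxes.intervals, key=lambda iv: (-iv.confidence, iv.start, iv.end)
    )
    kept: list[PhaseInterval] = []
    for cand in order:
        if any(
            k.phase == cand.phase
            and _overlap_score(k, cand, cfg.overlap) > cfg.duplicate_jaccard_threshold
            for k in kept
        ):
            continue
        kept.append(cand)
    return boxes.with_intervals(kept)


def shrink_overlaps(boxes: AnnotationSet) -> AnnotationSet:
    """Resolve residual overlaps between successive boxes by equal shrink.

    A single left-to-right sweep: for each successive pair overlapping by
    d > 0, the left box ends d/2 earlier and the right box starts d/2
    later, so they abut.  A shrink that would invert a box is an error.
    """
    ivs = sorted(boxes.intervals, key=lambda iv: (iv.start, iv.end))
    out: list[PhaseInterval] = []
    for iv in ivs:
        if out and out[-1].end > iv.start:
            prev = out[-1]
            d = prev.end - iv.start
            half = d / 2.0
            if half >= prev.length or half >= iv.length:
                raise ValueError(
                    f"overlap {d:g} s between [{prev.start}, {prev.end}) and "
                    f"[{iv.start}, {iv.end}) too large to shrink away"
                )
            out[-1] = PhaseInterval(
                prev.start, prev.end - half, prev.phase, prev.confidence
            )
            iv = PhaseInterval(iv.start + half, iv.end, iv.phase, iv.confidence)
        out.append(iv)
    return boxes.with_intervals(out)


def postprocess(
    boxes: AnnotationSet, cfg: PostprocessConfig | None = None
) -> PostprocessReport:
    """Full chain: prune → suppress duplicates → shrink overlaps.

    Returns the cleaned (non-overlapping) set together with per-stage
    removal counts; shrinking never removes a box, so
    n_input = n_output + n_pruned + n_suppressed.
    """
    cfg = cfg or PostprocessConfig()
    pruned = prune_low_confidence(boxes, cfg)
    deduped = remove_duplicates(pruned, cfg)
    final = shrink_overlaps(deduped)
    return PostprocessReport(
        result=final,
        n_input=len(boxes),
        n_pruned=len(boxes) - len(pruned),
        n_suppressed=len(pruned) - len(deduped),
    )
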