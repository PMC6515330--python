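import numpy as np
import pytest

from lungphase import AnnotationSet, PhaseInterval
from lungphase.annotations import EXPIRATION, INSPIRATION


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def random_annotation_set(
    rng,
    recording_id="rec",
    source_id="src",
    duration=15.0,
    max_intervals=8,
    with_confidence=False,
):
    """Random human-style (non-overlapping) annotation set."""
    n = int(rng.integers(0, max_intervals + 1))
    cuts = np.sort(rng.uniform(0.0, duration, size=2 * n))
    intervals = []
    for k in range(n):
        s, e = cuts[2 * k], cuts[2 * k + 1]
        if e - s < 1e-3:
            continue
        intervals.append(
            PhaseInterval(
                float(s),
                float(e),
                INSPIRATION if rng.random() < 0.5 else EXPIRATION,
                float(rng.uniform(0, 1)) if with_confidence else None,
            )
        )
    return AnnotationSet(recording_id, duration, source_id, tuple(intervals))


def random_scored_boxes(rng, duration=15.0, n_max=12, recording_id="rec"):
    """Random scored boxes with arbitrary overlaps (duplicate-suppression
    stress test; not necessarily shrinkable)."""
    n = int(rng.integers(0, n_max + 1))
    intervals = []
    for _ in range(n):
        s = float(rng.uniform(0.0, duration - 0.5))
        e = float(min(s + rng.uniform(0.3, 4.0), duration))
        intervals.append(
            PhaseInterval(
                s,
                e,
                INSPIRATION if rng.random() < 0.5 else EXPIRATION,
                float(rng.uniform(0, 1)),
            )
        )
    return AnnotationSet(recording_id, duration, "detector", tuple(intervals))


def detector_like_boxes(rng, duration=15.0, recording_id="rec"):
    """Scored boxes shaped like real detector output: alternating phases
    with small boundary errors (possible small neighbor overlaps) plus
    occasional near-duplicate proposals of the same phase."""
    intervals = []
    t = float(rng.uniform(0.0, 0.5))
    phase = INSPIRATION
    while t < duration - 1.0:
        length = float(rng.uniform(1.0, 2.5))
        end = min(t + length, duration)
        jitter = 0.08 * length
        s = max(t - rng.uniform(0, jitter), 0.0)
        e = min(end + rng.uniform(0, jitter), duration)
        conf = float(rng.uniform(0.2, 1.0))
        intervals.append(PhaseInterval(s, e, phase, conf))
        if rng.random() < 0.3:  # near-duplicate proposal
            ds = max(s + rng.uniform(-0.1, 0.1), 0.0)
            de = min(e + rng.uniform(-0.1, 0.1), duration)
            if de - ds > 0.1:
                intervals.append(
                    PhaseInterval(ds, de, phase, float(rng.uniform(0.2, 1.0)))
                )
        t = end + float(rng.uniform(0.05, 0.5))
        phase = EXPIRATION if phase == INSPIRATION else INSPIRATION
    return AnnotationSet(recording_id, duration, "detector", tuple(intervals))
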