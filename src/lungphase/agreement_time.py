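"""Continuous-time agreement between two annotation sources.

Instead of counting matched boxes, this evaluation treats an annotation
source as the region of time it marks as a breathing phase.  With A the
region marked by the reference source (here: the human annotator) and B
the region marked by the comparison source, the confusion *durations* are

    TP = |A ∩ B|      FP = |A − B|      TN = |¬A ∩ ¬B|      FN = |¬A − ¬B|

where ¬ is the complement within the recording and |·| is duration in
seconds.  Note the orientation: FP is reference-time not covered by the
comparison and FN is comparison-time not covered by the reference, the
mirror image of the usual screening-test convention.  It is kept because
the downstream statistics were defined on it; ``orientation="conventional"``
swaps the roles of A and B for readers who expect the usual layout.

From the pooled durations we compute sensitivity TP/(TP+FN), specificity
TN/(TN+FP), and a continuous-time analogue of Cohen's kappa
("pseudo-kappa"): observed agreement po = (TP+TN)/total, chance agreement
pe estimated by re-pairing annotations across recordings at random (a
derangement, so no annotation meets its own recording), and
kappa = (po − pe)/(1 − pe), with bootstrap percentile confidence
intervals over recordings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .annotations import EXPIRATION, INSPIRATION, AnnotationSet
from .intervals import IntervalSet

__all__ = [
    "SCOPES",
    "TimeConfusion",
    "PseudoKappaResult",
    "phase_region",
    "time_confusion",
    "confusion_for_pair",
    "sensitivity",
    "specificity",
    "corpus_summary",
    "pseudo_kappa",
    "interpret_kappa",
]

SCOPES = ("inspiration", "expiration", "both")


@dataclass(frozen=True)
class TimeConfusion:
    """Confusion durations (seconds) for one recording and one comparison."""

    tp: float
    fp: float
    tn: float
    fn: float
    total: float

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < -1e-12:
                raise ValueError(f"{name} negative")
        if abs(self.tp + self.fp + self.tn + self.fn - self.total) > 1e-9:
            raise ValueError("confusion durations do not sum to total")

    def __add__(self, other: "TimeConfusion") -> "TimeConfusion":
        return TimeConfusion(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
            self.total + other.total,
        )

    @property
    def agreement(self) -> float:
        """Fraction of time the two sources agree."""
        return (self.tp + self.tn) / self.total


@dataclass(frozen=True)
class PseudoKappaResult:
    po: float
    pe: float
    kappa: float
    ci_low: float
    ci_high: float
    interpretation: str
    n_shuffles: int
    n_bootstrap: int
    seed: int


def phase_region(ann: AnnotationSet, scope: str = "both") -> IntervalSet:
    """Union of the intervals in the selected scope, merged into disjoint
    spans.  ``scope`` is "inspiration", "expiration", or "both"."""
    if scope not in SCOPES:
        raise ValueError(f"scope must be one of {SCOPES}, got {scope!r}")
    if scope == "both":
        ivs = ann.intervals
    else:
        ivs = ann.of_phase(INSPIRATION if scope == "inspiration" else EXPIRATION)
    return IntervalSet((iv.start, iv.end) for iv in ivs)


def time_confusion(
    a_region: IntervalSet, b_region: IntervalSet, total: float
) -> TimeConfusion:
    """Exact confusion durations between region A (reference) and region B
    (comparison) within [0, total)."""
    for name, region in (("A", a_region), ("B", b_region)):
        if region and (region.spans[0, 0] < -1e-12 or region.spans[-1, 1] > total + 1e-9):
            raise ValueError(f"region {name} exceeds [0, {total}]")
    tp = a_region.intersection(b_region).measure
    fp = a_region.measure - tp  # |A - B|
    fn = b_region.measure - tp  # |¬A - ¬B| = |B - A|
    tn = total - tp - fp - fn
    return TimeConfusion(tp, fp, max(tn, 0.0), fn, total)


def confusion_for_pair(
    a: AnnotationSet, b: AnnotationSet, scope: str = "both",
    orientation: str = "paper",
) -> TimeConfusion:
    """Confusion durations for a paired (reference a, comparison b) file.

    ``orientation="conventional"`` swaps the roles of a and b so that FP
    means comparison-time outside the reference.
    """
    if orientation not in ("paper", "conventional"):
        raise ValueError("orientation must be 'paper' or 'conventional'")
    total = min(a.duration, b.duration)
    ra = phase_region(a, scope).clip(total)
    rb = phase_region(b, scope).clip(total)
    if orientation == "conventional":
        ra, rb = rb, ra
    return time_confusion(ra, rb, total)


def sensitivity(tc: TimeConfusion) -> float:
    """TP/(TP+FN); NaN when the denominator is zero (undefined)."""
    denom = tc.tp + tc.fn
    return tc.tp / denom if denom > 0 else math.nan


def specificity(tc: TimeConfusion) -> float:
    """TN/(TN+FP); NaN when the denominator is zero (undefined)."""
    denom = tc.tn + tc.fp
    return tc.tn / denom if denom > 0 else math.nan


def _check_pairs(pairs) -> None:
    for a, b in pairs:
        if a.recording_id != b.recording_id:
            raise ValueError(
                f"unpaired recordings: {a.recording_id!r} vs {b.recording_id!r}"
            )


def corpus_summary(
    pairs: list[tuple[AnnotationSet, AnnotationSet]],
    scope: str = "both",
    orientation: str = "paper",
) -> dict:
    """Per-file sensitivity/specificity and their unweighted means.

    Files with an undefined ratio (zero denominator) are excluded from the
    corresponding mean, mirroring how degenerate recordings are dropped
    from averages.
    """
    _check_pairs(pairs)
    sens, spec = [], []
    for a, b in pairs:
        tc = confusion_for_pair(a, b, scope, orientation)
        sens.append(sensitivity(tc))
        spec.append(specificity(tc))
    def _mean(xs):
        xs = [x for x in xs if not math.isnan(x)]
        return float(np.mean(xs)) if xs else math.nan
    return {
        "scope": scope,
        "per_file_sensitivity": sens,
        "per_file_specificity": spec,
        "mean_sensitivity": _mean(sens),
        "mean_specificity": _mean(spec),
        "n_files": len(pairs),
    }


def interpret_kappa(kappa: float) -> str:
    """Map a kappa value to the conventional verbal agreement scale.

    Bins are half-open on the left, so 0.80 is still "substantial".
    """
    if math.isnan(kappa):
        return "undefined"
    if kappa <= 0:
        return "no agreement"
    for hi, label in (
        (0.20, "slight agreement"),
        (0.40, "fair agreement"),
        (0.60, "moderate agreement"),
        (0.80, "substantial agreement"),
    ):
        if kappa <= hi:
            return label
    return "almost perfect agreement"


def _agreement_matrix(pairs, scope):
    """D[i, j] = seconds of agreement when file i's reference annotation is
    paired with file j's comparison annotation (both clipped to the shorter
    duration); T[i, j] = that shorter duration.

    Precomputing the full matrix makes every shuffle and bootstrap
    replicate an O(n) table lookup.
    """
    n = len(pairs)
    ra = [phase_region(a, scope) for a, _ in pairs]
    rb = [phase_region(b, scope) for _, b in pairs]
    dur = [(a.duration, b.duration) for a, b in pairs]
    D = np.empty((n, n))
    T = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            total = min(dur[i][0], dur[j][1])
            tc = time_confusion(ra[i].clip(total), rb[j].clip(total), total)
            D[i, j] = tc.tp + tc.tn
            T[i, j] = total
    return D, T


def _random_derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random permutation of range(n) with no fixed point."""
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def _kappa_from_matrix(idx, D, T, n_shuffles, rng):
    """kappa over the sub-corpus given by index array ``idx``."""
    idx = np.asarray(idx)
    po = D[idx, idx].sum() / T[idx, idx].sum()
    pe_vals = np.empty(n_shuffles)
    for s in range(n_shuffles):
        perm = _random_derangement(len(idx), rng)
        rows, cols = idx, idx[perm]
        pe_vals[s] = D[rows, cols].sum() / T[rows, cols].sum()
    pe = float(pe_vals.mean())
    kappa = (po - pe) / (1.0 - pe) if pe < 1.0 else math.nan
    return float(po), pe, kappa


def pseudo_kappa(
    pairs: list[tuple[AnnotationSet, AnnotationSet]],
    scope: str = "both",
    n_shuffles: int = 100,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> PseudoKappaResult:
    """Continuous-time pseudo-kappa with bootstrap percentile CI.

    po is the duration-weighted agreement (TP+TN)/total pooled over the
    corpus.  pe is the mean pooled agreement over ``n_shuffles`` random
    derangements of the file pairing, which breaks the correlation between
    the two sources while preserving each one's marginal phase occupancy.
    The CI resamples recordings with replacement ``n_bootstrap`` times and
    takes the 2.5/97.5 percentiles of the recomputed kappa.
    """
    _check_pairs(pairs)
    n = len(pairs)
    if n < 2:
        raise ValueError("pseudo_kappa needs at least 2 paired recordings")
    rng = np.random.default_rng(seed)
    D, T = _agreement_matrix(pairs, scope)
    po, pe, kappa = _kappa_from_matrix(np.arange(n), D, T, n_shuffles, rng)
    boot = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        boot[b] = _kappa_from_matrix(idx, D, T, n_shuffles, rng)[2]
    boot = boot[~np.isnan(boot)]
    if boot.size:
        ci_low, ci_high = np.percentile(boot, [2.5, 97.5])
    else:
        ci_low = ci_high = math.nan
    return PseudoKappaResult(
        po=po,
        pe=pe,
        kappa=kappa,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        interpretation=interpret_kappa(kappa),
        n_shuffles=n_shuffles,
        n_bootstrap=n_bootstrap,
        seed=seed,
    )
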