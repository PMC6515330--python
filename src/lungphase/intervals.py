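"""Exact arithmetic on finite unions of closed-open real intervals.

The continuous-time agreement measures need set operations (union,
intersection, complement) and Lebesgue measure on annotation regions,
computed exactly by boundary sweeps rather than on a sampled grid.  An
interval set is represented as an (n, 2) float array of disjoint, sorted
[start, end) spans.
"""

from __future__ import annotations

import numpy as np

__all__ = ["IntervalSet"]


class IntervalSet:
    """Immutable finite union of disjoint [start, end) intervals."""

    __slots__ = ("spans",)

    def __init__(self, spans=()):
        arr = np.asarray(list(spans), dtype=np.float64).reshape(-1, 2)
        if arr.size and np.any(arr[:, 0] > arr[:, 1]):
            raise ValueError("interval with start > end")
        self.spans = self._normalize(arr)

    @staticmethod
    def _normalize(arr: np.ndarray) -> np.ndarray:
        arr = arr[arr[:, 0] < arr[:, 1]]  # drop empty spans
        if arr.shape[0] == 0:
            return arr.reshape(0, 2)
        arr = arr[np.argsort(arr[:, 0], kind="stable")]
        merged = [list(arr[0])]
        for s, e in arr[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out = np.array(merged, dtype=np.float64)
        out.flags.writeable = False
        return out

    @property
    def measure(self) -> float:
        """Total length in seconds."""
        if self.spans.shape[0] == 0:
            return 0.0
        return float(np.sum(self.spans[:, 1] - self.spans[:, 0]))

    def __bool__(self) -> bool:
        return self.spans.shape[0] > 0

    def __eq__(self, other) -> bool:
        return isinstance(other, IntervalSet) and np.array_equal(
            self.spans, other.spans
        )

    def __repr__(self) -> str:
        body = ", ".join(f"[{s:g}, {e:g})" for s, e in self.spans)
        return f"IntervalSet({{{body}}})"

    def union(self, other: "IntervalSet") -> "IntervalSet":
        out = IntervalSet.__new__(IntervalSet)
        out.spans = self._normalize(np.vstack([self.spans, other.spans]))
        return out

    def intersection(self, other: "IntervalSet") -> "IntervalSet":
        pieces = []
        i = j = 0
        a, b = self.spans, other.spans
        while i < len(a) and j < len(b):
            lo = max(a[i, 0], b[j, 0])
            hi = min(a[i, 1], b[j, 1])
            if lo < hi:
                pieces.append((lo, hi))
            if a[i, 1] <= b[j, 1]:
                i += 1
            else:
                j += 1
        return IntervalSet(pieces)

    def complement(self, total: float) -> "IntervalSet":
        """Complement within [0, total)."""
        pieces = []
        cursor = 0.0
        for s, e in self.spans:
            if s > cursor:
                pieces.append((cursor, s))
            cursor = max(cursor, e)
        if cursor < total:
            pieces.append((cursor, total))
        return IntervalSet(pieces)

    def difference(self, other: "IntervalSet") -> "IntervalSet":
        hi = 0.0
        for spans in (self.spans, other.spans):
            if spans.shape[0]:
                hi = max(hi, float(spans[-1, 1]))
        return self.intersection(other.complement(hi))

    def clip(self, total: float) -> "IntervalSet":
        """Restrict to [0, total)."""
        return self.intersection(IntervalSet([(0.0, total)]))
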