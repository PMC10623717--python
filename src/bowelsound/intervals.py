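"""Half-open sample-index interval sets.

All segment bookkeeping in the package (bowel-sound labels, detections,
movement-artifact spans) uses 0-based, half-open ``[start, end)`` intervals
measured in samples. Seconds appear only at I/O boundaries, so interval
algebra (intersection, difference, energy partitioning) is exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = ["IntervalSet"]


def _normalize(pairs: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Sort and merge touching/overlapping pairs into a canonical form."""
    items = sorted((int(a), int(b)) for a, b in pairs)
    for a, b in items:
        if a < 0 or b <= a:
            raise ValueError(f"invalid interval ({a}, {b}): need 0 <= start < end")
    merged: list[list[int]] = []
    for a, b in items:
        if merged and a <= merged[-1][1]:  # touching counts as overlap
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return tuple((a, b) for a, b in merged)


@dataclass(frozen=True)
class IntervalSet:
    """An ordered, disjoint set of half-open sample intervals."""

    intervals: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "intervals", _normalize(self.intervals))

    # -- construction ------------------------------------------------------
    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[int, int]]) -> "IntervalSet":
        return cls(tuple((int(a), int(b)) for a, b in pairs))

    @classmethod
    def from_seconds(cls, pairs: Iterable[tuple[float, float]], fs: float) -> "IntervalSet":
        """Convert second-valued pairs to samples (round-half-even)."""
        out = []
        for a, b in pairs:
            sa = int(np.round(a * fs))
            sb = int(np.round(b * fs))
            if sb <= sa:
                sb = sa + 1  # preserve a nonempty interval after rounding
            out.append((sa, sb))
        return cls.from_pairs(out)

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "IntervalSet":
        mask = np.asarray(mask, dtype=bool)
        if mask.size == 0 or not mask.any():
            return cls()
        d = np.diff(mask.astype(np.int8))
        starts = np.flatnonzero(d == 1) + 1
        ends = np.flatnonzero(d == -1) + 1
        if mask[0]:
            starts = np.r_[0, starts]
        if mask[-1]:
            ends = np.r_[ends, mask.size]
        return cls.from_pairs(zip(starts.tolist(), ends.tolist()))

    # -- basic queries -----------------------------------------------------
    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[tuple[int, int]]:
        return iter(self.intervals)

    def __bool__(self) -> bool:
        return bool(self.intervals)

    @property
    def total_samples(self) -> int:
        return sum(b - a for a, b in self.intervals)

    def durations(self) -> np.ndarray:
        return np.array([b - a for a, b in self.intervals], dtype=np.int64)

    def to_seconds(self, fs: float) -> list[tuple[float, float]]:
        return [(a / fs, b / fs) for a, b in self.intervals]

    def to_mask(self, n: int) -> np.ndarray:
        mask = np.zeros(int(n), dtype=bool)
        for a, b in self.intervals:
            if a >= n:
                break
            mask[a : min(b, n)] = True
        return mask

    # -- set algebra -------------------------------------------------------
    def union(self, other: "IntervalSet") -> "IntervalSet":
        return IntervalSet(self.intervals + other.intervals)

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        out = []
        i = j = 0
        a, b = self.intervals, other.intervals
        while i < len(a) and j < len(b):
            lo = max(a[i][0], b[j][0])
            hi = min(a[i][1], b[j][1])
            if lo < hi:
                out.append((lo, hi))
            if a[i][1] < b[j][1]:
                i += 1
            else:
                j += 1
        return IntervalSet.from_pairs(out)

    def difference(self, other: "IntervalSet") -> "IntervalSet":
        out = []
        for a, b in self.intervals:
            cur = a
            for c, d in other.intervals:
                if d <= cur or c >= b:
                    continue
                if c > cur:
                    out.append((cur, c))
                cur = max(cur, d)
                if cur >= b:
                    break
            if cur < b:
                out.append((cur, b))
        return IntervalSet.from_pairs(out)

    def complement(self, n: int) -> "IntervalSet":
        return IntervalSet.from_pairs([(0, int(n))]).difference(self)

    def overlaps(self, start: int, end: int) -> bool:
        return any(a < end and start < b for a, b in self.intervals)

    # -- segment post-processing -------------------------------------------
    def merge_within(self, gap: int, inclusive: bool = False) -> "IntervalSet":
        """Merge intervals separated by less than ``gap`` samples.

        With ``inclusive=True`` gaps of exactly ``gap`` samples also merge.
        """
        if not self.intervals:
            return self
        merged = [list(self.intervals[0])]
        for a, b in self.intervals[1:]:
            sep = a - merged[-1][1]
            if sep < gap or (inclusive and sep == gap):
                merged[-1][1] = b
            else:
                merged.append([a, b])
        return IntervalSet.from_pairs((a, b) for a, b in merged)

    def filter_min_length(self, min_len: int) -> "IntervalSet":
        return IntervalSet.from_pairs((a, b) for a, b in self.intervals if b - a >= min_len)
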