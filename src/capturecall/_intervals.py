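"""Small helpers for 1-based inclusive genomic intervals."""

from __future__ import annotations

from typing import Iterable, List, Tuple

Interval = Tuple[int, int]


def merge_intervals(intervals: Iterable[Interval]) -> List[Interval]:
    """Sort and merge overlapping or directly adjacent intervals."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    merged: List[Interval] = []
    for s, e in ivs:
        if e < s:
            raise ValueError(f"interval end {e} < start {s}")
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def complement(intervals: Iterable[Interval], start: int, end: int) -> List[Interval]:
    """Complement of an interval set within [start, end], all 1-based inclusive."""
    out: List[Interval] = []
    cursor = start
    for s, e in merge_intervals(intervals):
        if s < start or e > end:
            raise ValueError(f"interval ({s},{e}) outside bounds ({start},{end})")
        if s > cursor:
            out.append((cursor, s - 1))
        cursor = max(cursor, e + 1)
    if cursor <= end:
        out.append((cursor, end))
    return out


def total_bp(intervals: Iterable[Interval]) -> int:
    return sum(e - s + 1 for s, e in intervals)


def distance_to_nearest(pos: int, intervals: List[Interval]) -> int:
    """Distance in bp from pos to the nearest interval (0 if inside any).

    Assumes intervals sorted and disjoint. Returns a large sentinel when the
    interval list is empty.
    """
    if not intervals:
        return 2**62
    import bisect

    i = bisect.bisect_right([s for s, _ in intervals], pos)
    best = 2**62
    if i > 0:
        s, e = intervals[i - 1]
        best = 0 if pos <= e else pos - e
    if i < len(intervals):
        s, _ = intervals[i]
        best = min(best, max(0, s - pos))
    return best
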