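"""Single-copy capture target and interval/gap statistics.

Genomic coordinates are 1-based inclusive throughout; BED emitted elsewhere
is 0-based half-open. Megabases are printed to 2 decimals and percentages to
1 decimal, the precision the numbers are conventionally reported at.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple, Union

from ._intervals import complement, merge_intervals, total_bp
from .synthetic_data import ReferenceInterval, RepeatAnnotation


@dataclass
class MaskedTarget:
    """Complement of the repeat mask within the reference interval."""

    single_copy_intervals: List[Tuple[int, int]]
    total_single_copy_bp: int
    masked_bp: int

    def check_conservation(self, interval_length: int) -> None:
        assert self.total_single_copy_bp + self.masked_bp == interval_length


@dataclass
class TargetStats:
    interval_length_bp: int
    interval_length_mb: float
    n_gaps: int
    gap_bp: int
    gap_fraction_pct: float


def compute_single_copy_target(
    ref: ReferenceInterval, repeats: RepeatAnnotation
) -> MaskedTarget:
    """Subtract the repeat annotation from the interval; conservation holds:
    masked + single-copy = total."""
    for s, e in repeats.intervals:
        if s < ref.start or e > ref.end:
            raise ValueError(f"repeat interval ({s},{e}) outside the reference bounds")
    sc = complement(repeats.intervals, ref.start, ref.end)
    target = MaskedTarget(
        single_copy_intervals=sc,
        total_single_copy_bp=total_bp(sc),
        masked_bp=repeats.masked_bp,
    )
    target.check_conservation(ref.length)
    return target


def interval_length(start: int, end: int) -> Tuple[int, float]:
    """Length of a 1-based inclusive interval in bp and Mb (2 decimals)."""
    if end < start:
        raise ValueError("end < start")
    bp = end - start + 1
    return bp, round(bp / 1e6, 2)


def target_gap_stats(
    ref: Union[ReferenceInterval, int],
    assembly_gaps: Sequence[Tuple[int, int]],
) -> TargetStats:
    """Count assembly gaps and their share of the target interval.

    ``ref`` may be a ReferenceInterval or a bare interval length in bp (for
    statistics on intervals whose sequence is not materialised).
    """
    if isinstance(ref, ReferenceInterval):
        length, lo, hi = ref.length, ref.start, ref.end
    else:
        length, lo, hi = int(ref), 1, int(ref)
        if length <= 0:
            raise ValueError("interval length must be positive")
    gaps = sorted((int(s), int(e)) for s, e in assembly_gaps)
    prev_end = None
    for s, e in gaps:
        if e < s or s < lo or e > hi:
            raise ValueError(f"gap ({s},{e}) invalid or outside bounds")
        if prev_end is not None and s <= prev_end:
            raise ValueError("gaps overlap")
        prev_end = e
    gap_bp = total_bp(gaps)
    return TargetStats(
        interval_length_bp=length,
        interval_length_mb=round(length / 1e6, 2),
        n_gaps=len(gaps),
        gap_bp=gap_bp,
        gap_fraction_pct=round(100.0 * gap_bp / length, 1),
    )
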