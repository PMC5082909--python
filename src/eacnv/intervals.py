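"""Genomic interval arithmetic under 1-based, fully-closed coordinates.

Every overlap rule in the pipeline (reference-set filtering, reciprocal
overlap, transcript intersection) reduces to the three primitives here.
Coordinates are 1-based inclusive throughout the package; conversion from
0-based half-open BED happens at the file boundary in :mod:`eacnv.io_formats`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "normalize_chrom",
    "overlap_bp",
    "coverage_fraction",
    "reciprocal_overlap",
    "size_kb",
    "round_half_away",
]


def normalize_chrom(label: str) -> str:
    """Normalize a chromosome label to un-prefixed form ('chr8' -> '8')."""
    label = str(label).strip()
    if label.lower().startswith("chr"):
        label = label[3:]
    return label


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A chromosome span, 1-based and inclusive at both ends.

    Parameters
    ----------
    chrom : str
        Chromosome label without a ``chr`` prefix (``"1"``..``"22"``,
        ``"X"``, ``"Y"``).
    start, end : int
        First and last base of the span. ``start >= 1`` and
        ``end >= start``; a single base has ``start == end`` and size 1.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"interval start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"interval end ({self.end}) precedes start ({self.start})"
            )

    @property
    def size_bp(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start:,}-{self.end:,}"


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals.

    Returns 0 for different chromosomes or disjoint spans. Adjacent
    intervals (``a.end + 1 == b.start``) share no base. Symmetric.
    """
    if normalize_chrom(a.chrom) != normalize_chrom(b.chrom):
        return 0
    lo = max(a.start, b.start)
    hi = min(a.end, b.end)
    return max(0, hi - lo + 1)


def _merged_spans(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of (start, end) closed spans as a sorted, disjoint list."""
    spans = sorted(intervals)
    merged: list[tuple[int, int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1] + 1:
            prev_s, prev_e = merged[-1]
            merged[-1] = (prev_s, max(prev_e, e))
        else:
            merged.append((s, e))
    return merged


def coverage_fraction(
    query: GenomicInterval, features: Sequence[GenomicInterval]
) -> float:
    """Fraction of *query* bases covered by the union of *features*.

    Overlapping features are not double-counted; features on other
    chromosomes contribute nothing. Result is in [0, 1].
    """
    if query is None:
        raise ValueError("query interval is required")
    qc = normalize_chrom(query.chrom)
    clipped = []
    for f in features:
        if normalize_chrom(f.chrom) != qc:
            continue
        lo = max(query.start, f.start)
        hi = min(query.end, f.end)
        if hi >= lo:
            clipped.append((lo, hi))
    if not clipped:
        return 0.0
    covered = sum(e - s + 1 for s, e in _merged_spans(clipped))
    return covered / query.size_bp


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """min(fraction of a covered by b, fraction of b covered by a).

    Two intervals reciprocally overlap at fraction f when each covers at
    least f of the other — the standard CNV-matching criterion.
    """
    shared = overlap_bp(a, b)
    if shared == 0:
        return 0.0
    return min(shared / a.size_bp, shared / b.size_bp)


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (2.5 -> 3, -2.5 -> -3).

    Python's built-in ``round`` uses banker's rounding; printed table
    values in this domain follow the conventional half-away rule.
    """
    factor = 10.0**ndigits
    scaled = x * factor
    rounded = math.floor(scaled + 0.5) if scaled >= 0 else math.ceil(scaled - 0.5)
    return rounded / factor


def size_kb(interval: GenomicInterval) -> int:
    """Interval size in Kb, rounded half away from zero to an integer."""
    return int(round_half_away(interval.size_bp / 1000.0))
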