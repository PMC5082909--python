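"""Harmonize raw two-caller CNV output: thresholds, merging, concordance, ROH.

The dual-caller design mirrors standard SNP-array practice: CNVs are
called independently by two algorithms with different error profiles,
calls below each caller's confidence floor are discarded (35 for the
partition-style caller, 10 for the penn-style caller, minimum three
consecutive probes for either), fragmented calls from one caller are
re-merged, and the union of calls is carried forward with a
concordance label recording whether the other caller saw the same
event.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from .intervals import GenomicInterval, reciprocal_overlap
from .models import CnvCall, ProbeRecord, RohSegment

__all__ = [
    "CallerThresholds",
    "apply_caller_thresholds",
    "merge_adjacent_calls",
    "label_concordance",
    "detect_roh",
]

#: Caller confidence floors (caller-specific score scales).
DEFAULT_CONFIDENCE = {"partitionstyle": 35.0, "pennstyle": 10.0}
MIN_PROBES = 3

#: Default merge gap fraction of the published merge utility.
DEFAULT_GAP_FRACTION = 0.2

#: Reciprocal-overlap fraction for cross-caller concordance.
CONCORDANCE_RECIPROCAL = 0.5

#: ROH minima: span and homozygous probe count.
ROH_MIN_BP = 1_000_000
ROH_MIN_PROBES = 50


@dataclass(frozen=True)
class CallerThresholds:
    """Confidence floors per caller plus the shared probe minimum."""

    confidence: dict = None
    min_probes: int = MIN_PROBES

    def __post_init__(self):
        if self.confidence is None:
            object.__setattr__(self, "confidence", dict(DEFAULT_CONFIDENCE))

    def passes(self, call: CnvCall) -> bool:
        floor = self.confidence.get(call.caller)
        if floor is None:
            raise ValueError(f"no confidence threshold for caller {call.caller!r}")
        return call.confidence >= floor and call.n_probes >= self.min_probes


def apply_caller_thresholds(
    calls: list[CnvCall], thresholds: CallerThresholds | None = None
) -> list[CnvCall]:
    """Drop calls below their caller's confidence floor or under 3 probes.

    Idempotent: a second application removes nothing further.
    """
    thresholds = thresholds or CallerThresholds()
    return [c for c in calls if thresholds.passes(c)]


def merge_adjacent_calls(
    calls: list[CnvCall], gap_fraction: float = DEFAULT_GAP_FRACTION
) -> list[CnvCall]:
    """Merge fragmented same-state calls, iterating to a fixed point.

    Two calls from the same sample, caller, chromosome and copy number
    merge when the inter-call gap is at most ``gap_fraction`` of the
    span the merge would produce. Probe counts add; the merged
    confidence is the more conservative (minimum) of the pair.
    """
    if gap_fraction < 0:
        raise ValueError(f"gap_fraction must be nonnegative, got {gap_fraction}")

    groups: dict[tuple, list[CnvCall]] = defaultdict(list)
    for c in calls:
        groups[(c.sample, c.caller, c.interval.chrom, c.copy_number)].append(c)

    merged: list[CnvCall] = []
    for group in groups.values():
        group = sorted(group, key=lambda c: (c.interval.start, c.interval.end))
        out = [group[0]]
        for nxt in group[1:]:
            cur = out[-1]
            span_start = cur.interval.start
            span_end = max(cur.interval.end, nxt.interval.end)
            gap = max(0, nxt.interval.start - cur.interval.end - 1)
            span = span_end - span_start + 1
            if gap <= gap_fraction * span:
                out[-1] = cur.with_(
                    interval=GenomicInterval(cur.interval.chrom, span_start, span_end),
                    n_probes=cur.n_probes + nxt.n_probes,
                    confidence=min(cur.confidence, nxt.confidence),
                )
            else:
                out.append(nxt)
        merged.extend(out)
    # sorting within groups makes one left-to-right pass reach the fixed
    # point: any pair left unmerged only grows harder to merge as spans grow
    merged.sort(key=lambda c: (c.sample, c.caller, c.interval.chrom, c.interval.start))
    return merged


def label_concordance(
    penn: list[CnvCall],
    partition: list[CnvCall],
    reciprocal: float = CONCORDANCE_RECIPROCAL,
) -> list[tuple[CnvCall, str]]:
    """Label each call ``both`` / ``penn_only`` / ``partition_only``.

    A call earns ``both`` when the other caller has a same-sample,
    same-type call with reciprocal overlap at least ``reciprocal``
    (default 50%). The union of calls is retained regardless of label —
    the label is bookkeeping, not a filter.
    """

    def safe_type(c: CnvCall):
        # diploid PAR/XTR records have no CNV direction; they never match
        try:
            return c.cnv_type
        except ValueError:
            return None

    def matches(call: CnvCall, others: list[CnvCall]) -> bool:
        ctype = safe_type(call)
        if ctype is None:
            return False
        return any(
            o.sample == call.sample
            and safe_type(o) == ctype
            and reciprocal_overlap(call.interval, o.interval) >= reciprocal
            for o in others
        )

    labeled: list[tuple[CnvCall, str]] = []
    for c in penn:
        labeled.append((c, "both" if matches(c, partition) else "penn_only"))
    for c in partition:
        labeled.append((c, "both" if matches(c, penn) else "partition_only"))
    return labeled


def detect_roh(
    probes: list[ProbeRecord],
    sample: str,
    min_bp: int = ROH_MIN_BP,
    min_probes: int = ROH_MIN_PROBES,
) -> list[RohSegment]:
    """Find extended runs of homozygosity per chromosome.

    A run is a maximal stretch of consecutive AA/BB probes; no-calls
    (NC) are tolerated inside a run, any heterozygous (AB) probe
    terminates it. Runs must span at least ``min_bp`` (default 1 Mb)
    and contain at least ``min_probes`` homozygous probes.
    """
    by_chrom: dict[str, list[ProbeRecord]] = defaultdict(list)
    for p in probes:
        by_chrom[p.chrom].append(p)

    segments: list[RohSegment] = []
    for chrom in sorted(by_chrom):
        chrom_probes = by_chrom[chrom]
        positions = [p.position for p in chrom_probes]
        if positions != sorted(positions):
            raise ValueError(f"probes on chromosome {chrom} are not position-sorted")
        run: list[ProbeRecord] = []

        def flush(run: list[ProbeRecord]) -> None:
            if not run:
                return
            span = run[-1].position - run[0].position + 1
            if span >= min_bp and len(run) >= min_probes:
                segments.append(
                    RohSegment(
                        sample=sample,
                        interval=GenomicInterval(chrom, run[0].position, run[-1].position),
                        n_probes=len(run),
                    )
                )

        for p in chrom_probes:
            if p.is_homozygous():
                run.append(p)
            elif p.genotype == "NC":
                continue
            else:  # heterozygous probe breaks the run
                flush(run)
                run = []
        flush(run)
    segments.sort(key=lambda s: (s.interval.chrom, s.interval.start))
    return segments
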