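"""Gene-level annotation of candidate CNVs.

Intersects candidates with a transcript annotation (any 1-bp overlap
counts), flags hits against a model-organism-derived candidate gene
list, and reports overlap with — or distance to — the established
Ebstein anomaly genes NKX2-5, GATA4 and MYH7.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Optional

from .intervals import GenomicInterval, overlap_bp, round_half_away
from .models import CandidateCnv, TranscriptRecord

__all__ = [
    "KNOWN_EA_GENES",
    "index_transcripts",
    "intersect_transcripts",
    "flag_candidate_genes",
    "flag_known_ea_genes",
    "annotate_candidates",
]

#: Genes with prior reports of coding mutations in Ebstein anomaly.
KNOWN_EA_GENES = ("NKX2-5", "GATA4", "MYH7")


def index_transcripts(
    transcripts: Iterable[TranscriptRecord],
) -> dict[str, list[TranscriptRecord]]:
    """Bucket transcripts by chromosome (start-sorted)."""
    index: dict[str, list[TranscriptRecord]] = defaultdict(list)
    for t in transcripts:
        index[t.interval.chrom].append(t)
    for chrom in index:
        index[chrom].sort(key=lambda t: (t.interval.start, t.interval.end, t.gene))
    return dict(index)


def intersect_transcripts(
    candidate: CandidateCnv | GenomicInterval,
    transcript_index: dict[str, list[TranscriptRecord]],
) -> list[str]:
    """Sorted, deduplicated symbols of transcripts overlapping by >= 1 bp."""
    interval = (
        candidate.interval if isinstance(candidate, CandidateCnv) else candidate
    )
    hits = {
        t.gene
        for t in transcript_index.get(interval.chrom, [])
        if overlap_bp(interval, t.interval) > 0
    }
    return sorted(hits)


def flag_candidate_genes(symbols: list[str], candidate_list: frozenset) -> list[str]:
    """Case-insensitive intersection with a candidate-gene list, order kept."""
    wanted = {s.upper() for s in candidate_list}
    return [s for s in symbols if s.upper() in wanted]


def flag_known_ea_genes(
    candidate: CandidateCnv | GenomicInterval,
    known_gene_intervals: dict[str, GenomicInterval],
) -> dict[str, dict]:
    """Overlap with known disease genes, plus distance when disjoint.

    Returns per gene ``{"overlaps": bool, "distance_mb": float | None}``;
    distance (in Mb, one decimal) is reported only for same-chromosome
    non-overlapping pairs.
    """
    interval = (
        candidate.interval if isinstance(candidate, CandidateCnv) else candidate
    )
    report: dict[str, dict] = {}
    for gene, gi in known_gene_intervals.items():
        overlaps = overlap_bp(interval, gi) > 0
        distance_mb = None
        if not overlaps and gi.chrom == interval.chrom:
            gap = (
                gi.start - interval.end - 1
                if gi.start > interval.end
                else interval.start - gi.end - 1
            )
            distance_mb = round_half_away(gap / 1e6, 1)
        report[gene] = {"overlaps": overlaps, "distance_mb": distance_mb}
    return report


def annotate_candidates(
    candidates: list[CandidateCnv],
    transcripts: Iterable[TranscriptRecord],
    candidate_gene_list: frozenset = frozenset(),
    known_gene_intervals: Optional[dict[str, GenomicInterval]] = None,
) -> list[CandidateCnv]:
    """Attach transcript lists and gene flags to candidates in place."""
    index = index_transcripts(transcripts)
    for c in candidates:
        c.transcripts = intersect_transcripts(c, index)
        c.candidate_gene_hits = flag_candidate_genes(c.transcripts, candidate_gene_list)
        if known_gene_intervals:
            c.call.annotations["known_ea_genes"] = flag_known_ea_genes(
                c, known_gene_intervals
            )
    return candidates
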