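"""Shared domain records for the CNV pipeline.

These dataclasses are the in-memory currency passed between pipeline
stages: array probes, raw caller CNV calls, filtered candidate CNVs,
runs of homozygosity, sequence variants and reference CNV sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from .intervals import GenomicInterval, coverage_fraction, normalize_chrom

__all__ = [
    "ProbeRecord",
    "CnvCall",
    "RohSegment",
    "TranscriptRecord",
    "SequenceVariant",
    "CandidateCnv",
    "EnrichmentRecord",
    "ReferenceSet",
    "RegionMap",
    "HG19_REGIONS",
    "cnv_type_of",
]

# CNV type labels used for same-type matching everywhere
LOSS = "loss"
GAIN = "gain"
BOTH = "both"


def cnv_type_of(copy_number: int, expected_ploidy: int = 2) -> str:
    """'loss' below expected ploidy, 'gain' above it.

    Copy number equal to expected ploidy is not a CNV; callers never
    emit such calls on autosomes, and sex-chromosome calls are judged
    against sex-specific ploidy upstream.
    """
    if copy_number == expected_ploidy:
        raise ValueError(
            f"copy number {copy_number} equals expected ploidy; not a CNV"
        )
    return LOSS if copy_number < expected_ploidy else GAIN


@dataclass(frozen=True)
class ProbeRecord:
    """One SNP-array probe: genotype call plus intensity summaries.

    ``baf`` (B-allele frequency) is in [0, 1]; ``lrr`` (log R ratio) is
    the log-scaled total intensity deviation, ~0 for diploid copy number.
    """

    marker: str
    chrom: str
    position: int
    genotype: str  # AA / AB / BB / NC
    baf: float
    lrr: float

    def is_homozygous(self) -> bool:
        return self.genotype in ("AA", "BB")


@dataclass(frozen=True)
class RegionMap:
    """Sex-chromosome structure: PAR and XTR spans, for ploidy handling.

    PAR (pseudoautosomal) and XTR (X-transposed) regions behave as
    diploid in both sexes; the rest of X/Y is haploid in males.
    """

    par: tuple[GenomicInterval, ...] = ()
    xtr: tuple[GenomicInterval, ...] = ()

    def classify(self, interval: GenomicInterval) -> str:
        chrom = normalize_chrom(interval.chrom)
        if chrom not in ("X", "Y"):
            return "autosome"
        if any(coverage_fraction(interval, [p]) > 0.5 for p in self.par):
            return "PAR"
        if any(coverage_fraction(interval, [x]) > 0.5 for x in self.xtr):
            return "XTR"
        return "X_nonPAR" if chrom == "X" else "Y_nonPAR"

    def expected_ploidy(self, interval: GenomicInterval, sex: str) -> int:
        """Expected copy number for a span given sample sex ('M'/'F')."""
        region = self.classify(interval)
        if region in ("autosome", "PAR", "XTR"):
            return 2
        if region == "X_nonPAR":
            return 2 if sex == "F" else 1
        return 1  # Y_nonPAR; female Y calls are artifacts handled upstream


# hg19 PAR1/PAR2 and XTR spans on X (Y PARs mirror X coordinates per build
# convention; classification only needs the X-side spans plus Y labels).
HG19_REGIONS = RegionMap(
    par=(
        GenomicInterval("X", 60_001, 2_699_520),
        GenomicInterval("X", 154_931_044, 155_260_560),
        GenomicInterval("Y", 10_001, 2_649_520),
        GenomicInterval("Y", 59_034_050, 59_363_566),
    ),
    xtr=(GenomicInterval("X", 88_193_855, 93_193_855),),
)


@dataclass(frozen=True)
class CnvCall:
    """One caller's CNV call for one sample."""

    sample: str
    interval: GenomicInterval
    copy_number: int
    n_probes: int
    confidence: float
    caller: str  # "pennstyle" | "partitionstyle"
    region_class: str = "autosome"
    expected_ploidy: int = 2
    annotations: dict = field(default_factory=dict, compare=False)

    @property
    def cnv_type(self) -> str:
        return cnv_type_of(self.copy_number, self.expected_ploidy)

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def is_sex_chrom(self) -> bool:
        return normalize_chrom(self.interval.chrom) in ("X", "Y")

    def with_(self, **kwargs) -> "CnvCall":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class RohSegment:
    """Extended copy-neutral run of homozygosity (>= 1 Mb)."""

    sample: str
    interval: GenomicInterval
    n_probes: int


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript: gene symbol, span, biotype."""

    gene: str
    interval: GenomicInterval
    biotype: str = "protein_coding"
    transcript_id: str = ""


@dataclass(frozen=True)
class SequenceVariant:
    """A called sequence variant with per-allele read support.

    ``tier`` separates variants in established disease genes
    (``known_ea_gene``) from those in candidate genes
    (``candidate_gene``), which face an extra predicted-impact
    requirement during triage.
    """

    sample: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    ref_reads: int
    alt_reads: int
    population_af: Optional[float] = None
    tier: str = "candidate_gene"
    impact_flag: bool = False
    zygosity_call: str = "het"
    annotations: dict = field(default_factory=dict, compare=False)

    @property
    def depth(self) -> int:
        return self.ref_reads + self.alt_reads


@dataclass
class CandidateCnv:
    """A CNV call that survived selection, with its annotation payload."""

    call: CnvCall
    overlap_profile: dict = field(default_factory=dict)
    transcripts: list = field(default_factory=list)
    candidate_gene_hits: list = field(default_factory=list)
    recurrent: bool = False
    n_cases_sharing: int = 1
    cnv_id: Optional[int] = None
    review_flag: str = "pass"
    locus: str = ""

    @property
    def sample(self) -> str:
        return self.call.sample

    @property
    def interval(self) -> GenomicInterval:
        return self.call.interval

    @property
    def cnv_type(self) -> str:
        return self.call.cnv_type


@dataclass
class EnrichmentRecord:
    """Over-representation result for one gene set against one query list."""

    set_name: str
    overlap_genes: frozenset
    p_value: float
    adjusted_p: float = 1.0
    source_list: str = "all"
    gene_cnv_ids: dict = field(default_factory=dict)  # gene -> set of CNV ids
    members: frozenset = frozenset()


@dataclass
class ReferenceSet:
    """A reference CNV interval collection with per-entry type labels.

    Entries are (interval, type) with type in {loss, gain, both}.
    ``features_matching`` yields entries usable for same-type overlap;
    ``both`` entries match either query type.
    """

    name: str
    entries: list  # list[tuple[GenomicInterval, str]]

    def features_matching(self, cnv_type: str) -> list[GenomicInterval]:
        return [iv for iv, t in self.entries if t == BOTH or t == cnv_type]

    def coverage_of(self, interval: GenomicInterval, cnv_type: str) -> float:
        return coverage_fraction(interval, self.features_matching(cnv_type))

    def __len__(self) -> int:
        return len(self.entries)
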