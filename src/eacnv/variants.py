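"""Triage of targeted-sequencing variants by allelic balance and rarity.

True heterozygous variants carry roughly equal reference and alternate
read support (allelic balance ~0.5); capture-sequencing artifacts skew
strongly toward the reference allele. The triage keeps rare variants
with credible heterozygous support, applying a stricter
predicted-impact requirement to candidate-gene variants than to
variants in established disease genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .models import SequenceVariant

__all__ = [
    "TriageConfig",
    "allelic_balance",
    "classify_allelic_balance",
    "rare_frequency_filter",
    "triage",
    "TriageResult",
    "CARDIOMYOPATHY_PANEL",
]

#: Genes with autosomal-dominant cardiomyopathy associations used for
#: the case-level summary of sarcomere/desmosome variant carriers.
CARDIOMYOPATHY_PANEL = frozenset({"MYH7", "MYH6", "TTN", "TCAP", "JUP"})

ARTIFACT_MAX_AB = 0.25
EXPECTED_HET_BAND = (0.40, 0.85)


@dataclass
class TriageConfig:
    """Thresholds for variant triage.

    max_population_af: rarity ceiling on the population allele
    frequency (variants absent from the population database always
    pass). artifact_max_ab and expected-het band bound the allelic
    balance classes. Candidate-tier variants must additionally carry a
    predicted-impact annotation.
    """

    max_population_af: float = 0.005
    artifact_max_ab: float = ARTIFACT_MAX_AB
    het_band: tuple = EXPECTED_HET_BAND
    cardiomyopathy_panel: frozenset = CARDIOMYOPATHY_PANEL


def allelic_balance(v: SequenceVariant) -> float:
    """Alternate-read fraction alt/(ref+alt); requires nonzero depth."""
    if v.depth < 1:
        raise ValueError(f"variant {v.gene} {v.chrom}:{v.pos} has zero read depth")
    return v.alt_reads / v.depth


def classify_allelic_balance(
    ab: float, config: Optional[TriageConfig] = None
) -> str:
    """Partition [0, 1] into likely_artifact / expected_het / review.

    Below 0.25 the variant looks like a systematic artifact; within
    0.40-0.85 it looks like a genuine heterozygote; the remainder needs
    review (including near-1 values, which may be homozygous calls).
    """
    config = config or TriageConfig()
    if not (0.0 <= ab <= 1.0):
        raise ValueError(f"allelic balance {ab} outside [0, 1]")
    if ab < config.artifact_max_ab:
        return "likely_artifact"
    lo, hi = config.het_band
    if lo <= ab <= hi:
        return "expected_het"
    return "review"


def rare_frequency_filter(
    v: SequenceVariant, max_af: float = 0.005
) -> bool:
    """Retain variants absent from, or rare in, the population database."""
    return v.population_af is None or v.population_af < max_af


@dataclass
class TriageResult:
    """Outcome of variant triage over a cohort."""

    known_tier: list = field(default_factory=list)
    candidate_tier: list = field(default_factory=list)
    artifacts: list = field(default_factory=list)
    rejected_common: list = field(default_factory=list)
    rejected_impact: list = field(default_factory=list)
    sanger_candidates: list = field(default_factory=list)
    ab_class: dict = field(default_factory=dict)  # id(variant) keyed off list index

    @property
    def reported(self) -> list:
        return self.known_tier + self.candidate_tier

    def samples_with_variants(self, tier: Optional[str] = None) -> set:
        pool = (
            self.reported
            if tier is None
            else (self.known_tier if tier == "known_ea_gene" else self.candidate_tier)
        )
        return {v.sample for v in pool}

    def samples_in_panel(self, panel: Iterable[str]) -> set:
        """Distinct samples carrying a reported variant in the gene panel."""
        wanted = {g.upper() for g in panel}
        return {v.sample for v in self.reported if v.gene.upper() in wanted}

    def per_sample_summary(self) -> dict[str, list]:
        summary: dict[str, list] = {}
        for v in self.reported:
            summary.setdefault(v.sample, []).append(v)
        return summary


def triage(
    variants: Iterable[SequenceVariant], config: Optional[TriageConfig] = None
) -> TriageResult:
    """Apply allelic-balance and rarity rules; tier the survivors.

    Known-disease-gene variants are reported when rare and not
    artifact-classed; candidate-gene variants additionally require a
    predicted-impact annotation (loss of function, high impact, or
    pathogenic by multiple predictors — supplied as an input flag).
    Variants classed ``expected_het`` or ``review`` are queued for
    orthogonal confirmation (the Sanger-candidate list).
    """
    config = config or TriageConfig()
    result = TriageResult()
    for v in variants:
        ab = allelic_balance(v)
        ab_class = classify_allelic_balance(ab, config)
        if ab_class == "likely_artifact":
            result.artifacts.append(v)
            continue
        if not rare_frequency_filter(v, config.max_population_af):
            result.rejected_common.append(v)
            continue
        if v.tier == "known_ea_gene":
            result.known_tier.append(v)
        else:
            if not v.impact_flag:
                result.rejected_impact.append(v)
                continue
            result.candidate_tier.append(v)
        result.sanger_candidates.append(v)
        result.ab_class[(v.sample, v.chrom, v.pos, v.alt)] = ab_class
    return result
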