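"""Candidate CNV selection and prioritization.

A harmonized call becomes a candidate when it is large enough to trust
(probe and size floors), rare enough to matter (bounded overlap with
common copy-number polymorphism references, project controls and a
database of unrelated cases), and not a catalogued population variant
(multiple same-type entries in a DGV-like catalogue each covering most
of the call). Sex-chromosome calls get the same treatment after
removing spans that are effectively diploid in both sexes (copy-number
2 inside PAR/XTR). Recurrence across unrelated cases is then counted by
reciprocal-overlap grouping, and an LRR-based review flag stands in for
manual intensity-plot inspection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .intervals import reciprocal_overlap, size_kb
from .models import CandidateCnv, CnvCall, ProbeRecord, ReferenceSet

__all__ = [
    "FilterConfig",
    "profile_overlaps",
    "select_autosomal_candidates",
    "flag_dgv_exclusion",
    "select_sex_chromosome_candidates",
    "count_recurrence",
    "export_ranking_input",
    "review_candidates_by_lrr",
    "SelectionAudit",
]


@dataclass
class FilterConfig:
    """Thresholds of the selection rules.

    min_probes / min_size_kb: evidence floors for autosomal candidates.
    max_ref_overlap: a candidate must be covered strictly less than
    this fraction by every reference set (same CNV type only).
    dgv_min_entries / dgv_min_fraction: a call is excluded when at
    least ``dgv_min_entries`` same-type catalogue entries each cover at
    least ``dgv_min_fraction`` of it.
    recurrence_reciprocal: reciprocal-overlap fraction grouping
    same-type candidates across cases into one recurrent CNV.
    """

    min_probes: int = 10
    min_size_kb: int = 25
    max_ref_overlap: float = 0.35
    dgv_min_entries: int = 2
    dgv_min_fraction: float = 0.5
    recurrence_reciprocal: float = 0.5
    lrr_min_shift: float = 0.1
    reference_names: tuple = (
        "hapmap_cnp",
        "chop_blocks",
        "internal_controls",
        "unrelated_case_db",
    )

    def __post_init__(self):
        for name, frac in (
            ("max_ref_overlap", self.max_ref_overlap),
            ("dgv_min_fraction", self.dgv_min_fraction),
            ("recurrence_reciprocal", self.recurrence_reciprocal),
        ):
            if not (0 < frac <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {frac}")
        if self.min_probes <= 0 or self.min_size_kb <= 0:
            raise ValueError("probe and size floors must be positive")


@dataclass
class SelectionAudit:
    """Per-call record of the first selection rule that removed it."""

    call: CnvCall
    reason: str  # filtered_probes | filtered_size | filtered_common | filtered_dgv | filtered_par_xtr | retained


def profile_overlaps(
    call: CnvCall, references: dict[str, ReferenceSet], config: FilterConfig
) -> dict[str, float]:
    """Coverage of the call by each reference set (same CNV type only)."""
    profile = {}
    for name in config.reference_names:
        if name not in references:
            raise KeyError(f"reference set {name!r} not loaded")
        profile[name] = references[name].coverage_of(call.interval, call.cnv_type)
    return profile


def flag_dgv_exclusion(
    call: CnvCall | CandidateCnv,
    dgv: ReferenceSet,
    config: Optional[FilterConfig] = None,
) -> bool:
    """True when multiple same-type catalogue entries each cover most of the call.

    Entries are judged individually (never unioned): the rule asks
    whether the call looks like an already-catalogued polymorphism seen
    repeatedly, not whether polymorphic sequence tiles across it.
    """
    config = config or FilterConfig()
    cnv = call.call if isinstance(call, CandidateCnv) else call
    n_covering = 0
    for entry_iv, entry_type in dgv.entries:
        if entry_type not in ("both", cnv.cnv_type):
            continue
        covered = (
            0.0
            if entry_iv.chrom != cnv.interval.chrom
            else (
                max(
                    0,
                    min(entry_iv.end, cnv.interval.end)
                    - max(entry_iv.start, cnv.interval.start)
                    + 1,
                )
                / cnv.interval.size_bp
            )
        )
        if covered >= config.dgv_min_fraction:
            n_covering += 1
            if n_covering >= config.dgv_min_entries:
                return True
    return False


def _passes_reference_rules(
    call: CnvCall,
    references: dict[str, ReferenceSet],
    dgv: Optional[ReferenceSet],
    config: FilterConfig,
) -> tuple[Optional[CandidateCnv], str]:
    profile = profile_overlaps(call, references, config)
    if any(frac >= config.max_ref_overlap for frac in profile.values()):
        return None, "filtered_common"
    if dgv is not None and flag_dgv_exclusion(call, dgv, config):
        return None, "filtered_dgv"
    return CandidateCnv(call=call, overlap_profile=profile), "retained"


def select_autosomal_candidates(
    calls: Iterable[CnvCall],
    references: dict[str, ReferenceSet],
    config: Optional[FilterConfig] = None,
    dgv: Optional[ReferenceSet] = None,
) -> tuple[list[CandidateCnv], list[SelectionAudit]]:
    """Apply the autosomal selection rules; return survivors plus audit.

    Retains calls with at least ``min_probes`` probes, at least
    ``min_size_kb`` Kb, strictly less than ``max_ref_overlap`` coverage
    by every same-type reference set, and (when a DGV-like catalogue is
    supplied) no multiple-entry catalogue exclusion.
    """
    config = config or FilterConfig()
    candidates: list[CandidateCnv] = []
    audit: list[SelectionAudit] = []
    for call in calls:
        if call.is_sex_chrom:
            continue
        if size_kb(call.interval) < config.min_size_kb:
            audit.append(SelectionAudit(call, "filtered_size"))
            continue
        if call.n_probes < config.min_probes:
            audit.append(SelectionAudit(call, "filtered_probes"))
            continue
        candidate, reason = _passes_reference_rules(call, references, dgv, config)
        audit.append(SelectionAudit(call, reason))
        if candidate is not None:
            candidates.append(candidate)
    return candidates, audit


def select_sex_chromosome_candidates(
    calls: Iterable[CnvCall],
    sample_sex: dict[str, str],
    references: dict[str, ReferenceSet],
    config: Optional[FilterConfig] = None,
    dgv: Optional[ReferenceSet] = None,
) -> tuple[list[CandidateCnv], list[SelectionAudit]]:
    """Sex-chromosome selection: >= 25 Kb, PAR/XTR diploid spans removed.

    Copy-number-2 calls inside PAR or XTR are normal diploid state in
    both sexes and are dropped before the reference-overlap rules
    (which replace the study's manual review with the same exclusions
    applied to autosomes).
    """
    config = config or FilterConfig()
    candidates: list[CandidateCnv] = []
    audit: list[SelectionAudit] = []
    for call in calls:
        if not call.is_sex_chrom:
            continue
        if call.sample not in sample_sex:
            raise ValueError(f"unknown sex for sample {call.sample!r}")
        sex = sample_sex[call.sample]
        if size_kb(call.interval) < config.min_size_kb:
            audit.append(SelectionAudit(call, "filtered_size"))
            continue
        if call.region_class in ("PAR", "XTR") and call.copy_number == 2:
            audit.append(SelectionAudit(call, "filtered_par_xtr"))
            continue
        call = call.with_(annotations={**call.annotations, "sex": sex})
        candidate, reason = _passes_reference_rules(call, references, dgv, config)
        audit.append(SelectionAudit(call, reason))
        if candidate is not None:
            candidates.append(candidate)
    return candidates, audit


def dedupe_candidates(
    candidates: list[CandidateCnv], config: Optional[FilterConfig] = None
) -> list[CandidateCnv]:
    """Collapse the same event called by both callers in one sample.

    Same-sample, same-type candidates with >= 50% reciprocal overlap
    are one event; the penn-style representative is kept (reported
    coordinates follow that caller's segmentation), falling back to
    the higher-confidence call. The surviving record notes which
    callers saw the event.
    """
    config = config or FilterConfig()
    out: list[CandidateCnv] = []
    for c in candidates:
        for kept in out:
            if (
                kept.sample == c.sample
                and kept.cnv_type == c.cnv_type
                and reciprocal_overlap(kept.interval, c.interval)
                >= config.recurrence_reciprocal
            ):
                callers = set(kept.call.annotations.get("callers", [kept.call.caller]))
                callers.add(c.call.caller)
                prefer_new = (
                    c.call.caller == "pennstyle" and kept.call.caller != "pennstyle"
                ) or (
                    c.call.caller == kept.call.caller
                    and c.call.confidence > kept.call.confidence
                )
                if prefer_new:
                    out[out.index(kept)] = c
                    kept = c
                kept.call.annotations["callers"] = sorted(callers)
                break
        else:
            c.call.annotations.setdefault("callers", [c.call.caller])
            out.append(c)
    return out


def count_recurrence(
    candidates: list[CandidateCnv], config: Optional[FilterConfig] = None
) -> list[CandidateCnv]:
    """Group candidates into recurrent CNVs and assign CNV identifiers.

    Candidates in different samples with the same CNV type and
    reciprocal overlap >= ``recurrence_reciprocal`` are co-recurrent;
    connectivity is transitive, so a chain of pairwise-overlapping
    candidates shares one identifier. Identifiers are ordinals in
    (chromosome, start) order of each group's leftmost member.
    """
    config = config or FilterConfig()
    n = len(candidates)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for i in range(n):
        for j in range(i + 1, n):
            a, b = candidates[i], candidates[j]
            if a.sample == b.sample or a.cnv_type != b.cnv_type:
                continue
            if reciprocal_overlap(a.interval, b.interval) >= config.recurrence_reciprocal:
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    def chrom_key(ch: str):
        return (0, int(ch)) if ch.isdigit() else (1, ch)

    ordered = sorted(
        groups.values(),
        key=lambda idxs: min(
            (chrom_key(candidates[i].interval.chrom), candidates[i].interval.start)
            for i in idxs
        ),
    )
    for cnv_id, idxs in enumerate(ordered, start=1):
        samples = {candidates[i].sample for i in idxs}
        for i in idxs:
            candidates[i].cnv_id = cnv_id
            candidates[i].n_cases_sharing = len(samples)
            candidates[i].recurrent = len(samples) > 1
    return candidates


def export_ranking_input(
    calls: Iterable[CnvCall], config: Optional[FilterConfig] = None
) -> list[CnvCall]:
    """Superset of calls handed to external phenotype-based CNV ranking.

    Penn-style calls need >= ``min_probes`` probes and >= ``min_size_kb``
    Kb; partition-style autosomal calls only the size floor;
    partition-style sex-chromosome calls the size floor plus exclusion
    of copy-number-2 PAR/XTR spans.
    """
    config = config or FilterConfig()
    out = []
    for c in calls:
        if size_kb(c.interval) < config.min_size_kb:
            continue
        if c.caller == "pennstyle":
            if c.n_probes >= config.min_probes:
                out.append(c)
        elif c.caller == "partitionstyle":
            if c.is_sex_chrom and c.region_class in ("PAR", "XTR") and c.copy_number == 2:
                continue
            out.append(c)
    return out


def review_candidates_by_lrr(
    candidates: list[CandidateCnv],
    probes_by_sample: dict[str, list[ProbeRecord]],
    config: Optional[FilterConfig] = None,
) -> list[CandidateCnv]:
    """Rule-based stand-in for manual LRR/BAF plot review.

    A candidate fails review when the mean log R ratio across its
    probes is inconsistent with its copy-number direction: magnitude
    below ``lrr_min_shift`` (no intensity support) or sign opposite to
    the called change. Candidates without probe data keep their flag.
    """
    config = config or FilterConfig()
    for c in candidates:
        probes = probes_by_sample.get(c.sample)
        if not probes:
            continue
        lrrs = [
            p.lrr
            for p in probes
            if p.chrom == c.interval.chrom and c.interval.contains(p.position)
        ]
        if not lrrs:
            continue
        mean_lrr = float(np.mean(lrrs))
        expected_sign = -1.0 if c.cnv_type == "loss" else 1.0
        supported = abs(mean_lrr) >= config.lrr_min_shift and (
            mean_lrr * expected_sign > 0
        )
        c.review_flag = "pass" if supported else "fail"
    return candidates
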