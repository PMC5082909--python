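"""End-to-end orchestration: harmonize -> select -> annotate -> triage -> enrich.

``run_cnv_stages`` executes the CNV arm on in-memory inputs and returns
a :class:`PipelineResult` with the surviving candidates, the complete
selection audit and a machine-readable summary of per-stage counts.
``evaluate_truth`` compares a synthetic cohort's planted events against
that result, yielding the observed fate of every event — the basis of
the planted-truth recovery checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .annotate import annotate_candidates
from .enrichment import (
    adjust_records,
    apply_exclusion_rules,
    build_enrichment_map,
    build_query_lists,
    fisher_enrichment,
)
from .harmonize import (
    CallerThresholds,
    apply_caller_thresholds,
    label_concordance,
    merge_adjacent_calls,
)
from .intervals import overlap_bp, reciprocal_overlap
from .models import CandidateCnv, CnvCall, ReferenceSet
from .selection import (
    FilterConfig,
    SelectionAudit,
    count_recurrence,
    dedupe_candidates,
    review_candidates_by_lrr,
    select_autosomal_candidates,
    select_sex_chromosome_candidates,
)
from .simulate import SyntheticCohort
from .variants import TriageConfig, TriageResult, triage

__all__ = ["PipelineResult", "run_cnv_stages", "run_full", "evaluate_truth"]


@dataclass
class PipelineResult:
    candidates: list = field(default_factory=list)
    audits: list = field(default_factory=list)
    concordance: list = field(default_factory=list)
    triage_result: Optional[TriageResult] = None
    enrichment_records: list = field(default_factory=list)
    enrichment_map = None
    summary: dict = field(default_factory=dict)

    def retained(self) -> list:
        return [c for c in self.candidates if c.review_flag == "pass"]


def run_cnv_stages(
    penn_calls: list[CnvCall],
    partition_calls: list[CnvCall],
    references: dict[str, ReferenceSet],
    dgv: Optional[ReferenceSet] = None,
    sample_sex: Optional[dict] = None,
    probes_by_sample: Optional[dict] = None,
    filter_config: Optional[FilterConfig] = None,
    thresholds: Optional[CallerThresholds] = None,
) -> PipelineResult:
    """Threshold, merge, label, select, review and group CNV calls."""
    filter_config = filter_config or FilterConfig()
    penn = merge_adjacent_calls(apply_caller_thresholds(penn_calls, thresholds))
    partition = merge_adjacent_calls(apply_caller_thresholds(partition_calls, thresholds))
    concordance = label_concordance(penn, partition)
    union = penn + partition

    autosomal, audit_auto = select_autosomal_candidates(
        union, references, filter_config, dgv
    )
    candidates = autosomal
    audits: list[SelectionAudit] = list(audit_auto)
    if sample_sex is not None:
        sex_candidates, audit_sex = select_sex_chromosome_candidates(
            union, sample_sex, references, filter_config, dgv
        )
        candidates = candidates + sex_candidates
        audits.extend(audit_sex)
    candidates = dedupe_candidates(candidates, filter_config)
    candidates = count_recurrence(candidates, filter_config)
    if probes_by_sample:
        candidates = review_candidates_by_lrr(candidates, probes_by_sample, filter_config)

    result = PipelineResult(
        candidates=candidates, audits=audits, concordance=concordance
    )
    reasons: dict[str, int] = {}
    for a in audits:
        reasons[a.reason] = reasons.get(a.reason, 0) + 1
    result.summary = {
        "raw_calls": {"pennstyle": len(penn_calls), "partitionstyle": len(partition_calls)},
        "thresholded_merged": {"pennstyle": len(penn), "partitionstyle": len(partition)},
        "concordant_both": sum(1 for _, lab in concordance if lab == "both"),
        "selection_reasons": reasons,
        "candidates": len(candidates),
        "candidates_pass_review": len(result.retained()),
        "recurrent_groups": len(
            {c.cnv_id for c in candidates if c.recurrent}
        ),
        "distinct_cnv_ids": len({c.cnv_id for c in candidates}),
        "cases_with_candidate": len({c.sample for c in candidates}),
    }
    return result


def run_full(cohort: SyntheticCohort, filter_config: Optional[FilterConfig] = None,
             triage_config: Optional[TriageConfig] = None) -> PipelineResult:
    """Run every stage over a synthetic cohort bundle."""
    result = run_cnv_stages(
        cohort.penn_calls,
        cohort.partition_calls,
        cohort.references,
        dgv=cohort.dgv,
        sample_sex=cohort.sample_sex,
        probes_by_sample=cohort.probes_by_sample,
        filter_config=filter_config,
    )
    annotate_candidates(
        result.candidates, cohort.transcripts, cohort.candidate_gene_list
    )
    result.triage_result = triage(
        [pv.variant for pv in cohort.variants], triage_config
    )
    queries = build_query_lists(result.retained())
    records = []
    for ql in queries.values():
        recs = fisher_enrichment(ql, cohort.gene_set_library)
        records.extend(adjust_records(recs))
    surviving = apply_exclusion_rules(records)
    result.enrichment_records = surviving
    result.enrichment_map = build_enrichment_map(surviving)
    result.summary.update(
        {
            "variants_reported": len(result.triage_result.reported),
            "variant_cases": len(result.triage_result.samples_with_variants()),
            "gene_sets_surviving": len({r.set_name for r in surviving}),
            "enrichment_clusters": result.enrichment_map.n_clusters,
        }
    )
    return result


def write_summary(result: PipelineResult, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# planted-truth evaluation


def evaluate_truth(
    cohort: SyntheticCohort, result: PipelineResult, match_reciprocal: float = 0.5
) -> dict[str, dict]:
    """Observed pipeline fate of every planted event.

    An event is ``retained_candidate`` when a review-passing candidate
    in the same sample matches it at >= ``match_reciprocal`` reciprocal
    overlap (``artifact_flagged`` when the matching candidate failed
    review); otherwise its fate is the audit reason of the best-matching
    rejected call, or ``not_called`` when no thresholded call reached
    the selection stage.
    """
    fates: dict[str, dict] = {}
    for ev in cohort.events:
        observed = "not_called"
        for cand in result.candidates:
            if cand.sample != ev.sample:
                continue
            if reciprocal_overlap(cand.interval, ev.interval) >= match_reciprocal:
                observed = (
                    "retained_candidate"
                    if cand.review_flag == "pass"
                    else "artifact_flagged"
                )
                break
        else:
            # planted events are widely separated, so any same-sample
            # same-copy-number overlap identifies the event's call even
            # when jitter is large relative to a small event
            best = None
            best_ro = -1.0
            for audit in result.audits:
                if audit.reason == "retained" or audit.call.sample != ev.sample:
                    continue
                if audit.call.copy_number != ev.copy_number:
                    continue
                if overlap_bp(audit.call.interval, ev.interval) == 0:
                    continue
                ro = reciprocal_overlap(audit.call.interval, ev.interval)
                if ro > best_ro:
                    best, best_ro = audit, ro
            if best is not None:
                observed = best.reason
        fates[ev.event_id] = {
            "class": ev.klass,
            "expected": ev.expected_fate,
            "observed": observed,
            "sample": ev.sample,
        }
    return fates


def recovery_rates(fates: dict[str, dict]) -> dict[str, float]:
    """Per-class agreement summaries used by the acceptance checks.

    ``rare_retained``: fraction of planted rare autosomal events
    retained as review-passing candidates. ``common_filtered`` /
    ``subthreshold_filtered``: fraction NOT retained (must be 1.0).
    ``audited_reason_correct``: among filtered-class events for which a
    thresholded call reached selection, the fraction whose audit reason
    matches the planted expectation.
    """
    def of_class(*klasses):
        return [f for f in fates.values() if f["class"] in klasses]

    rates: dict[str, float] = {}
    rare = of_class("rare_candidate")
    if rare:
        rates["rare_retained"] = sum(
            f["observed"] == "retained_candidate" for f in rare
        ) / len(rare)
    common = of_class("common_cnp")
    if common:
        rates["common_filtered"] = sum(
            f["observed"] != "retained_candidate" for f in common
        ) / len(common)
    sub = of_class("small_size", "low_probe")
    if sub:
        rates["subthreshold_filtered"] = sum(
            f["observed"] != "retained_candidate" for f in sub
        ) / len(sub)
    filtered = of_class("common_cnp", "small_size", "low_probe", "dgv_like")
    audited = [f for f in filtered if f["observed"] != "not_called"]
    if audited:
        rates["audited_reason_correct"] = sum(
            f["observed"] == f["expected"] for f in audited
        ) / len(audited)
    return rates
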