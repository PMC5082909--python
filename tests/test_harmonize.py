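"""Thresholding, merging, concordance labeling and ROH detection."""

import pytest

from eacnv.harmonize import (
    apply_caller_thresholds,
    detect_roh,
    label_concordance,
    merge_adjacent_calls,
)
from eacnv.intervals import GenomicInterval
from eacnv.models import CnvCall, ProbeRecord


def call(chrom="1", start=1_000, end=10_000, cn=1, probes=12, conf=50.0,
         caller="pennstyle", sample="S1"):
    return CnvCall(
        sample=sample,
        interval=GenomicInterval(str(chrom), start, end),
        copy_number=cn,
        n_probes=probes,
        confidence=conf,
        caller=caller,
    )


class TestThresholds:
    @pytest.mark.parametrize(
        "caller, conf, probes, kept",
        [
            ("partitionstyle", 34.9, 12, False),
            ("partitionstyle", 35.0, 12, True),
            ("pennstyle", 10.0, 12, True),
            ("pennstyle", 9.9, 12, False),
            ("pennstyle", 50.0, 2, False),
            ("partitionstyle", 50.0, 3, True),
        ],
    )
    def test_floors(self, caller, conf, probes, kept):
        calls = [call(caller=caller, conf=conf, probes=probes)]
        assert bool(apply_caller_thresholds(calls)) is kept

    def test_idempotent(self):
        calls = [call(conf=c) for c in (5, 10, 50)]
        once = apply_caller_thresholds(calls)
        assert apply_caller_thresholds(once) == once


class TestMerge:
    def test_small_gap_merges(self):
        a = call(start=1_000, end=10_000)
        b = call(start=11_000, end=20_000)
        (merged,) = merge_adjacent_calls([a, b])
        assert merged.interval == GenomicInterval("1", 1_000, 20_000)
        assert merged.n_probes == a.n_probes + b.n_probes
        assert merged.confidence == min(a.confidence, b.confidence)

    def test_different_copy_number_never_merges(self):
        a = call(start=1_000, end=10_000, cn=1)
        b = call(start=11_000, end=20_000, cn=3)
        assert len(merge_adjacent_calls([a, b])) == 2

    def test_large_gap_stays_split(self):
        a = call(start=1_000, end=10_000)
        b = call(start=50_000, end=60_000)  # gap ~66% of merged span
        assert len(merge_adjacent_calls([a, b])) == 2

    def test_single_call_identity(self):
        a = call()
        assert merge_adjacent_calls([a]) == [a]

    def test_fixed_point_and_coverage_monotone(self):
        calls = [call(start=s, end=s + 5_000) for s in range(1_000, 60_000, 6_000)]
        merged = merge_adjacent_calls(calls)
        assert merge_adjacent_calls(merged) == merged
        covered_before = sum(c.interval.size_bp for c in calls)
        covered_after = sum(c.interval.size_bp for c in merged)
        assert covered_after >= covered_before

    def test_negative_gap_fraction_rejected(self):
        with pytest.raises(ValueError):
            merge_adjacent_calls([call()], gap_fraction=-0.1)


class TestConcordance:
    def test_identical_call_both(self):
        a = call(caller="pennstyle")
        b = call(caller="partitionstyle")
        labels = dict((c.caller, lab) for c, lab in label_concordance([a], [b]))
        assert labels == {"pennstyle": "both", "partitionstyle": "both"}

    def test_absent_partner_is_single_caller(self):
        (pair,) = label_concordance([call()], [])
        assert pair[1] == "penn_only"

    def test_below_reciprocal_not_both(self):
        a = call(start=1, end=10_000)
        b = call(start=1, end=3_000, caller="partitionstyle")  # 30% reciprocal
        labels = [lab for _, lab in label_concordance([a], [b])]
        assert labels == ["penn_only", "partition_only"]

    def test_type_mismatch_not_both(self):
        a = call(cn=1)
        b = call(cn=3, caller="partitionstyle")
        labels = [lab for _, lab in label_concordance([a], [b])]
        assert labels == ["penn_only", "partition_only"]

    def test_swap_symmetry(self):
        penn = [call(), call(start=50_000, end=60_000)]
        part = [call(caller="partitionstyle")]
        fwd = label_concordance(penn, part)
        rev = label_concordance(part, penn)
        flip = {"penn_only": "partition_only", "partition_only": "penn_only", "both": "both"}
        fwd_map = {(c.caller, c.interval.start): lab for c, lab in fwd}
        rev_map = {(c.caller, c.interval.start): lab for c, lab in rev}
        assert rev_map == {k: flip[v] for k, v in fwd_map.items()}


def probe(pos, genotype, chrom="1"):
    return ProbeRecord(
        marker=f"m{pos}", chrom=chrom, position=pos, genotype=genotype, baf=0.0, lrr=0.0
    )


class TestRoh:
    def test_long_homozygous_run_detected(self):
        probes = [probe(1 + i * 20_000, "AA") for i in range(60)]  # ~1.18 Mb
        (seg,) = detect_roh(probes, "S1")
        assert seg.interval.size_bp >= 1_000_000
        assert seg.n_probes == 60

    def test_short_run_rejected(self):
        probes = [probe(1 + i * 15_000, "BB") for i in range(60)]  # ~0.89 Mb
        assert detect_roh(probes, "S1") == []

    def test_het_probe_splits_run(self):
        # 1.5 Mb of homozygosity broken in the middle: neither half reaches 1 Mb
        probes = [probe(1 + i * 20_000, "AA") for i in range(75)]
        mid = probes[37]
        probes[37] = probe(mid.position, "AB")
        assert detect_roh(probes, "S1") == []

    def test_nc_probes_tolerated(self):
        probes = [
            probe(1 + i * 20_000, "NC" if i % 10 == 5 else "AA") for i in range(60)
        ]
        (seg,) = detect_roh(probes, "S1")
        assert seg.n_probes == 54  # homozygous probes only

    def test_probe_floor(self):
        probes = [probe(1 + i * 30_000, "AA") for i in range(40)]  # 1.17 Mb, 40 probes
        assert detect_roh(probes, "S1") == []

    def test_unsorted_input_rejected(self):
        probes = [probe(100, "AA"), probe(50, "AA")]
        with pytest.raises(ValueError, match="sorted"):
            detect_roh(probes, "S1")
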