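"""Candidate-selection rules: floors, reference overlap, DGV, recurrence."""

import pytest

from eacnv.intervals import GenomicInterval
from eacnv.models import CandidateCnv, CnvCall, ProbeRecord, ReferenceSet
from eacnv.selection import (
    FilterConfig,
    count_recurrence,
    export_ranking_input,
    flag_dgv_exclusion,
    profile_overlaps,
    review_candidates_by_lrr,
    select_autosomal_candidates,
    select_sex_chromosome_candidates,
)

REF_NAMES = ("hapmap_cnp", "chop_blocks", "internal_controls", "unrelated_case_db")


def call(chrom="1", start=1_000_000, size=40_000, cn=1, probes=15, sample="S1",
         caller="pennstyle", region="autosome", ploidy=2):
    return CnvCall(
        sample=sample,
        interval=GenomicInterval(str(chrom), start, start + size - 1),
        copy_number=cn,
        n_probes=probes,
        confidence=50.0,
        caller=caller,
        region_class=region,
        expected_ploidy=ploidy,
    )


def refs_with(name, entries):
    refs = {n: ReferenceSet(n, []) for n in REF_NAMES}
    refs[name] = ReferenceSet(name, entries)
    return refs


class TestProfileOverlaps:
    def test_no_overlap_all_zero(self, empty_references):
        profile = profile_overlaps(call(), empty_references, FilterConfig())
        assert set(profile) == set(REF_NAMES)
        assert all(v == 0.0 for v in profile.values())

    def test_contained_same_type_is_one(self):
        c = call(cn=1)
        refs = refs_with(
            "hapmap_cnp", [(GenomicInterval("1", 900_000, 1_200_000), "loss")]
        )
        assert profile_overlaps(c, refs, FilterConfig())["hapmap_cnp"] == 1.0

    def test_opposite_type_ignored(self):
        c = call(cn=1)  # deletion
        refs = refs_with(
            "hapmap_cnp", [(GenomicInterval("1", 900_000, 1_200_000), "gain")]
        )
        assert profile_overlaps(c, refs, FilterConfig())["hapmap_cnp"] == 0.0

    def test_missing_reference_set_rejected(self, empty_references):
        del empty_references["chop_blocks"]
        with pytest.raises(KeyError, match="chop_blocks"):
            profile_overlaps(call(), empty_references, FilterConfig())


class TestAutosomalSelection:
    def test_probe_floor(self, empty_references):
        survivors, audit = select_autosomal_candidates(
            [call(probes=9)], empty_references
        )
        assert survivors == []
        assert audit[0].reason == "filtered_probes"

    def test_size_floor(self, empty_references):
        survivors, audit = select_autosomal_candidates(
            [call(size=24_400, probes=12)], empty_references
        )
        assert survivors == []
        assert audit[0].reason == "filtered_size"

    def test_overlap_boundary_is_strict(self):
        # same-type feature covering exactly 35% of the call
        c = call(size=100_000, cn=1)
        refs = refs_with(
            "hapmap_cnp",
            [(GenomicInterval("1", 1_000_000, 1_034_999), "loss")],
        )
        survivors, audit = select_autosomal_candidates([c], refs)
        assert survivors == []
        assert audit[0].reason == "filtered_common"
        # one base fewer: 34.999% -> retained
        refs = refs_with(
            "hapmap_cnp",
            [(GenomicInterval("1", 1_000_000, 1_034_998), "loss")],
        )
        survivors, _ = select_autosomal_candidates([c], refs)
        assert len(survivors) == 1

    def test_sex_calls_not_handled_here(self, empty_references):
        survivors, audit = select_autosomal_candidates(
            [call(chrom="X", region="X_nonPAR")], empty_references
        )
        assert survivors == [] and audit == []

    def test_filters_monotone_in_thresholds(self, empty_references):
        calls = [call(start=s, size=30_000 + s % 50_000, probes=8 + s % 20)
                 for s in range(1_000_000, 9_000_000, 500_000)]
        lax = FilterConfig(min_probes=10, min_size_kb=25, max_ref_overlap=0.5)
        strict = FilterConfig(min_probes=10, min_size_kb=40, max_ref_overlap=0.35)
        kept_lax, _ = select_autosomal_candidates(calls, empty_references, lax)
        kept_strict, _ = select_autosomal_candidates(calls, empty_references, strict)
        lax_ids = {(c.sample, c.interval) for c in kept_lax}
        strict_ids = {(c.sample, c.interval) for c in kept_strict}
        assert strict_ids <= lax_ids


class TestDgvExclusion:
    def entry(self, frac, cnv_type="loss", shift=0):
        size = int(100_000 * frac)
        return (
            GenomicInterval("1", 1_000_000 + shift, 1_000_000 + shift + size - 1),
            cnv_type,
        )

    def test_two_entries_each_covering_half_excludes(self):
        c = call(size=100_000, cn=1)
        dgv = ReferenceSet("dgv", [self.entry(0.8), self.entry(0.8, shift=20_000)])
        assert flag_dgv_exclusion(c, dgv) is True

    def test_single_full_entry_retained(self):
        c = call(size=100_000, cn=1)
        dgv = ReferenceSet("dgv", [self.entry(1.0)])
        assert flag_dgv_exclusion(c, dgv) is False

    def test_opposite_type_entries_retained(self):
        c = call(size=100_000, cn=1)
        dgv = ReferenceSet("dgv", [self.entry(1.0, "gain"), self.entry(1.0, "gain")])
        assert flag_dgv_exclusion(c, dgv) is False

    def test_entries_not_unioned(self):
        # two same-type entries covering 40% each (80% union) do not trigger
        c = call(size=100_000, cn=1)
        dgv = ReferenceSet("dgv", [self.entry(0.4), self.entry(0.4, shift=50_000)])
        assert flag_dgv_exclusion(c, dgv) is False


class TestSexSelection:
    def test_female_x_duplication_retained(self, empty_references):
        c = call(chrom="X", start=44_381_642, size=491_150, cn=3,
                 region="X_nonPAR", caller="partitionstyle")
        survivors, _ = select_sex_chromosome_candidates(
            [c], {"S1": "F"}, empty_references
        )
        assert len(survivors) == 1
        assert survivors[0].call.annotations["sex"] == "F"

    def test_par_copy_two_excluded(self, empty_references):
        c = call(chrom="X", start=50_000, size=100_000, cn=2, region="PAR")
        survivors, audit = select_sex_chromosome_candidates(
            [c], {"S1": "M"}, empty_references
        )
        assert survivors == []
        assert audit[0].reason == "filtered_par_xtr"

    def test_below_size_floor_excluded(self, empty_references):
        c = call(chrom="X", start=2_000_000, size=20_000, cn=3, region="X_nonPAR")
        survivors, audit = select_sex_chromosome_candidates(
            [c], {"S1": "F"}, empty_references
        )
        assert survivors == []
        assert audit[0].reason == "filtered_size"

    def test_unknown_sex_rejected(self, empty_references):
        c = call(chrom="X", region="X_nonPAR", cn=3)
        with pytest.raises(ValueError, match="sex"):
            select_sex_chromosome_candidates([c], {}, empty_references)


class TestRecurrence:
    def cand(self, sample, start=1_000_000, size=100_000, cn=3, chrom="8"):
        return CandidateCnv(call=call(chrom=chrom, start=start, size=size,
                                      cn=cn, sample=sample))

    def test_two_case_duplication_grouped(self):
        a = self.cand("C12", start=83_573_868, size=390_363)
        b = self.cand("C47", start=83_848_688, size=133_142)
        # ~30% reciprocal: below the rule; widen b to overlap well
        b2 = self.cand("C47", start=83_600_000, size=390_000)
        grouped = count_recurrence([a, b2])
        assert grouped[0].cnv_id == grouped[1].cnv_id
        assert all(c.recurrent and c.n_cases_sharing == 2 for c in grouped)
        low = count_recurrence([a, b])
        assert low[0].cnv_id != low[1].cnv_id

    def test_unique_candidate(self):
        (c,) = count_recurrence([self.cand("C1")])
        assert not c.recurrent and c.n_cases_sharing == 1 and c.cnv_id == 1

    def test_type_mismatch_not_grouped(self):
        a = self.cand("C1", cn=1)
        b = self.cand("C2", cn=3)
        grouped = count_recurrence([a, b])
        assert grouped[0].cnv_id != grouped[1].cnv_id

    def test_partition_property(self):
        cands = [
            self.cand(f"C{i}", start=1_000_000 + (i % 3) * 2_000_000)
            for i in range(9)
        ]
        grouped = count_recurrence(cands)
        assert all(c.cnv_id is not None for c in grouped)
        by_id = {}
        for c in grouped:
            by_id.setdefault(c.cnv_id, []).append(c)
        assert sum(len(v) for v in by_id.values()) == len(cands)


class TestRankingExport:
    def test_rules(self):
        penn_small_probes = call(probes=9, size=30_000)
        penn_ok = call(probes=10, size=30_000)
        part_auto = call(caller="partitionstyle", probes=5, size=26_000)
        part_par2 = call(chrom="X", start=50_000, size=100_000, cn=2,
                         region="PAR", caller="partitionstyle")
        part_sex_ok = call(chrom="X", start=2_000_000, size=100_000, cn=3,
                           region="X_nonPAR", caller="partitionstyle")
        out = export_ranking_input(
            [penn_small_probes, penn_ok, part_auto, part_par2, part_sex_ok]
        )
        assert penn_small_probes not in out
        assert penn_ok in out
        assert part_auto in out
        assert part_par2 not in out
        assert part_sex_ok in out


class TestLrrReview:
    def probes_for(self, c, lrr):
        step = c.interval.size_bp // 10
        return [
            ProbeRecord(
                marker=f"m{i}",
                chrom=c.interval.chrom,
                position=c.interval.start + i * step,
                genotype="AA",
                baf=0.0,
                lrr=lrr,
            )
            for i in range(10)
        ]

    def test_supported_deletion_passes(self):
        cand = CandidateCnv(call=call(cn=1))
        review_candidates_by_lrr([cand], {"S1": self.probes_for(cand, -0.45)})
        assert cand.review_flag == "pass"

    def test_flat_lrr_fails(self):
        cand = CandidateCnv(call=call(cn=1))
        review_candidates_by_lrr([cand], {"S1": self.probes_for(cand, 0.01)})
        assert cand.review_flag == "fail"

    def test_wrong_sign_fails(self):
        cand = CandidateCnv(call=call(cn=3))
        review_candidates_by_lrr([cand], {"S1": self.probes_for(cand, -0.4)})
        assert cand.review_flag == "fail"
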