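"""Hypergeometric enrichment, BH adjustment, exclusion rules, enrichment map."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eacnv.enrichment import (
    KNOWN_GENE_SENTINEL,
    EnrichmentRecord,
    QueryList,
    adjust_records,
    apply_exclusion_rules,
    bh_adjust,
    build_enrichment_map,
    build_query_lists,
    fisher_enrichment,
    overlap_coefficient,
)
from eacnv.intervals import GenomicInterval
from eacnv.models import CandidateCnv, CnvCall


def hypergeom_tail_oracle(k, M, n, N):
    """P[X >= k] by exhaustive enumeration of the hypergeometric pmf."""
    total = 0
    for x in range(k, min(n, N) + 1):
        total += math.comb(n, x) * math.comb(M - n, N - x)
    return total / math.comb(M, N)


def cand(sample, cn, genes, cnv_id):
    call = CnvCall(
        sample=sample,
        interval=GenomicInterval("1", 1_000_000, 1_100_000),
        copy_number=cn,
        n_probes=20,
        confidence=50.0,
        caller="pennstyle",
    )
    c = CandidateCnv(call=call, cnv_id=cnv_id)
    c.transcripts = list(genes)
    return c


class TestQueryLists:
    def test_no_candidates_only_known_genes(self):
        lists = build_query_lists([])
        for ql in lists.values():
            assert ql.genes == frozenset({"MYH7", "GATA4", "NKX2-5"})
            assert all(ids == {KNOWN_GENE_SENTINEL} for ids in ql.gene_cnv_ids.values())

    def test_deletion_gene_in_all_and_deletions_only(self):
        lists = build_query_lists([cand("C1", 1, ["SUMF1"], 10)])
        assert "SUMF1" in lists["all"].genes
        assert "SUMF1" in lists["deletions"].genes
        assert "SUMF1" not in lists["duplications"].genes

    def test_gene_hit_by_both_types_unions_cnv_ids(self):
        cands = [cand("C1", 1, ["BMPR2"], 1), cand("C2", 3, ["BMPR2"], 2)]
        lists = build_query_lists(cands)
        assert lists["all"].gene_cnv_ids["BMPR2"] == {1, 2}
        assert lists["deletions"].gene_cnv_ids["BMPR2"] == {1}
        assert lists["duplications"].gene_cnv_ids["BMPR2"] == {2}


class TestFisher:
    def test_disjoint_query_p_one(self):
        lib = {"S": frozenset({"A", "B"})}
        bg = frozenset({"A", "B", "C", "D"})
        (rec,) = fisher_enrichment(frozenset({"C", "D"}), lib, bg)
        assert rec.p_value == 1.0

    def test_query_equals_background_p_one(self):
        bg = frozenset({"A", "B", "C"})
        (rec,) = fisher_enrichment(bg, {"S": bg}, bg)
        assert rec.p_value == pytest.approx(1.0)

    def test_small_example_vs_enumeration(self):
        bg = frozenset(f"G{i}" for i in range(20))
        members = frozenset(f"G{i}" for i in range(5))
        query = frozenset(f"G{i}" for i in range(4)) | {"G10"}
        (rec,) = fisher_enrichment(query, {"S": members}, bg)
        assert rec.p_value == pytest.approx(hypergeom_tail_oracle(4, 20, 5, 5))

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            fisher_enrichment(frozenset({"A"}), {}, frozenset())

    @settings(max_examples=100, derandomize=True)
    @given(st.data())
    def test_matches_enumeration_on_small_universes(self, data):
        M = data.draw(st.integers(4, 25))
        universe = [f"G{i}" for i in range(M)]
        bg = frozenset(universe)
        members = frozenset(data.draw(st.sets(st.sampled_from(universe), min_size=1)))
        query = frozenset(data.draw(st.sets(st.sampled_from(universe), min_size=1)))
        (rec,) = fisher_enrichment(query, {"S": members}, bg)
        k = len(query & members)
        expected = hypergeom_tail_oracle(k, M, len(members), len(query)) if k else 1.0
        assert rec.p_value == pytest.approx(expected, rel=1e-9)


class TestBhAdjust:
    def test_single_p_identity(self):
        assert bh_adjust([0.03]) == [pytest.approx(0.03)]

    def test_all_equal_unchanged(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_step_up_arithmetic(self):
        assert bh_adjust([0.01, 0.02, 0.9]) == pytest.approx([0.03, 0.03, 0.9])

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=12))
    def test_matches_manual_step_up(self, ps):
        m = len(ps)
        order = sorted(range(m), key=lambda i: ps[i])
        expected = [0.0] * m
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, ps[i] * m / rank)
            expected[i] = min(running, 1.0)
        assert bh_adjust(ps) == pytest.approx(expected)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=12))
    def test_never_decreases(self, ps):
        assert all(q >= p - 1e-12 for p, q in zip(ps, bh_adjust(ps)))


def record(name, overlap, adj, source="all", ids=None, members=None):
    overlap = frozenset(overlap)
    return EnrichmentRecord(
        set_name=name,
        overlap_genes=overlap,
        p_value=adj,
        adjusted_p=adj,
        source_list=source,
        gene_cnv_ids=ids or {g: {1} for g in overlap},
        members=frozenset(members or overlap),
    )


class TestExclusionRules:
    def test_nonsignificant_dropped(self):
        recs = [record("S", {"A", "B"}, 0.06, ids={"A": {1}, "B": {2}})]
        assert apply_exclusion_rules(recs) == []

    def test_known_only_overlap_dropped(self):
        recs = [
            record("S", {"MYH7", "GATA4"}, 0.01,
                   ids={"MYH7": {KNOWN_GENE_SENTINEL}, "GATA4": {KNOWN_GENE_SENTINEL}})
        ]
        assert apply_exclusion_rules(recs) == []

    def test_single_cnv_dropped(self):
        recs = [record("S", {"A", "B"}, 0.01, ids={"A": {8}, "B": {8}})]
        assert apply_exclusion_rules(recs) == []

    def test_multi_cnv_survives(self):
        recs = [record("S", {"A", "B"}, 0.01, ids={"A": {1}, "B": {2}})]
        assert len(apply_exclusion_rules(recs)) == 1

    def test_subset_list_redundancy(self):
        recs = [
            record("S", {"A", "B"}, 0.01, source="all", ids={"A": {1}, "B": {2}}),
            record("S", {"A", "B"}, 0.01, source="deletions", ids={"A": {1}, "B": {2}}),
            record("T", {"C", "D"}, 0.01, source="duplications", ids={"C": {3}, "D": {4}}),
        ]
        out = apply_exclusion_rules(recs)
        assert {(r.set_name, r.source_list) for r in out} == {
            ("S", "all"),
            ("T", "duplications"),
        }

    def test_output_subset_and_order_independent(self):
        recs = [
            record("S", {"A", "B"}, 0.01, ids={"A": {1}, "B": {2}}),
            record("T", {"C"}, 0.2, ids={"C": {3}}),
            record("U", {"MYH7"}, 0.001, ids={"MYH7": {KNOWN_GENE_SENTINEL}}),
        ]
        out = apply_exclusion_rules(recs)
        rev = apply_exclusion_rules(list(reversed(recs)))
        assert {r.set_name for r in out} == {r.set_name for r in rev} == {"S"}


class TestOverlapCoefficient:
    def test_examples(self):
        assert overlap_coefficient({"A"}, {"A"}) == 1.0
        assert overlap_coefficient({"A"}, {"B"}) == 0.0
        assert overlap_coefficient({"A", "B", "C", "D"},
                                   set("ABWXYZQRST")) == pytest.approx(0.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            overlap_coefficient(set(), {"A"})


class TestEnrichmentMap:
    def test_transitive_cluster(self):
        recs = [
            record("a", {"X"}, 0.01, members={"G1", "G2"}, ids={"X": {1, 2}}),
            record("b", {"X"}, 0.01, members={"G2", "G3"}, ids={"X": {1, 2}}),
            record("c", {"X"}, 0.01, members={"G3", "G4"}, ids={"X": {1, 2}}),
        ]
        emap = build_enrichment_map(recs)
        assert emap.n_clusters == 1
        assert emap.clusters["a"] == ["a", "b", "c"]

    def test_no_edges_all_singletons(self):
        recs = [
            record("a", {"X"}, 0.01, members={"G1", "G2"}),
            record("b", {"X"}, 0.01, members={"G3", "G4"}),
        ]
        emap = build_enrichment_map(recs)
        assert emap.n_clusters == 2 and emap.edges == []

    def test_cutoff_inclusive(self):
        recs = [
            record("a", {"X"}, 0.01, members={"G1", "G2"}),
            record("b", {"X"}, 0.01, members={"G2", "G5", "G6", "G7"}),
        ]
        emap = build_enrichment_map(recs, cutoff=0.5)
        assert emap.edges == [("a", "b", 0.5)]

    def test_order_invariance(self):
        recs = [
            record(n, {"X"}, 0.01, members=m)
            for n, m in [
                ("a", {"G1", "G2"}),
                ("b", {"G2", "G3"}),
                ("c", {"G9"}),
            ]
        ]
        fwd = build_enrichment_map(recs)
        rev = build_enrichment_map(list(reversed(recs)))
        assert fwd.clusters == rev.clusters and fwd.edges == rev.edges


def test_adjust_records_attaches_bh_within_list():
    recs = [
        record("a", {"X"}, 0.01),
        record("b", {"X"}, 0.02),
        record("c", {"X"}, 0.9),
    ]
    for r in recs:
        r.adjusted_p = 1.0
    adjust_records(recs)
    assert [r.adjusted_p for r in recs] == pytest.approx([0.03, 0.03, 0.9])
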