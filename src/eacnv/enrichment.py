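"""Gene-set over-representation of candidate-CNV genes, with an
enrichment map.

Three query lists are built from the candidate CNVs (all CNVs,
deletions only, duplications only), each augmented with the known
disease genes. Each list is tested against a gene-set library with the
one-sided hypergeometric (Fisher) test, Benjamini-Hochberg adjusted.
Surviving sets are pruned by redundancy rules (sets driven only by the
known genes, sets driven by a single CNV, deletion/duplication results
duplicating the all-CNVs result) and connected into an enrichment map:
nodes are gene sets, edges join sets whose member overlap coefficient
reaches the cutoff, clusters are the connected components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .models import CandidateCnv, EnrichmentRecord

__all__ = [
    "QueryList",
    "build_query_lists",
    "fisher_enrichment",
    "bh_adjust",
    "apply_exclusion_rules",
    "overlap_coefficient",
    "build_enrichment_map",
    "EnrichmentMap",
    "KNOWN_GENE_SENTINEL",
]

#: Pseudo-CNV identifier attached to the known disease genes added to
#: every query list (they are not carried by any candidate CNV).
KNOWN_GENE_SENTINEL = -1


@dataclass
class QueryList:
    """One enrichment query: gene symbols with contributing CNV ids."""

    name: str  # all | deletions | duplications
    gene_cnv_ids: dict[str, set] = field(default_factory=dict)

    @property
    def genes(self) -> frozenset:
        return frozenset(self.gene_cnv_ids)


def build_query_lists(
    candidates: Iterable[CandidateCnv],
    known_genes: Iterable[str] = ("MYH7", "GATA4", "NKX2-5"),
) -> dict[str, QueryList]:
    """Build the all/deletions/duplications query lists.

    Each candidate contributes its transcript symbols (uppercased) to
    the ``all`` list and to the list of its CNV type; every list also
    contains the known disease genes under a sentinel CNV id.
    """
    lists = {
        name: QueryList(name=name) for name in ("all", "deletions", "duplications")
    }
    for c in candidates:
        target = "deletions" if c.cnv_type == "loss" else "duplications"
        for gene in c.transcripts:
            g = gene.upper()
            for list_name in ("all", target):
                lists[list_name].gene_cnv_ids.setdefault(g, set()).add(c.cnv_id)
    for ql in lists.values():
        for g in known_genes:
            ql.gene_cnv_ids.setdefault(g.upper(), set()).add(KNOWN_GENE_SENTINEL)
    return lists


def fisher_enrichment(
    query: QueryList | frozenset,
    library: dict[str, frozenset],
    background: Optional[frozenset] = None,
) -> list[EnrichmentRecord]:
    """One-sided hypergeometric over-representation test per gene set.

    The p-value is P[X >= k] with X ~ Hypergeom(M=|background|,
    n=|set|, N=|query|) and k the observed overlap. Query symbols
    outside the background are dropped. Records are returned for every
    set in the library, BH-adjustment left to the caller.
    """
    if isinstance(query, QueryList):
        gene_cnv_ids = query.gene_cnv_ids
        source = query.name
        genes = query.genes
    else:
        gene_cnv_ids = {g: set() for g in query}
        source = "all"
        genes = frozenset(query)

    if background is None:
        background = frozenset().union(*library.values()) if library else frozenset()
    if not background:
        raise ValueError("empty background universe")

    query_in_bg = genes & background
    M, N = len(background), len(query_in_bg)
    records = []
    for name in sorted(library):
        members = library[name] & background
        overlap = frozenset(query_in_bg & members)
        k, n = len(overlap), len(members)
        p = float(hypergeom.sf(k - 1, M, n, N)) if k > 0 else 1.0
        records.append(
            EnrichmentRecord(
                set_name=name,
                overlap_genes=overlap,
                p_value=min(p, 1.0),
                source_list=source,
                gene_cnv_ids={g: set(gene_cnv_ids.get(g, set())) for g in overlap},
                members=frozenset(library[name]),
            )
        )
    return records


def bh_adjust(pvalues: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    if not pvalues:
        return []
    if any(not (0 <= p <= 1) for p in pvalues):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(pvalues, method="fdr_bh")[1])


def adjust_records(records: list[EnrichmentRecord]) -> list[EnrichmentRecord]:
    """Attach BH-adjusted p-values across one query list's records."""
    adjusted = bh_adjust([r.p_value for r in records])
    for r, q in zip(records, adjusted):
        r.adjusted_p = float(q)
    return records


def apply_exclusion_rules(
    records: list[EnrichmentRecord],
    known_genes: Iterable[str] = ("MYH7", "GATA4", "NKX2-5"),
    alpha: float = 0.05,
    count_known_as_pseudo_cnv: bool = False,
) -> list[EnrichmentRecord]:
    """Prune enrichment records by the significance and redundancy rules.

    Dropped are records with adjusted p >= alpha; records whose overlap
    is only the known disease genes; records whose overlap genes all
    derive from a single CNV; and deletion-/duplication-list records
    whose set also survives in the all-CNVs list. Rules are
    order-independent (each record is judged on its own fields plus the
    surviving all-list set names).
    """
    known = {g.upper() for g in known_genes}

    def significant(r: EnrichmentRecord) -> bool:
        return r.adjusted_p < alpha

    def not_known_only(r: EnrichmentRecord) -> bool:
        return bool(set(g.upper() for g in r.overlap_genes) - known)

    def multi_cnv(r: EnrichmentRecord) -> bool:
        cnv_ids = set()
        for g, ids in r.gene_cnv_ids.items():
            real = {i for i in ids if i != KNOWN_GENE_SENTINEL}
            cnv_ids |= real
            if count_known_as_pseudo_cnv and KNOWN_GENE_SENTINEL in ids:
                cnv_ids.add(KNOWN_GENE_SENTINEL)
        return len(cnv_ids) > 1

    keep = [r for r in records if significant(r) and not_known_only(r) and multi_cnv(r)]
    all_list_names = {r.set_name for r in keep if r.source_list == "all"}
    return [
        r
        for r in keep
        if r.source_list == "all" or r.set_name not in all_list_names
    ]


def overlap_coefficient(a: frozenset | set, b: frozenset | set) -> float:
    """|a n b| / min(|a|, |b|); both sets must be non-empty."""
    if not a or not b:
        raise ValueError("overlap coefficient undefined for empty sets")
    return len(set(a) & set(b)) / min(len(a), len(b))


@dataclass
class EnrichmentMap:
    """Similarity network over surviving gene sets.

    ``clusters`` maps a deterministic label (smallest member set name)
    to the sorted node list of one connected component; ``edges`` are
    (name_a, name_b, coefficient) with name_a < name_b.
    """

    graph: nx.Graph
    clusters: dict[str, list[str]]
    edges: list[tuple[str, str, float]]

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def build_enrichment_map(
    records: list[EnrichmentRecord], cutoff: float = 0.5
) -> EnrichmentMap:
    """Connect gene sets whose member overlap coefficient >= cutoff.

    Node attributes carry each set's adjusted p (node colour in the
    conventional rendering); edge weights carry the coefficient.
    Components are labelled by their alphabetically smallest member.
    """
    graph = nx.Graph()
    by_name: dict[str, EnrichmentRecord] = {}
    for r in records:
        # a set surviving from several query lists appears once
        if r.set_name not in by_name or r.adjusted_p < by_name[r.set_name].adjusted_p:
            by_name[r.set_name] = r
    for name, r in sorted(by_name.items()):
        graph.add_node(name, adjusted_p=r.adjusted_p, source_list=r.source_list)
    names = sorted(by_name)
    edges = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            coeff = overlap_coefficient(by_name[a].members, by_name[b].members)
            if coeff >= cutoff:
                graph.add_edge(a, b, weight=coeff)
                edges.append((a, b, coeff))
    clusters = {
        min(comp): sorted(comp) for comp in nx.connected_components(graph)
    }
    return EnrichmentMap(graph=graph, clusters=clusters, edges=sorted(edges))
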