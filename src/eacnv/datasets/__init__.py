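"""Reference datasets from a population-based isolated Ebstein anomaly cohort.

These small tables summarize the published results of a genome-wide
CNV screen of 47 isolated Ebstein anomaly cases drawn from 2,023,083
New York State live births (1998-2005): the candidate CNV table, the
validated rare sequence variants in known and candidate disease genes,
and the case-versus-all-births demographics table. They serve as
ground truth for regression tests and as inputs to the cohort
statistics stage.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "COHORT",
    "load_candidate_cnvs",
    "load_known_gene_variants",
    "load_candidate_gene_variants",
    "load_demographics",
]

#: Cohort accounting constants: all NYS live births in the study window,
#: ascertained Ebstein anomaly cases, and the exclusion cascade down to
#: the isolated cases eligible for genotyping.
COHORT = {
    "births": 2_023_083,
    "ascertained_cases": 117,
    "exclusions": {
        "syndromes_chromosomal": 14,
        "other_chds": 37,
        "other_major_defects": 14,
        "plural_births": 1,
    },
    "eligible_cases": 51,
    "genotyped_cases": 47,
}


def _read(name: str, **kwargs) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, sep="\t", **kwargs)


def load_candidate_cnvs() -> pd.DataFrame:
    """Candidate CNV table: one row per (CNV id, carrying case)."""
    return _read("candidate_cnvs.tsv", dtype={"chrom": str})


def load_known_gene_variants() -> pd.DataFrame:
    """Validated rare variants in the known disease genes."""
    return _read("known_gene_variants.tsv", dtype={"chrom": str}, na_values=["-"])


def load_candidate_gene_variants() -> pd.DataFrame:
    """Validated rare variants in candidate genes."""
    return _read("candidate_gene_variants.tsv", dtype={"chrom": str}, na_values=["-"])


def load_demographics() -> pd.DataFrame:
    """Case-versus-all-births demographics with printed percentages."""
    return _read("nys_cohort_demographics.tsv")
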