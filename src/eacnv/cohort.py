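"""Cohort accounting: birth prevalence, exclusion cascade, demographics.

The statistics here mirror how registry-based birth-defect studies
report their cohorts: a one-in-N birth prevalence rounded to the
nearest hundred, an audited exclusion cascade from all ascertained
cases down to the analyzable isolated cases, and Pearson chi-square
homogeneity tests of case demographics against all registry births.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .intervals import round_half_away

__all__ = [
    "ContingencyTable",
    "one_in_n_prevalence",
    "exclusion_cascade",
    "pearson_chi_square",
    "percent_of_column",
    "demographics_report",
]


@dataclass
class ContingencyTable:
    """Categories x (population, cases) count table."""

    labels: Sequence[str]
    population: Sequence[int]
    cases: Sequence[int]

    def __post_init__(self):
        if len(self.labels) < 2:
            raise ValueError("need at least two categories")
        if not (len(self.labels) == len(self.population) == len(self.cases)):
            raise ValueError("labels and count columns must align")
        if any(x < 0 for x in list(self.population) + list(self.cases)):
            raise ValueError("counts must be nonnegative")


def one_in_n_prevalence(cases: int, births: int) -> int:
    """Birth prevalence denominator '1 in N', N to the nearest hundred."""
    if cases < 1:
        raise ValueError("at least one case required")
    if births < cases:
        raise ValueError("births must be >= cases")
    return int(round_half_away(births / cases / 100.0)) * 100


def exclusion_cascade(
    total: int, exclusions: dict[str, int]
) -> tuple[int, list[dict]]:
    """Sequentially subtract labeled exclusions; return remainder + audit."""
    remaining = total
    audit = []
    for label, n in exclusions.items():
        remaining -= n
        if remaining < 0:
            raise ValueError(
                f"exclusion {label!r} ({n}) drives the running total negative"
            )
        audit.append({"step": label, "excluded": n, "remaining": remaining})
    return remaining, audit


def pearson_chi_square(table: ContingencyTable) -> tuple[float, float]:
    """Pearson chi-square without continuity correction.

    Tests homogeneity of the category distribution between the
    population and case columns; df = categories - 1.
    """
    counts = np.array([list(table.population), list(table.cases)], dtype=float)
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("every row and column marginal must be positive")
    stat, p, _, _ = chi2_contingency(counts, correction=False)
    return float(stat), float(p)


def percent_of_column(counts: Sequence[int]) -> list[float]:
    """Column percentages to one decimal, half rounded away from zero.

    Rounding passes through an intermediate two-decimal stage, matching
    the convention of registry reports whose percentages are first
    tabulated at two decimals and then abbreviated to one (visible in
    cells such as 48.7485% printed as 48.8).
    """
    total = sum(counts)
    if total <= 0:
        raise ValueError("column total must be positive")
    return [
        round_half_away(round_half_away(100.0 * c / total, 2), 1) for c in counts
    ]


def demographics_report(demographics: pd.DataFrame) -> pd.DataFrame:
    """Recompute percentages and chi-square p per characteristic.

    Expects columns (characteristic, category, population_count,
    case_count); returns one row per category with recomputed
    percentages plus the characteristic-level chi-square statistic and
    p-value repeated across its categories.
    """
    out_rows = []
    for characteristic, block in demographics.groupby("characteristic", sort=False):
        table = ContingencyTable(
            labels=list(block["category"]),
            population=list(block["population_count"]),
            cases=list(block["case_count"]),
        )
        stat, p = pearson_chi_square(table)
        pop_pct = percent_of_column(table.population)
        case_pct = percent_of_column(table.cases) if sum(table.cases) else [0.0] * len(
            table.cases
        )
        for label, pop, case, pp, cp in zip(
            table.labels, table.population, table.cases, pop_pct, case_pct
        ):
            out_rows.append(
                {
                    "characteristic": characteristic,
                    "category": label,
                    "population_count": pop,
                    "population_pct": pp,
                    "case_count": case,
                    "case_pct": cp,
                    "chi_square": stat,
                    "p_value": p,
                }
            )
    return pd.DataFrame(out_rows)
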