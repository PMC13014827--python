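"""Monetization of utilization counts with tariff unit costs.

All arithmetic carries full floating-point precision; rounding to integer
euros (half away from zero) happens only when a report is rendered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import CATEGORIES, GROUPS
from .errors import CohortError, TariffError

#: Cohort columns holding per-category per-person costs.
COST_COLUMNS: tuple[str, ...] = tuple(f"cost_{c}" for c in CATEGORIES)
TOTAL_COST_COLUMN = "total_cost"


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def inflate_cost(
    base_cost: float, from_year: int, to_year: int, cpi_index_by_year: Mapping[int, float]
) -> float:
    """Restate ``base_cost`` from ``from_year`` prices to ``to_year`` prices.

    Multiplies by the ratio of consumer-price indices.  Raises
    :class:`TariffError` naming any year absent from the index table.
    """
    if base_cost <= 0:
        raise ValueError(f"base_cost must be > 0, got {base_cost!r}")
    for year in (from_year, to_year):
        if year not in cpi_index_by_year:
            raise TariffError(f"year {year} not present in the CPI index table")
    return base_cost * cpi_index_by_year[to_year] / cpi_index_by_year[from_year]


@dataclass
class UnitCostTable:
    """Per-category tariffs with a common target price year and CPI anchors."""

    unit_costs: Mapping[str, float]
    price_year: int
    cpi_index_by_year: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in CATEGORIES if c not in self.unit_costs]
        if missing:
            raise TariffError(f"tariff table missing categories: {missing}")
        for cat, cost in self.unit_costs.items():
            if cost <= 0:
                raise ValueError(f"unit cost for {cat!r} must be > 0, got {cost!r}")

    def unit_cost(self, category: str) -> float:
        try:
            return self.unit_costs[category]
        except KeyError:
            raise TariffError(f"no tariff entry for category {category!r}") from None

    @classmethod
    def from_csv(cls, tariff_path, cpi_path=None, to_year: int | None = None):
        """Load a tariff CSV (category, unit_cost, price_year) and optionally a
        CPI CSV (year, index), restating every tariff to ``to_year`` prices."""
        tab = pd.read_csv(tariff_path)
        cpi: dict[int, float] = {}
        if cpi_path is not None:
            cpi_tab = pd.read_csv(cpi_path)
            cpi = dict(zip(cpi_tab["year"].astype(int), cpi_tab["index"].astype(float)))
        years = tab["price_year"].astype(int)
        target = int(to_year) if to_year is not None else int(years.max())
        costs = {}
        for _, row in tab.iterrows():
            cost, year = float(row["unit_cost"]), int(row["price_year"])
            if year != target:
                cost = inflate_cost(cost, year, target, cpi)
            costs[str(row["category"])] = cost
        return cls(unit_costs=costs, price_year=target, cpi_index_by_year=cpi)


def default_tariffs(alt: bool = False) -> UnitCostTable:
    """The packaged 2024 tariff table.

    ``alt=True`` selects the variant pricing a primary-care emergency visit
    at 73.34 euros instead of 73.30 (both figures appear in the source
    tariff documentation; the prose value is the default).
    """
    name = "tariffs_2024_alt.csv" if alt else "tariffs_2024.csv"
    data = resources.files("deprecon.data")
    with resources.as_file(data.joinpath(name)) as tariff_path, resources.as_file(
        data.joinpath("cpi_es.csv")
    ) as cpi_path:
        return UnitCostTable.from_csv(tariff_path, cpi_path, to_year=2024)


@dataclass(frozen=True)
class CostBreakdown:
    """Per-person costs; ``total_cost`` is exactly the sum of the categories."""

    per_category_cost: Mapping[str, float]
    total_cost: float


def cost_per_person(counts: Mapping[str, float], table: UnitCostTable) -> CostBreakdown:
    """count x unit cost per category, summed; no intermediate rounding."""
    unknown = [c for c in counts if c not in table.unit_costs]
    if unknown:
        raise TariffError(f"counts contain categories without a tariff: {unknown}")
    per_cat = {c: counts[c] * table.unit_cost(c) for c in counts}
    return CostBreakdown(per_category_cost=per_cat, total_cost=sum(per_cat.values()))


def add_costs(cohort: pd.DataFrame, table: UnitCostTable) -> pd.DataFrame:
    """Return a copy of the cohort with per-category and total cost columns."""
    out = cohort.copy()
    for cat in CATEGORIES:
        out[f"cost_{cat}"] = out[cat] * table.unit_cost(cat)
    out[TOTAL_COST_COLUMN] = out[list(COST_COLUMNS)].sum(axis=1)
    return out


@dataclass
class GroupSummary:
    """Per-group utilization and cost summary (one row per category + total).

    ``table`` columns: quantity, unit_cost, use and cost means per group
    (full precision), rounded cost cells, the (continuation -
    discontinuation) difference, and the standard errors of the group total
    costs (sample SD with n-1 denominator over sqrt(n)).
    """

    table: pd.DataFrame
    n_by_group: Mapping[str, int]
    se_total_by_group: Mapping[str, float]

    def rounded(self) -> pd.DataFrame:
        """Integer-euro rendering of the cost cells (half away from zero)."""
        out = self.table[["quantity", "unit_cost"]].copy()
        for g in GROUPS:
            out[f"mean_use_{g}"] = self.table[f"mean_use_{g}"]
            out[f"cost_{g}"] = self.table[f"mean_cost_{g}"].map(round_half_up)
        out["difference"] = self.table["difference"].map(round_half_up)
        return out


def group_cost_summary(cohort: pd.DataFrame, table: UnitCostTable) -> GroupSummary:
    """Per-group mean use and mean cost per person per category plus totals.

    Mean per-category cost is (group mean count) x (unit cost); the total row
    carries the mean per-person total cost with its standard error.  Raises
    :class:`CohortError` if either group is empty (the between-group
    difference would be undefined).
    """
    with_costs = add_costs(cohort, table)
    subs = {g: with_costs[with_costs["group"] == g] for g in GROUPS}
    for g, sub in subs.items():
        if len(sub) == 0:
            raise CohortError(f"group {g!r} is empty; group comparison undefined")

    rows = []
    for cat in CATEGORIES:
        row: dict = {"quantity": cat, "unit_cost": table.unit_cost(cat)}
        for g in GROUPS:
            mean_use = float(subs[g][cat].mean())
            row[f"mean_use_{g}"] = mean_use
            row[f"mean_cost_{g}"] = mean_use * table.unit_cost(cat)
        row["difference"] = (
            row[f"mean_cost_{GROUPS[0]}"] - row[f"mean_cost_{GROUPS[1]}"]
        )
        rows.append(row)
    total_row: dict = {"quantity": "total", "unit_cost": np.nan}
    se = {}
    for g in GROUPS:
        totals = subs[g][TOTAL_COST_COLUMN].to_numpy(dtype=float)
        total_row[f"mean_use_{g}"] = np.nan
        total_row[f"mean_cost_{g}"] = float(totals.mean())
        se[g] = (
            float(totals.std(ddof=1) / math.sqrt(len(totals)))
            if len(totals) > 1
            else float("nan")
        )
    total_row["difference"] = (
        total_row[f"mean_cost_{GROUPS[0]}"] - total_row[f"mean_cost_{GROUPS[1]}"]
    )
    rows.append(total_row)
    return GroupSummary(
        table=pd.DataFrame(rows),
        n_by_group={g: len(subs[g]) for g in GROUPS},
        se_total_by_group=se,
    )
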