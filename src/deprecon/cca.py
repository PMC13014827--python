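"""Cost-consequence comparison between the two study arms.

Group means, (continuation - discontinuation) differences, and Mann-Whitney
rank tests, optionally stratified by a covariate (e.g. sex).
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CATEGORIES, GROUPS
from .costs import TOTAL_COST_COLUMN, UnitCostTable, add_costs
from .errors import CohortError

#: Combined sample size at and above which the normal approximation is used.
EXACT_THRESHOLD = 20


def _u_statistic(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2.0)


def mann_whitney(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    method: str = "auto",
) -> tuple[float, float]:
    """Mann-Whitney U (a-over-b direction) and a two-sided p-value.

    Midranks handle ties.  For combined n below :data:`EXACT_THRESHOLD` the
    null distribution of U is enumerated exactly over all rank assignments
    (conditional on the observed tie pattern); at or above it a normal
    approximation with tie-corrected variance and a continuity correction is
    used.  The two-sided p doubles the smaller tail, capped at 1.  Two
    samples with a single common value yield p = 1 by convention.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise CohortError("mann_whitney requires two non-empty samples")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks
    u_a = _u_statistic(ranks[:n_a], n_a)

    if np.all(pooled == pooled[0]):
        return u_a, 1.0

    if method == "auto":
        method = "exact" if n < EXACT_THRESHOLD else "asymptotic"
    if method == "exact":
        offset = n_a * (n_a + 1) / 2.0
        n_le = n_ge = total = 0
        for combo in combinations(ranks, n_a):
            u = sum(combo) - offset
            total += 1
            if u <= u_a + 1e-9:
                n_le += 1
            if u >= u_a - 1e-9:
                n_ge += 1
        p = min(1.0, 2.0 * min(n_le, n_ge) / total)
        return u_a, p
    if method != "asymptotic":
        raise ValueError(f"unknown method {method!r}")

    mu = n_a * n_b / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return u_a, 1.0
    diff = u_a - mu
    # continuity correction shrinks |U - mu| by 0.5
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var) if diff != 0 else 0.0
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return u_a, p


def compare_groups(
    cohort_with_costs: pd.DataFrame,
    strata: str | None = None,
) -> pd.DataFrame:
    """One comparison row per resource category plus total cost, per stratum.

    ``cohort_with_costs`` must carry the cost columns added by
    :func:`deprecon.costs.add_costs`.  Rank tests use per-participant counts
    for category rows and per-participant total cost for the total row.  A
    stratum lacking one of the groups is reported with status ``untestable``
    rather than silently dropped.
    """
    if TOTAL_COST_COLUMN not in cohort_with_costs.columns:
        raise CohortError("cohort lacks cost columns; run add_costs first")
    if strata is None:
        strata_values = [("all", cohort_with_costs)]
    else:
        if strata not in cohort_with_costs.columns:
            raise CohortError(f"stratification column {strata!r} not in cohort")
        strata_values = [
            (str(level), sub)
            for level, sub in cohort_with_costs.groupby(strata, sort=True)
        ]

    rows = []
    quantities = [(cat, cat) for cat in CATEGORIES] + [
        ("total_cost", TOTAL_COST_COLUMN)
    ]
    for stratum, sub in strata_values:
        by_group = {g: sub[sub["group"] == g] for g in GROUPS}
        testable = all(len(s) > 0 for s in by_group.values())
        for label, col in quantities:
            row: dict = {"stratum": stratum, "quantity": label}
            for g in GROUPS:
                row[f"n_{g}"] = len(by_group[g])
                row[f"mean_{g}"] = (
                    float(by_group[g][col].mean()) if len(by_group[g]) else np.nan
                )
            if testable:
                row["difference"] = (
                    row[f"mean_{GROUPS[0]}"] - row[f"mean_{GROUPS[1]}"]
                )
                _, row["p_value"] = mann_whitney(
                    by_group[GROUPS[0]][col].to_numpy(),
                    by_group[GROUPS[1]][col].to_numpy(),
                )
                row["status"] = "ok"
            else:
                row["difference"] = np.nan
                row["p_value"] = np.nan
                row["status"] = "untestable"
            rows.append(row)
    return pd.DataFrame(rows)


def table2(cohort: pd.DataFrame, tariffs: UnitCostTable) -> pd.DataFrame:
    """Unstratified comparison (the main resource-use/cost table layout)."""
    return compare_groups(add_costs(cohort, tariffs), strata=None)


def table3(cohort: pd.DataFrame, tariffs: UnitCostTable) -> pd.DataFrame:
    """Sex-stratified comparison layout."""
    return compare_groups(add_costs(cohort, tariffs), strata="sex")
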