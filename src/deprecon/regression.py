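"""Poisson regressions of utilization counts, reported as rate ratios.

Log-link Poisson maximum likelihood per resource category; incidence rate
ratios are exponentiated coefficients with 95% Wald intervals.  Categorical
covariates use fixed, documented reference levels (never inferred from the
data): group = continuation, CCI band = 0-2, sex = women, income = low,
minor mental disorder = no.

Plain Poisson standard errors are the default; ``robust=True`` switches to
sandwich (HC0) standard errors for overdispersed counts — a plain Poisson
model does not itself account for overdispersion.  No exposure offset is
used: every participant shares the same six-month window.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import linalg, stats

from .cohort import CATEGORIES
from .errors import CohortError

#: predictor column -> (reference level, non-reference levels in output order)
CATEGORICAL_LEVELS: dict[str, tuple[str, tuple[str, ...]]] = {
    "group": ("continuation", ("discontinuation",)),
    "cci_band": ("0-2", ("3-4", ">=5")),
    "sex": ("women", ("men",)),
    "income_band": ("low", ("high",)),
    "minor_mental_disorder": ("no", ("yes",)),
}

NUMERIC_PREDICTORS = ("age", "bzd_duration")

#: Default covariate list per outcome model.
MODEL_COVARIATES: dict[str, tuple[str, ...]] = {
    "primary_care": ("group", "age", "cci_band", "income_band", "minor_mental_disorder"),
    "specialist": ("group", "age", "cci_band", "income_band", "sex"),
    "pc_emergency": (
        "group", "age", "cci_band", "income_band", "minor_mental_disorder", "sex",
    ),
    "hospital_emergency": (
        "group", "age", "cci_band", "income_band", "minor_mental_disorder", "sex",
    ),
}

Z_95 = stats.norm.ppf(0.975)


def build_design(
    cohort: pd.DataFrame,
    covariates: Sequence[str],
    reference_levels: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Design matrix with an intercept and documented dummy coding.

    ``reference_levels`` overrides the default reference for any categorical
    predictor (used e.g. to flip the group contrast).
    """
    overrides = dict(reference_levels or {})
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(cohort))}
    for name in covariates:
        if name not in cohort.columns:
            raise CohortError(f"covariate column {name!r} not present in cohort")
        if name in NUMERIC_PREDICTORS:
            cols[name] = cohort[name].to_numpy(dtype=float)
        elif name in CATEGORICAL_LEVELS:
            default_ref, others = CATEGORICAL_LEVELS[name]
            levels = [default_ref, *others]
            ref = overrides.get(name, default_ref)
            if ref not in levels:
                raise CohortError(
                    f"reference level {ref!r} not a level of {name!r} ({levels})"
                )
            observed = set(cohort[name].astype(str))
            unknown = observed - set(levels)
            if unknown:
                raise CohortError(f"column {name!r} has unknown levels {sorted(unknown)}")
            for level in levels:
                if level == ref:
                    continue
                cols[f"{name}[{level}]"] = (
                    cohort[name].astype(str) == level
                ).to_numpy(dtype=float)
        else:
            raise CohortError(f"unsupported covariate {name!r}")
    return pd.DataFrame(cols, index=cohort.index)


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # pivoted QR: columns pivoted beyond the numerical rank are the
        # (near-)collinear ones
        _, _, piv = linalg.qr(arr, mode="economic", pivoting=True)
        bad = [X.columns[piv[i]] for i in range(rank, arr.shape[1])]
        raise CohortError(
            f"design matrix is rank deficient (rank {rank} < {arr.shape[1]}); "
            f"collinear columns: {bad}"
        )


def fit_poisson_irr(
    cohort: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str],
    robust: bool = False,
    reference_levels: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Fit one log-link Poisson model; return an IRR record per predictor.

    Columns of the result: outcome, predictor, irr, ci_low, ci_high,
    p_value, flag.  The intercept row carries exp(intercept), i.e. the
    fitted rate at the reference covariate pattern.  A covariate level whose
    participants have all-zero counts is reported with flag ``separation``
    and a warning (its Wald interval is unreliable).
    """
    if outcome not in cohort.columns:
        raise CohortError(f"outcome column {outcome!r} not present in cohort")
    y = cohort[outcome].to_numpy(dtype=float)
    if (y < 0).any() or not np.allclose(y, np.rint(y)):
        raise CohortError(f"outcome {outcome!r} must hold nonnegative integer counts")
    X = build_design(cohort, covariates, reference_levels)

    if y.sum() == 0:
        warnings.warn(
            f"outcome {outcome!r} is all-zero; model degenerate", RuntimeWarning
        )
        return pd.DataFrame(
            {
                "outcome": outcome,
                "predictor": list(X.columns),
                "irr": np.nan,
                "ci_low": np.nan,
                "ci_high": np.nan,
                "p_value": np.nan,
                "flag": "degenerate_all_zero",
            }
        )

    _check_rank(X)
    model = sm.GLM(y, X, family=sm.families.Poisson())
    res = model.fit(cov_type="HC0" if robust else "nonrobust")

    separated = set()
    for col in X.columns:
        if col == "intercept" or col in NUMERIC_PREDICTORS:
            continue
        mask = X[col].to_numpy() == 1.0
        if mask.any() and y[mask].sum() == 0:
            separated.add(col)
            warnings.warn(
                f"level {col} has all-zero {outcome!r} counts (separation); "
                "its IRR is unreliable",
                RuntimeWarning,
            )

    coef = res.params
    se = res.bse
    with np.errstate(over="ignore"):  # separated levels have huge Wald SEs
        records = pd.DataFrame(
            {
                "outcome": outcome,
                "predictor": list(X.columns),
                "irr": np.exp(coef.to_numpy()),
                "ci_low": np.exp(coef.to_numpy() - Z_95 * se.to_numpy()),
                "ci_high": np.exp(coef.to_numpy() + Z_95 * se.to_numpy()),
                "p_value": res.pvalues.to_numpy(),
                "flag": ["separation" if c in separated else "" for c in X.columns],
            }
        )
    return records


def irr_table(
    cohort: pd.DataFrame,
    robust: bool = False,
    model_covariates: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Fit the four per-category models and stack their IRR records."""
    spec_map = model_covariates or MODEL_COVARIATES
    frames = []
    for outcome in CATEGORIES:
        frames.append(
            fit_poisson_irr(cohort, outcome, spec_map[outcome], robust=robust)
        )
    return pd.concat(frames, ignore_index=True)
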