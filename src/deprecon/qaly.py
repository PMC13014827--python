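"""Utility and QALY derivation from 7-item functional health totals.

The instrument total (7 best ... 35 worst) maps linearly onto a 0-1 utility
scale via ``utility = (35 - score) / 28``.  Over the half-year horizon two
quantities are computed:

* ``qaly_absolute`` — area under the linearly interpolated utility curve,
  ``(u0 + u6) / 2 * 0.5``, in [0, 0.5];
* ``qaly_gain``     — half-year QALY *change*, ``(u6 - u0) / 2 * 0.5``,
  in [-0.25, 0.25].

Both are emitted because the published group-level values (0.0275 / 0.0611
at baseline utility ~0.59) are only reproducible under the gain reading;
downstream cost-utility stages default to ``qaly_gain``.

Participants missing the six-month score are excluded from QALY analyses
(complete case); no imputation is performed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DomainError

HORIZON_YEARS = 0.5
SCORE_BEST, SCORE_WORST = 7.0, 35.0
_SCALE = SCORE_WORST - SCORE_BEST  # 28

#: Columns appended to a cohort frame by :func:`add_utility_columns`.
UTILITY_COLUMNS = ("u_baseline", "u_6m", "qaly_absolute", "qaly_gain")


def wonca_to_utility(score):
    """Map a total score in [7, 35] to utility in [0, 1]; affine, decreasing.

    Accepts scalars or arrays; NaN passes through (missing follow-up).
    """
    arr = np.asarray(score, dtype=float)
    valid = np.isnan(arr) | ((arr >= SCORE_BEST) & (arr <= SCORE_WORST))
    if not np.all(valid):
        bad = np.asarray(arr)[~valid].ravel()[0]
        raise DomainError(
            f"score {bad!r} outside the instrument range [{SCORE_BEST:g}, {SCORE_WORST:g}]"
        )
    out = (SCORE_WORST - arr) / _SCALE
    return float(out) if np.isscalar(score) else out


def _check_utilities(*values) -> None:
    for u in values:
        arr = np.asarray(u, dtype=float)
        ok = np.isnan(arr) | ((arr >= 0.0) & (arr <= 1.0))
        if not np.all(ok):
            raise DomainError("utilities must lie in [0, 1]")


def qaly_absolute(u_baseline, u_6m):
    """Half-year QALYs under linear utility interpolation between assessments."""
    _check_utilities(u_baseline, u_6m)
    out = (np.asarray(u_baseline, dtype=float) + np.asarray(u_6m, dtype=float)) / 2.0
    out = out * HORIZON_YEARS
    return float(out) if np.isscalar(u_baseline) and np.isscalar(u_6m) else out


def qaly_gain(u_baseline, u_6m):
    """Half-year QALY change; zero when the two utilities are equal."""
    _check_utilities(u_baseline, u_6m)
    out = (np.asarray(u_6m, dtype=float) - np.asarray(u_baseline, dtype=float)) / 2.0
    out = out * HORIZON_YEARS
    return float(out) if np.isscalar(u_baseline) and np.isscalar(u_6m) else out


def add_utility_columns(cohort: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with utility and QALY columns (:data:`UTILITY_COLUMNS`).

    Rows with a missing six-month score keep NaN QALYs so that consumers can
    apply the complete-case rule without losing the participant record.
    """
    out = cohort.copy()
    out["u_baseline"] = wonca_to_utility(out["wonca_baseline"].to_numpy())
    out["u_6m"] = wonca_to_utility(out["wonca_6m"].to_numpy())
    out["qaly_absolute"] = qaly_absolute(
        out["u_baseline"].to_numpy(), out["u_6m"].to_numpy()
    )
    out["qaly_gain"] = qaly_gain(out["u_baseline"].to_numpy(), out["u_6m"].to_numpy())
    return out
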