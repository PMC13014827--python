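"""Deterministic cost-utility analysis and probabilistic sensitivity analysis.

The deterministic stage computes incremental cost, incremental QALYs
(discontinuation minus continuation), the ICER, and a dominance class.  The
probabilistic stage propagates parameter (mean) uncertainty: per-arm mean
costs are drawn from gamma distributions and per-arm mean QALY gains from
beta distributions, both moment-matched to the arm's (mean, SE) — the SE of
the mean, not the participant-level SD, because reported arm moments are
"mean (SE)" and second-order uncertainty is about the mean.  Arms and
dimensions are sampled independently; no correlation structure is imposed.

Cost-effectiveness-plane convention: x = delta QALY, y = delta cost;
"southeast" (more effective, less costly) is x > 0, y < 0.  Draws landing
exactly on an axis — a probability-zero event for continuous marginals —
are assigned to the more-effective / less-costly side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import GROUPS
from .costs import TOTAL_COST_COLUMN
from .errors import CohortError, DomainError

QUADRANTS = ("ne", "se", "sw", "nw")


@dataclass(frozen=True)
class ArmMoments:
    """Summary moments of one study arm."""

    cost_mean: float
    cost_se: float
    qaly_mean: float
    qaly_se: float
    n: int = 0


@dataclass(frozen=True)
class IcerResult:
    """Incremental comparison, oriented discontinuation minus continuation."""

    delta_cost: float
    delta_qaly: float
    icer: float | None
    dominance: str
    icer_defined: bool

    def to_dict(self) -> dict:
        return {
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "icer": self.icer,
            "dominance": self.dominance,
            "icer_defined": self.icer_defined,
        }


def compute_icer(arm_cont: ArmMoments, arm_disc: ArmMoments) -> IcerResult:
    """Incremental cost, incremental QALYs, ICER and dominance class.

    Dominance: ``dominant`` (cheaper and more effective), ``dominated``
    (costlier and less effective), ``tradeoff_ne`` (costlier, more
    effective), ``tradeoff_sw`` (cheaper, less effective).  When the QALY
    difference is zero the ICER is undefined and dominance falls back to the
    cost sign alone (``equivalent`` if both differences vanish).
    """
    delta_cost = arm_disc.cost_mean - arm_cont.cost_mean
    delta_qaly = arm_disc.qaly_mean - arm_cont.qaly_mean
    if delta_qaly == 0:
        if delta_cost < 0:
            dominance = "dominant"
        elif delta_cost > 0:
            dominance = "dominated"
        else:
            dominance = "equivalent"
        return IcerResult(delta_cost, delta_qaly, None, dominance, False)
    if delta_cost < 0 and delta_qaly > 0:
        dominance = "dominant"
    elif delta_cost > 0 and delta_qaly < 0:
        dominance = "dominated"
    elif delta_qaly > 0:
        dominance = "tradeoff_ne"
    else:
        dominance = "tradeoff_sw"
    return IcerResult(delta_cost, delta_qaly, delta_cost / delta_qaly, dominance, True)


def gamma_from_moments(mu: float, sigma: float) -> tuple[float, float]:
    """(shape, scale) of the gamma with mean ``mu`` and SD ``sigma``.

    shape = mu^2/sigma^2, scale = sigma^2/mu; the implied mean and SD
    recover the inputs exactly.
    """
    if mu <= 0 or sigma <= 0:
        raise DomainError(f"gamma moments require mu > 0 and sigma > 0, got ({mu}, {sigma})")
    return mu * mu / (sigma * sigma), sigma * sigma / mu


def beta_from_moments(mu: float, sigma: float) -> tuple[float, float]:
    """(a, b) of the beta with mean ``mu`` in (0, 1) and SD ``sigma``.

    Method of moments: nu = mu(1-mu)/sigma^2 - 1, a = mu*nu, b = (1-mu)*nu.
    The variance must satisfy sigma^2 < mu(1-mu); a QALY-gain mean <= 0
    cannot be represented on [0, 1] and raises rather than being rescaled.
    """
    if not 0.0 < mu < 1.0:
        raise DomainError(f"beta mean must lie in (0, 1), got {mu}")
    if sigma <= 0:
        raise DomainError(f"beta SD must be > 0, got {sigma}")
    bound = mu * (1.0 - mu)
    if sigma * sigma >= bound:
        raise DomainError(
            f"infeasible beta variance: sigma^2 = {sigma * sigma:g} must be < "
            f"mu(1-mu) = {bound:g}"
        )
    nu = bound / (sigma * sigma) - 1.0
    return mu * nu, (1.0 - mu) * nu


def classify_quadrant(delta_qaly: np.ndarray, delta_cost: np.ndarray) -> np.ndarray:
    """Vectorized quadrant labels; axis points go east / south."""
    east = np.asarray(delta_qaly) >= 0
    south = np.asarray(delta_cost) <= 0
    out = np.where(east, np.where(south, "se", "ne"), np.where(south, "sw", "nw"))
    return out.astype(object)


@dataclass
class PsaResult:
    """Paired incremental draws with quadrant and ICER summaries."""

    draws: pd.DataFrame  # columns delta_qaly, delta_cost, quadrant
    quadrant_proportions: Mapping[str, float]
    icer_summary: Mapping[str, float]
    seed: int
    n_iter: int
    arm_cont: ArmMoments = field(repr=False, default=None)
    arm_disc: ArmMoments = field(repr=False, default=None)


def run_psa(
    arm_cont: ArmMoments,
    arm_disc: ArmMoments,
    n_iter: int = 1000,
    seed: int = 0,
) -> PsaResult:
    """Monte-Carlo PSA with gamma costs and beta QALYs per arm.

    Feasibility of all four moment pairs is checked before any sampling.
    Reproducible given ``seed``; exactly ``n_iter`` paired draws.
    """
    if n_iter < 1:
        raise ValueError(f"n_iter must be >= 1, got {n_iter}")
    params = {}
    for name, arm in (("continuation", arm_cont), ("discontinuation", arm_disc)):
        try:
            params[name] = (
                gamma_from_moments(arm.cost_mean, arm.cost_se),
                beta_from_moments(arm.qaly_mean, arm.qaly_se),
            )
        except DomainError as exc:
            raise DomainError(f"arm {name!r}: {exc}") from exc

    rng = np.random.default_rng(seed)
    draws = {}
    for name in ("continuation", "discontinuation"):
        (shape, scale), (a, b) = params[name]
        draws[name] = (
            rng.gamma(shape, scale, size=n_iter),
            rng.beta(a, b, size=n_iter),
        )
    delta_cost = draws["discontinuation"][0] - draws["continuation"][0]
    delta_qaly = draws["discontinuation"][1] - draws["continuation"][1]
    quad = classify_quadrant(delta_qaly, delta_cost)
    frame = pd.DataFrame(
        {"delta_qaly": delta_qaly, "delta_cost": delta_cost, "quadrant": quad}
    )
    proportions = {q: float(np.mean(quad == q)) for q in QUADRANTS}

    with np.errstate(divide="ignore", invalid="ignore"):
        icers = delta_cost / delta_qaly
    finite = icers[np.isfinite(icers)]
    icer_summary = {
        "mean": float(np.mean(finite)),
        "median": float(np.median(finite)),
        "p2.5": float(np.percentile(finite, 2.5)),
        "p97.5": float(np.percentile(finite, 97.5)),
        "n_finite": int(finite.size),
    }
    return PsaResult(
        draws=frame,
        quadrant_proportions=proportions,
        icer_summary=icer_summary,
        seed=seed,
        n_iter=n_iter,
        arm_cont=arm_cont,
        arm_disc=arm_disc,
    )


def icer_histogram(result: PsaResult, bins: int = 40) -> pd.DataFrame:
    """Binned counts of the per-draw ICER distribution (text-friendly)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        icers = result.draws["delta_cost"] / result.draws["delta_qaly"]
    finite = icers[np.isfinite(icers)].to_numpy()
    counts, edges = np.histogram(finite, bins=bins)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


def arm_moments_from_cohort(
    cohort: pd.DataFrame, group: str, qaly_column: str = "qaly_gain"
) -> ArmMoments:
    """Estimate (mean, SE) of total cost and QALYs for one arm, complete case."""
    sub = cohort[cohort["group"] == group]
    if len(sub) < 2:
        raise CohortError(f"group {group!r} needs >= 2 participants for SEs")
    for col in (TOTAL_COST_COLUMN, qaly_column):
        if col not in sub.columns:
            raise CohortError(f"cohort lacks column {col!r}; run costing/QALY stages")
    costs = sub[TOTAL_COST_COLUMN].dropna().to_numpy(dtype=float)
    qalys = sub[qaly_column].dropna().to_numpy(dtype=float)
    if len(qalys) < 2:
        raise CohortError(f"group {group!r} has < 2 complete QALY observations")
    return ArmMoments(
        cost_mean=float(costs.mean()),
        cost_se=float(costs.std(ddof=1) / np.sqrt(len(costs))),
        qaly_mean=float(qalys.mean()),
        qaly_se=float(qalys.std(ddof=1) / np.sqrt(len(qalys))),
        n=len(sub),
    )


def subgroup_psa(
    cohort: pd.DataFrame,
    strata: str,
    n_iter: int = 1000,
    seed: int = 0,
    qaly_column: str = "qaly_gain",
) -> dict[str, PsaResult | dict]:
    """Run the PSA within each level of ``strata`` (``cci_band`` or ``sex``).

    Strata where arm moments cannot be estimated or are infeasible for the
    gamma/beta models are returned as ``{"skipped": reason}`` entries rather
    than aborting the whole analysis.
    """
    if strata not in cohort.columns:
        raise CohortError(f"stratification column {strata!r} not in cohort")
    results: dict[str, PsaResult | dict] = {}
    # independent, deterministic sub-seed per stratum
    seeds = {}
    levels = sorted(cohort[strata].astype(str).unique())
    for sub_seed, level in zip(np.random.SeedSequence(seed).spawn(len(levels)), levels):
        seeds[level] = int(sub_seed.generate_state(1)[0])
    for level in levels:
        sub = cohort[cohort[strata].astype(str) == level]
        try:
            arms = {
                g: arm_moments_from_cohort(sub, g, qaly_column=qaly_column)
                for g in GROUPS
            }
            results[level] = run_psa(
                arms[GROUPS[0]], arms[GROUPS[1]], n_iter=n_iter, seed=seeds[level]
            )
        except (CohortError, DomainError) as exc:
            results[level] = {"skipped": str(exc)}
    return results
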