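"""Synthetic two-group deprescribing cohort generator.

Generates participant tables with the statistical structure the downstream
analyses assume: Bernoulli group assignment, independent categorical
covariates, per-group Poisson utilization counts, and functional-health
scores whose six-month change is specified on the utility scale.

Simplifications (documented, configurable):

* Counts are independent Poisson per category given the group.  An optional
  common lognormal frailty multiplier (mean 1) induces overdispersion and
  positive cross-category correlation.
* Group assignment is Bernoulli(``p_discontinue``) independent of covariates
  by default; ``assignment_coefs`` switches to a logistic link on selected
  covariates for confounding experiments.
* Functional-health scores are generated on a continuous scale, the utility
  change is applied, then both scores are rounded to integers and clipped to
  the instrument range [7, 35].
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import CohortError, ConfigError

#: Utilization categories, in canonical column order.
CATEGORIES: tuple[str, ...] = (
    "primary_care",
    "specialist",
    "pc_emergency",
    "hospital_emergency",
)

#: The two study arms.  "continuation" keeps the drug; "discontinuation"
#: achieved sustained cessation at follow-up (label only; no dispensing
#: history is simulated).
GROUPS: tuple[str, str] = ("continuation", "discontinuation")

#: Instrument bounds of the 7-item functional health chart (lower = better).
WONCA_MIN, WONCA_MAX = 7, 35

#: Cohort CSV column order.  ``to_csv``/``read_cohort_csv`` rely on it.
COHORT_COLUMNS: tuple[str, ...] = (
    "id",
    "group",
    "age",
    "sex",
    "income_band",
    "cci_band",
    "minor_mental_disorder",
    "bzd_duration",
    "indication",
    *CATEGORIES,
    "wonca_baseline",
    "wonca_6m",
)

_MARGINAL_LEVELS: dict[str, tuple[str, ...]] = {
    "sex": ("men", "women"),
    "income_band": ("low", "high"),
    "cci_band": ("0-2", "3-4", ">=5"),
    "minor_mental_disorder": ("no", "yes"),
    "indication": ("anxiety", "insomnia", "both", "other"),
}


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    ``group_mean_counts`` maps group -> category -> mean events per six
    months.  ``utility_change_mean_sd_by_group`` specifies the six-month
    utility change per group as (mean, sd) on the 0-1 utility scale; the
    generator converts it to the score scale as ``delta_score = -28 * delta_u``.
    """

    n_total: int
    p_discontinue: float
    group_mean_counts: Mapping[str, Mapping[str, float]]
    covariate_marginals: Mapping[str, Mapping[str, float]]
    age_mean_sd: tuple[float, float]
    bzd_duration_mean_sd: tuple[float, float]
    wonca_baseline_mean_sd: tuple[float, float]
    utility_change_mean_sd_by_group: Mapping[str, tuple[float, float]]
    seed: int = 0
    frailty_sd: float = 0.0
    assignment_coefs: Mapping[str, float] | None = field(default=None)

    def validate(self) -> None:
        """Raise :class:`ConfigError` naming the first offending field."""
        if not isinstance(self.n_total, (int, np.integer)) or self.n_total < 2:
            raise ConfigError(f"n_total must be an integer >= 2, got {self.n_total!r}")
        if not 0.0 <= self.p_discontinue <= 1.0:
            raise ConfigError(
                f"p_discontinue must be in [0, 1], got {self.p_discontinue!r}"
            )
        for group in GROUPS:
            if group not in self.group_mean_counts:
                raise ConfigError(f"group_mean_counts missing group {group!r}")
            for cat in CATEGORIES:
                rate = self.group_mean_counts[group].get(cat)
                if rate is None or rate < 0:
                    raise ConfigError(
                        f"group_mean_counts[{group!r}][{cat!r}] must be a rate >= 0, "
                        f"got {rate!r}"
                    )
            if group not in self.utility_change_mean_sd_by_group:
                raise ConfigError(
                    f"utility_change_mean_sd_by_group missing group {group!r}"
                )
            _, sd = self.utility_change_mean_sd_by_group[group]
            if sd < 0:
                raise ConfigError(
                    f"utility_change_mean_sd_by_group[{group!r}] sd must be >= 0"
                )
        for name, levels in _MARGINAL_LEVELS.items():
            marg = self.covariate_marginals.get(name)
            if marg is None:
                raise ConfigError(f"covariate_marginals missing {name!r}")
            if set(marg) != set(levels):
                raise ConfigError(
                    f"covariate_marginals[{name!r}] must have levels {levels}, "
                    f"got {tuple(marg)}"
                )
            probs = np.asarray([marg[lv] for lv in levels], dtype=float)
            if (probs < 0).any() or (probs > 1).any():
                raise ConfigError(
                    f"covariate_marginals[{name!r}] probabilities must be in [0, 1]"
                )
            if abs(probs.sum() - 1.0) > 1e-9:
                raise ConfigError(
                    f"covariate_marginals[{name!r}] must sum to 1 within 1e-9, "
                    f"sum is {probs.sum()!r}"
                )
        for fname in ("age_mean_sd", "bzd_duration_mean_sd", "wonca_baseline_mean_sd"):
            mean, sd = getattr(self, fname)
            if sd < 0:
                raise ConfigError(f"{fname} sd must be >= 0, got {sd!r}")
        if not WONCA_MIN <= self.wonca_baseline_mean_sd[0] <= WONCA_MAX:
            raise ConfigError(
                "wonca_baseline_mean_sd mean must lie in "
                f"[{WONCA_MIN}, {WONCA_MAX}], got {self.wonca_baseline_mean_sd[0]!r}"
            )
        if self.frailty_sd < 0:
            raise ConfigError(f"frailty_sd must be >= 0, got {self.frailty_sd!r}")

    @classmethod
    def from_dict(cls, raw: Mapping) -> "CohortConfig":
        try:
            cfg = cls(
                n_total=int(raw["n_total"]),
                p_discontinue=float(raw["p_discontinue"]),
                group_mean_counts={
                    g: {c: float(v) for c, v in cats.items()}
                    for g, cats in raw["group_mean_counts"].items()
                },
                covariate_marginals={
                    k: {str(lv): float(p) for lv, p in m.items()}
                    for k, m in raw["covariate_marginals"].items()
                },
                age_mean_sd=tuple(float(x) for x in raw["age_mean_sd"]),
                bzd_duration_mean_sd=tuple(
                    float(x) for x in raw["bzd_duration_mean_sd"]
                ),
                wonca_baseline_mean_sd=tuple(
                    float(x) for x in raw["wonca_baseline_mean_sd"]
                ),
                utility_change_mean_sd_by_group={
                    g: tuple(float(x) for x in v)
                    for g, v in raw["utility_change_mean_sd_by_group"].items()
                },
                seed=int(raw.get("seed", 0)),
                frailty_sd=float(raw.get("frailty_sd", 0.0)),
                assignment_coefs=raw.get("assignment_coefs"),
            )
        except KeyError as exc:  # missing top-level key
            raise ConfigError(f"cohort config missing field {exc.args[0]!r}") from exc
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_config(seed: int | None = None) -> CohortConfig:
    """The packaged configuration calibrated to the published study marginals."""
    text = resources.files("deprecon.data").joinpath("default_cohort.yaml").read_text()
    raw = yaml.safe_load(text)
    if seed is not None:
        raw["seed"] = int(seed)
    return CohortConfig.from_dict(raw)


def _draw_categorical(rng, levels: Sequence[str], probs, n: int) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    p = p / p.sum()  # remove float dust; validated to sum to 1 within 1e-9
    idx = rng.choice(len(levels), size=n, p=p)
    return np.asarray(levels, dtype=object)[idx]


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate a participant table; reproducible given ``config.seed``.

    Returns a DataFrame with columns :data:`COHORT_COLUMNS`, one row per
    participant.
    """
    config.validate()
    n = config.n_total
    # Independent sub-streams per generation stage so that editing one stage
    # cannot perturb the draws of another.
    streams = np.random.SeedSequence(config.seed).spawn(5)
    rng_assign, rng_cov, rng_counts, rng_wonca, rng_frailty = (
        np.random.default_rng(s) for s in streams
    )

    cov = {}
    for name, levels in _MARGINAL_LEVELS.items():
        marg = config.covariate_marginals[name]
        cov[name] = _draw_categorical(rng_cov, levels, [marg[lv] for lv in levels], n)
    age = np.clip(rng_cov.normal(*config.age_mean_sd, size=n), 18.0, 100.0).round(1)
    duration = np.clip(
        rng_cov.normal(*config.bzd_duration_mean_sd, size=n), 0.1, 40.0
    ).round(1)

    if config.assignment_coefs:
        coefs = dict(config.assignment_coefs)
        eta = np.full(n, float(coefs.pop("intercept", 0.0)))
        numeric = {"age": age, "bzd_duration": duration}
        for key, beta in coefs.items():
            if key in numeric:
                eta += float(beta) * numeric[key]
            elif key == "sex_men":
                eta += float(beta) * (cov["sex"] == "men")
            elif key == "minor_mental_disorder":
                eta += float(beta) * (cov["minor_mental_disorder"] == "yes")
            else:
                raise ConfigError(f"assignment_coefs has unsupported term {key!r}")
        p_disc = 1.0 / (1.0 + np.exp(-eta))
    else:
        p_disc = np.full(n, config.p_discontinue)
    disc = rng_assign.random(n) < p_disc
    group = np.where(disc, GROUPS[1], GROUPS[0]).astype(object)

    rates = np.empty((n, len(CATEGORIES)))
    for j, cat in enumerate(CATEGORIES):
        per_group = config.group_mean_counts
        rates[:, j] = np.where(
            disc, per_group[GROUPS[1]][cat], per_group[GROUPS[0]][cat]
        )
    if config.frailty_sd > 0:
        # Lognormal multiplier with mean exactly 1 shared across categories.
        s = config.frailty_sd
        sigma = np.sqrt(np.log1p(s * s))
        frailty = rng_frailty.lognormal(-0.5 * sigma * sigma, sigma, size=n)
        rates *= frailty[:, None]
    counts = rng_counts.poisson(rates)

    base_mean, base_sd = config.wonca_baseline_mean_sd
    wonca_base = rng_wonca.normal(base_mean, base_sd, size=n)
    du_mean = np.where(
        disc,
        config.utility_change_mean_sd_by_group[GROUPS[1]][0],
        config.utility_change_mean_sd_by_group[GROUPS[0]][0],
    )
    du_sd = np.where(
        disc,
        config.utility_change_mean_sd_by_group[GROUPS[1]][1],
        config.utility_change_mean_sd_by_group[GROUPS[0]][1],
    )
    delta_u = rng_wonca.normal(du_mean, du_sd)
    wonca_6m = wonca_base - 28.0 * delta_u  # higher utility -> lower score
    wonca_base = np.clip(np.rint(wonca_base), WONCA_MIN, WONCA_MAX).astype(int)
    wonca_6m = np.clip(np.rint(wonca_6m), WONCA_MIN, WONCA_MAX).astype(int)

    df = pd.DataFrame(
        {
            "id": [f"P{i:06d}" for i in range(1, n + 1)],
            "group": group,
            "age": age,
            "sex": cov["sex"],
            "income_band": cov["income_band"],
            "cci_band": cov["cci_band"],
            "minor_mental_disorder": cov["minor_mental_disorder"],
            "bzd_duration": duration,
            "indication": cov["indication"],
            **{cat: counts[:, j] for j, cat in enumerate(CATEGORIES)},
            "wonca_baseline": wonca_base,
            "wonca_6m": wonca_6m,
        }
    )
    return df[list(COHORT_COLUMNS)]


def calibration_report(cohort: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Configured-vs-realized moments, one row per calibrated quantity.

    Raises :class:`CohortError` on an empty cohort or an empty group (a
    degenerate configuration must fail loudly, not yield silent NaNs).
    """
    if len(cohort) == 0:
        raise CohortError("calibration_report requires a non-empty cohort")
    rows = []
    sizes = cohort["group"].value_counts()
    for group in GROUPS:
        if sizes.get(group, 0) == 0:
            raise CohortError(f"group {group!r} is empty; calibration undefined")
    p_conf = {GROUPS[0]: 1 - config.p_discontinue, GROUPS[1]: config.p_discontinue}
    for group in GROUPS:
        rows.append(
            ("group_share", group, p_conf[group], sizes[group] / len(cohort))
        )
        sub = cohort[cohort["group"] == group]
        for cat in CATEGORIES:
            rows.append(
                (
                    f"mean_{cat}",
                    group,
                    config.group_mean_counts[group][cat],
                    float(sub[cat].mean()),
                )
            )
        du_conf = config.utility_change_mean_sd_by_group[group][0]
        du_real = float((sub["wonca_baseline"] - sub["wonca_6m"]).mean()) / 28.0
        rows.append(("mean_utility_change", group, du_conf, du_real))
    rows.append(
        (
            "mean_wonca_baseline",
            "all",
            config.wonca_baseline_mean_sd[0],
            float(cohort["wonca_baseline"].mean()),
        )
    )
    rep = pd.DataFrame(
        rows, columns=["quantity", "group", "configured", "realized"]
    )
    rep["abs_deviation"] = rep["realized"] - rep["configured"]
    with np.errstate(divide="ignore", invalid="ignore"):
        rep["rel_deviation"] = np.where(
            rep["configured"] != 0,
            rep["abs_deviation"] / rep["configured"],
            np.nan,
        )
    return rep


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    """Serialize with the documented fixed column order and header."""
    cohort[list(COHORT_COLUMNS)].to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortError(f"cohort file {path} missing columns: {missing}")
    return df[list(COHORT_COLUMNS)]


def cohort_to_csv_bytes(cohort: pd.DataFrame) -> bytes:
    """Byte-exact serialization used by determinism checks."""
    buf = io.StringIO()
    write_cohort_csv(cohort, buf)
    return buf.getvalue().encode()
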