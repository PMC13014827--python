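"""End-to-end orchestration: simulate -> cost -> QALY -> CCA -> regression
-> CUA/PSA, with a file manifest and a reproducibility log.

All randomness flows from the single run seed; stage-level sub-seeds are
derived deterministically, so a rerun with the same configuration is
byte-identical for every deterministic artifact.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cca import compare_groups
from .cohort import (
    CATEGORIES,
    COHORT_COLUMNS,
    GROUPS,
    WONCA_MAX,
    WONCA_MIN,
    CohortConfig,
    default_config,
    generate_cohort,
    read_cohort_csv,
    write_cohort_csv,
)
from .costs import UnitCostTable, add_costs, default_tariffs
from .cua import arm_moments_from_cohort, compute_icer, run_psa
from .errors import ConfigError
from .qaly import add_utility_columns
from .regression import irr_table


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``cohort_path`` (existing CSV) and ``cohort_config``
    (synthetic generation) must be set; ``cohort_config=None`` with no path
    falls back to the packaged default synthetic cohort.
    """

    outdir: str
    cohort_path: str | None = None
    cohort_config: CohortConfig | None = None
    tariff_path: str | None = None
    cpi_path: str | None = None
    seed: int = 0
    n_iter: int = 1000
    write_cohort: bool = True
    run_cca: bool = True
    run_regression: bool = True
    run_cua: bool = True
    run_psa: bool = True

    def validate(self) -> None:
        if self.cohort_path is not None and self.cohort_config is not None:
            raise ConfigError("specify exactly one of cohort_path / cohort_config")
        if self.n_iter < 1:
            raise ConfigError(f"n_iter must be >= 1, got {self.n_iter}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        cohort_config = None
        if raw.get("cohort_config") is not None:
            cohort_config = CohortConfig.from_dict(raw["cohort_config"])
        cfg = cls(
            outdir=raw["outdir"],
            cohort_path=raw.get("cohort_path"),
            cohort_config=cohort_config,
            tariff_path=raw.get("tariff_path"),
            cpi_path=raw.get("cpi_path"),
            seed=int(raw.get("seed", 0)),
            n_iter=int(raw.get("n_iter", 1000)),
            write_cohort=bool(raw.get("write_cohort", True)),
            run_cca=bool(raw.get("run_cca", True)),
            run_regression=bool(raw.get("run_regression", True)),
            run_cua=bool(raw.get("run_cua", True)),
            run_psa=bool(raw.get("run_psa", True)),
        )
        cfg.validate()
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_tariffs(config: RunConfig) -> tuple[UnitCostTable, str]:
    if config.tariff_path is None:
        table = default_tariffs()
        return table, "packaged:tariffs_2024.csv"
    table = UnitCostTable.from_csv(config.tariff_path, config.cpi_path, to_year=2024)
    return table, _sha256(Path(config.tariff_path))


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Execute the configured stages; return a manifest name -> file path.

    Fails fast (before writing any output) on an invalid configuration or an
    unreadable cohort file.
    """
    config.validate()
    if config.cohort_path is not None:
        cohort = read_cohort_csv(config.cohort_path)
        cohort_seed = None
    else:
        root = np.random.SeedSequence(config.seed).spawn(2)
        cohort_seed = int(root[0].generate_state(1)[0])
        psa_seed = int(root[1].generate_state(1)[0])
        cohort_cfg = config.cohort_config or default_config()
        cohort_cfg = CohortConfig(
            **{**cohort_cfg.__dict__, "seed": cohort_seed}
        )
        cohort = generate_cohort(cohort_cfg)
    if config.cohort_path is not None:
        psa_seed = int(
            np.random.SeedSequence(config.seed).spawn(2)[1].generate_state(1)[0]
        )
    tariffs, tariff_hash = _load_tariffs(config)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    log: dict = {
        "seed": config.seed,
        "cohort_seed": cohort_seed,
        "psa_seed": psa_seed,
        "n_iter": config.n_iter,
        "tariff_sha256": tariff_hash,
        "versions": {
            "deprecon": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stage_counts": {"input": int(len(cohort))},
    }

    if config.write_cohort:
        path = outdir / "cohort.csv"
        write_cohort_csv(cohort, path)
        manifest["cohort"] = str(path)

    analysed = add_utility_columns(add_costs(cohort, tariffs))
    log["stage_counts"]["costed"] = int(len(analysed))
    log["stage_counts"]["complete_case_qaly"] = int(
        analysed["qaly_gain"].notna().sum()
    )

    if config.run_cca:
        t2 = compare_groups(analysed, strata=None)
        t3 = compare_groups(analysed, strata="sex")
        t2.to_csv(outdir / "table2.csv", index=False)
        t3.to_csv(outdir / "table3.csv", index=False)
        manifest["table2"] = str(outdir / "table2.csv")
        manifest["table3"] = str(outdir / "table3.csv")

    if config.run_regression:
        irr = irr_table(cohort)
        irr.to_csv(outdir / "table4_irr.csv", index=False)
        manifest["table4_irr"] = str(outdir / "table4_irr.csv")

    arms = None
    if config.run_cua or config.run_psa:
        arms = {g: arm_moments_from_cohort(analysed, g) for g in GROUPS}

    if config.run_cua:
        icer = compute_icer(arms[GROUPS[0]], arms[GROUPS[1]])
        payload = icer.to_dict()
        payload["arm_moments"] = {g: arms[g].__dict__ for g in GROUPS}
        (outdir / "icer.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
        manifest["icer"] = str(outdir / "icer.json")

    if config.run_psa:
        psa = run_psa(
            arms[GROUPS[0]], arms[GROUPS[1]], n_iter=config.n_iter, seed=psa_seed
        )
        psa.draws.to_csv(outdir / "psa_draws.csv", index=False)
        quad = pd.DataFrame(
            sorted(psa.quadrant_proportions.items()), columns=["quadrant", "proportion"]
        )
        quad.to_csv(outdir / "quadrants.csv", index=False)
        manifest["psa_draws"] = str(outdir / "psa_draws.csv")
        manifest["quadrants"] = str(outdir / "quadrants.csv")

    log["manifest"] = manifest
    log_path = outdir / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True))
    manifest["log"] = str(log_path)
    return manifest


@dataclass
class ValidationReport:
    """Outcome of cohort-file validation; one entry per violation."""

    path: str
    n_rows: int
    violations: list[dict] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_cohort_file(path) -> ValidationReport:
    """Check column presence, types, and value ranges of a cohort CSV.

    Row numbers in the report are 1-based over the data rows (header
    excluded).  A missing file raises the underlying I/O error.
    """
    df = pd.read_csv(path)
    report = ValidationReport(path=str(path), n_rows=len(df))

    def add(row: int | None, column: str, message: str) -> None:
        report.violations.append({"row": row, "column": column, "message": message})

    for col in COHORT_COLUMNS:
        if col not in df.columns:
            add(None, col, f"required column {col!r} missing")
    if report.violations:
        return report

    for i, value in enumerate(df["group"], start=1):
        if value not in GROUPS:
            add(i, "group", f"group label {value!r} not in allowed vocabulary {GROUPS}")
    for cat in CATEGORIES:
        values = df[cat]
        for i, v in enumerate(values, start=1):
            if pd.isna(v) or v < 0 or float(v) != int(v):
                add(i, cat, f"count {v!r} must be a nonnegative integer")
    for col in ("wonca_baseline", "wonca_6m"):
        for i, v in enumerate(df[col], start=1):
            if pd.isna(v):
                continue  # missing follow-up is handled complete-case
            if not WONCA_MIN <= v <= WONCA_MAX:
                add(
                    i,
                    col,
                    f"score {v!r} outside the instrument range "
                    f"[{WONCA_MIN}, {WONCA_MAX}]",
                )
    for i, v in enumerate(df["age"], start=1):
        if pd.isna(v) or v < 18 or v > 120:
            add(i, "age", f"age {v!r} outside plausible adult range [18, 120]")
    for i, v in enumerate(df["bzd_duration"], start=1):
        if pd.isna(v) or v < 0:
            add(i, "bzd_duration", f"duration {v!r} must be >= 0 years")
    return report
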