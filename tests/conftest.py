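import dataclasses

import pandas as pd
import pytest

from deprecon.cohort import COHORT_COLUMNS, CohortConfig, default_config


def make_cohort(rows):
    """Build a small cohort frame from partial row dicts (defaults filled in)."""
    defaults = dict(
        group="continuation",
        age=65.0,
        sex="women",
        income_band="low",
        cci_band="0-2",
        minor_mental_disorder="no",
        bzd_duration=4.0,
        indication="insomnia",
        primary_care=0,
        specialist=0,
        pc_emergency=0,
        hospital_emergency=0,
        wonca_baseline=18,
        wonca_6m=18,
    )
    records = []
    for i, row in enumerate(rows):
        rec = dict(defaults)
        rec.update(row)
        rec["id"] = rec.get("id", f"T{i:04d}")
        records.append(rec)
    return pd.DataFrame(records)[list(COHORT_COLUMNS)]


@pytest.fixture(scope="session")
def paper_config() -> CohortConfig:
    return default_config(seed=123)


@pytest.fixture(scope="session")
def small_config(paper_config) -> CohortConfig:
    return dataclasses.replace(paper_config, n_total=400, seed=11)
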