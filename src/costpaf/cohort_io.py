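"""Schema-validated readers/writers and run configuration.

Cohort tables are plain CSV with documented column names.  Two cohort roles
mirror the analysis design: a *linked* cohort carries per-sector cost
columns and follow-up and is used for model fitting; *unlinked* survey
cycles carry exposures and weights only and are used for PAF prediction.
The reader enforces which columns each role requires, validates categorical
tokens against the exposure vocabularies, and logs a row-count/missingness
summary.  Extra columns are carried through untouched (tolerant reader).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from costpaf.burden import CpiSeries, ExpenditureTable
from costpaf.cost_models import SECTORS
from costpaf.exposures import SCORED_COLUMNS, VOCABULARY

logger = logging.getLogger(__name__)

#: columns every cohort role must have
CORE_COLUMNS = ["person_id", "cycle_year", "sex", "weight"]
#: additionally required for the linked (fitting) role
LINKED_COLUMNS = ["person_years", *(f"cost_{s}" for s in SECTORS)]


class CohortSchemaError(ValueError):
    """Cohort file violates the documented schema."""


def _validate_categories(df: pd.DataFrame) -> None:
    for col, levels in VOCABULARY.items():
        if col not in df.columns:
            continue
        values = df[col].dropna()
        bad = ~values.isin(levels)
        if bad.any():
            row = int(values.index[bad][0])
            raise CohortSchemaError(
                f"unknown category token {values[bad].iloc[0]!r} in column "
                f"{col!r} at row {row}"
            )
    if "sex" in df.columns:
        bad = ~df["sex"].isin(["male", "female"])
        if bad.any():
            row = int(df.index[bad][0])
            raise CohortSchemaError(
                f"unknown sex token {df['sex'][bad].iloc[0]!r} at row {row}"
            )


def read_cohort(path, *, role: str = "linked") -> pd.DataFrame:
    """Read and validate a cohort CSV for the given role.

    ``role`` is ``"linked"`` (costs + person-years required) or
    ``"unlinked"`` (exposures and weights only).
    """
    if role not in ("linked", "unlinked"):
        raise ValueError(f"role must be 'linked' or 'unlinked', got {role!r}")
    df = pd.read_csv(path)
    required = list(CORE_COLUMNS)
    if role == "linked":
        required += LINKED_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortSchemaError(
            f"cohort file {path} is missing mandatory columns {missing}"
        )
    if "person_years" in df.columns:
        bad = df["person_years"] <= 0
        if bad.any():
            raise CohortSchemaError(
                f"non-positive person_years at row {int(df.index[bad][0])}"
            )
    if (df["weight"] <= 0).any():
        bad = df["weight"] <= 0
        raise CohortSchemaError(
            f"non-positive survey weight at row {int(df.index[bad][0])}"
        )
    for s in SECTORS:
        col = f"cost_{s}"
        if col in df.columns and (df[col] < 0).any():
            bad = df[col] < 0
            raise CohortSchemaError(
                f"negative {col} at row {int(df.index[bad][0])}"
            )
    _validate_categories(df)
    scored = [c for c in SCORED_COLUMNS if c in df.columns]
    n_missing = {
        c: int((df[c] == "missing").sum()) for c in scored if df[c].dtype == object
    }
    logger.info(
        "read %s cohort %s: %d rows, %d columns, missing-category counts %s",
        role, path, len(df), df.shape[1], n_missing,
    )
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_expenditure(path) -> ExpenditureTable:
    """Read a nominal-dollar annual sector expenditure CSV."""
    return ExpenditureTable(pd.read_csv(path), currency_year="nominal")


def write_expenditure(table: ExpenditureTable, path) -> None:
    table.data.to_csv(path, index=False)


def read_cpi(path) -> CpiSeries:
    return CpiSeries.from_frame(pd.read_csv(path))


def write_cpi(cpi: CpiSeries, path) -> None:
    cpi.to_frame().to_csv(path, index=False)


class SensitivityOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")

    bounds: bool = False
    trim_top: bool = False
    trim_fraction: float = 0.05
    ipw: bool = False
    ipw_treatment: str = "smoking"


class RunConfig(BaseModel):
    """End-to-end pipeline configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    cohort_path: str
    unlinked_path: str | None = None
    expenditure_path: str | None = None
    cpi_path: str | None = None
    output_dir: str = "costpaf_out"
    steps: list[int] = [1, 3, 5]
    risks: list[str] = ["smoking", "alcohol", "diet", "activity",
                        "combined", "ses"]
    weighted_fit: bool = False
    alcohol_heavy_only: bool = False
    baseline_year: int | None = None
    seed: int = 0
    sensitivity: SensitivityOptions = SensitivityOptions()

    @field_validator("steps")
    @classmethod
    def _steps_valid(cls, v):
        if not set(v) <= {1, 2, 3, 4, 5}:
            raise ValueError("ladder steps must be within 1..5")
        if 3 not in v:
            raise ValueError("the primary attribution step (3) must be fitted")
        return sorted(set(v))


def load_run_config(path) -> RunConfig:
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return RunConfig(**data)


def config_hash(config: BaseModel) -> str:
    payload = json.dumps(config.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()
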