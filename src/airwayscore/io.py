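"""Cohort CSV and thresholds-JSON reading and writing.

Cohort schema (header row, comma-delimited):
``id,bmi,retrognathia,ulbt_class,tmd_cm,hmd_cm,mmc_class`` with
retrognathia encoded ``present``/``absent`` (case-insensitive) or 1/0.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .scoring import PatientAirwayRecord, ScoreThresholds, ValidationError

COHORT_COLUMNS = ["id", "bmi", "retrognathia", "ulbt_class", "tmd_cm", "hmd_cm", "mmc_class"]

_RETRO_TRUE = {"present", "1", "true", "yes"}
_RETRO_FALSE = {"absent", "0", "false", "no"}


class CohortSchemaError(ValueError):
    """Raised when a cohort file violates the schema; names the row and field."""


def _parse_retrognathia(value: object, row: int) -> bool:
    text = str(value).strip().lower()
    if text in _RETRO_TRUE:
        return True
    if text in _RETRO_FALSE:
        return False
    raise CohortSchemaError(
        f"row {row}: retrognathia must be present/absent or 1/0, got {value!r}"
    )


def read_cohort_csv(path: str | Path) -> list[PatientAirwayRecord]:
    """Read and validate a cohort CSV into patient records."""
    try:
        frame = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise CohortSchemaError(f"{path}: file is empty") from None
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise CohortSchemaError(f"{path}: missing columns {missing}")
    if len(frame) == 0:
        raise CohortSchemaError(f"{path}: no data rows")
    records = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):  # 1-based + header
        try:
            records.append(
                PatientAirwayRecord(
                    id=str(row.id),
                    bmi=float(row.bmi),
                    retrognathia=_parse_retrognathia(row.retrognathia, i),
                    ulbt_class=int(row.ulbt_class),
                    tmd_cm=float(row.tmd_cm),
                    hmd_cm=float(row.hmd_cm),
                    mmc_class=int(row.mmc_class),
                )
            )
        except (ValidationError, TypeError) as exc:
            raise CohortSchemaError(f"row {i}: {exc}") from exc
        except ValueError as exc:
            raise CohortSchemaError(f"row {i}: not numeric — {exc}") from exc
    return records


def cohort_to_frame(records: Sequence[PatientAirwayRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "bmi": [r.bmi for r in records],
            "retrognathia": ["present" if r.retrognathia else "absent" for r in records],
            "ulbt_class": [r.ulbt_class for r in records],
            "tmd_cm": [r.tmd_cm for r in records],
            "hmd_cm": [r.hmd_cm for r in records],
            "mmc_class": [r.mmc_class for r in records],
        }
    )


def write_cohort_csv(records: Sequence[PatientAirwayRecord], path: str | Path) -> None:
    cohort_to_frame(records).to_csv(path, index=False)


def read_thresholds_json(path: str | Path) -> ScoreThresholds:
    """Thresholds overrides from a JSON object of field -> value."""
    with open(path) as fh:
        overrides = json.load(fh)
    unknown = set(overrides) - set(ScoreThresholds.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown threshold fields: {sorted(unknown)}")
    return ScoreThresholds(**overrides)
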