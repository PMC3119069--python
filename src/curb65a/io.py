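"""Cohort CSV round-tripping and run configuration.

The cohort schema is one row per patient:

    age,confusion,urea_mmol_l,resp_rate,sbp,dbp,proadm_nmol_l,diagnosis,
    death30,icu30,complication30,outpatient

Booleans are strictly 0/1, decimal points only, UTF-8, header mandatory.
``write_cohort`` followed by ``read_cohort`` is the identity on valid data.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortConfig
from .scoring import Diagnosis, PatientRecord, ScoreThresholds

__all__ = [
    "COHORT_COLUMNS",
    "CohortSchemaError",
    "CohortRowError",
    "read_cohort",
    "read_cohort_frame",
    "write_cohort",
    "cohort_to_frame",
    "frame_to_cohort",
    "RunConfig",
    "Subgroup",
    "cohort_config_from_yaml",
    "cohort_config_to_yaml",
]

COHORT_COLUMNS = [
    "age",
    "confusion",
    "urea_mmol_l",
    "resp_rate",
    "sbp",
    "dbp",
    "proadm_nmol_l",
    "diagnosis",
    "death30",
    "icu30",
    "complication30",
    "outpatient",
]

_BOOL_COLUMNS = ["confusion", "death30", "icu30", "complication30", "outpatient"]
_DIAGNOSES = {d.value for d in Diagnosis}


class CohortSchemaError(ValueError):
    """The file does not conform to the cohort CSV schema."""


class CohortRowError(ValueError):
    """A specific row fails validation; the message names row and column."""


def read_cohort_frame(path) -> pd.DataFrame:
    """Read and validate a cohort CSV into a DataFrame."""
    try:
        df = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise CohortSchemaError(f"{path}: file is empty (header mandatory)") from exc
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"{path}: missing columns {missing}")
    df = df[COHORT_COLUMNS]
    _validate_frame(df)
    return df


def _fail(row: int, column: str, why: str):
    # +2: one for the header line, one for 0-based indexing
    raise CohortRowError(f"row {row + 2}, column '{column}': {why}")


def _validate_frame(df: pd.DataFrame) -> None:
    for col in ["age", "urea_mmol_l", "resp_rate", "sbp", "dbp", "proadm_nmol_l"]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna() & df[col].notna())
        if bad.size:
            _fail(bad[0], col, f"non-numeric value {df[col].iloc[bad[0]]!r}")
    for col in _BOOL_COLUMNS:
        ok = df[col].isin([0, 1])
        if not ok.all():
            i = int(np.flatnonzero(~ok)[0])
            _fail(i, col, f"booleans must be 0/1, got {df[col].iloc[i]!r}")
    bad = np.flatnonzero(~df["diagnosis"].isin(_DIAGNOSES))
    if bad.size:
        _fail(
            int(bad[0]),
            "diagnosis",
            f"unknown value {df['diagnosis'].iloc[bad[0]]!r}; valid: {sorted(_DIAGNOSES)}",
        )
    checks = [
        ("age", df["age"] >= 18, "age must be >= 18"),
        ("resp_rate", df["resp_rate"] > 0, "respiratory rate must be positive"),
        ("sbp", df["sbp"] > 0, "systolic pressure must be positive"),
        ("dbp", df["dbp"] > 0, "diastolic pressure must be positive"),
        ("proadm_nmol_l", df["proadm_nmol_l"] > 0, "ProADM must be positive"),
        (
            "urea_mmol_l",
            (df["urea_mmol_l"] >= 0) | df["urea_mmol_l"].isna(),
            "urea must be nonnegative",
        ),
    ]
    for col, ok, why in checks:
        if not ok.all():
            _fail(int(np.flatnonzero(~ok)[0]), col, why)


def frame_to_cohort(df: pd.DataFrame) -> list[PatientRecord]:
    records = []
    for row in df.itertuples(index=False):
        rec = PatientRecord(
            age=int(row.age),
            confusion=bool(row.confusion),
            urea=float(row.urea_mmol_l) if not pd.isna(row.urea_mmol_l) else None,
            resp_rate=int(row.resp_rate),
            sbp=float(row.sbp),
            dbp=float(row.dbp),
            proadm=float(row.proadm_nmol_l),
            diagnosis=Diagnosis(row.diagnosis),
            death30=bool(row.death30),
            icu30=bool(row.icu30),
            complication30=bool(row.complication30),
            outpatient=bool(row.outpatient),
        )
        rec.validate()
        records.append(rec)
    return records


def cohort_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "age": [r.age for r in records],
            "confusion": [int(r.confusion) for r in records],
            "urea_mmol_l": [np.nan if r.urea is None else r.urea for r in records],
            "resp_rate": [r.resp_rate for r in records],
            "sbp": [r.sbp for r in records],
            "dbp": [r.dbp for r in records],
            "proadm_nmol_l": [r.proadm for r in records],
            "diagnosis": [r.diagnosis.value for r in records],
            "death30": [int(r.death30) for r in records],
            "icu30": [int(r.icu30) for r in records],
            "complication30": [int(r.complication30) for r in records],
            "outpatient": [int(r.outpatient) for r in records],
        }
    )


def read_cohort(path) -> list[PatientRecord]:
    """Read a cohort CSV into validated patient records."""
    return frame_to_cohort(read_cohort_frame(path))


def write_cohort(records, path) -> None:
    """Write patient records (or a cohort frame) to the cohort CSV schema."""
    df = records if isinstance(records, pd.DataFrame) else cohort_to_frame(records)
    # %.17g guarantees write-then-read is the identity on float fields
    df.to_csv(path, index=False, encoding="utf-8", float_format="%.17g")


# ------------------------------------------------------------- configuration


class Subgroup(enum.Enum):
    ALL = "all"
    CAP = "cap"
    NON_CAP = "non_cap"


@dataclass
class RunConfig:
    """One CLI invocation: command, paths, seed, subgroup and parameters."""

    command: str  # simulate | score | evaluate | report
    input_path: Optional[Path] = None
    output_dir: Optional[Path] = None
    seed: Optional[int] = None
    subgroup: Subgroup = Subgroup.ALL
    thresholds: ScoreThresholds = field(default_factory=ScoreThresholds)
    cohort: Optional[CohortConfig] = None
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.command == "simulate" and self.seed is None:
            raise ValueError("simulate requires a seed")
        if self.command in {"score", "evaluate", "report"} and self.input_path is None:
            raise ValueError(f"{self.command} requires an input path")


def cohort_config_from_yaml(path) -> CohortConfig:
    """Load a CohortConfig from YAML; absent keys keep their defaults."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in CohortConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown cohort config keys: {sorted(unknown)}")
    cfg = CohortConfig(**raw)
    cfg.validate()
    return cfg


def cohort_config_to_yaml(config: CohortConfig, path) -> None:
    data = {
        k: getattr(config, k) for k in CohortConfig.__dataclass_fields__
    }

    def _plain(v):
        if isinstance(v, tuple):
            return [_plain(x) for x in v]
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        return v

    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({k: _plain(v) for k, v in data.items()}, fh, sort_keys=False)
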