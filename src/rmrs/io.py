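"""Reading, validating and writing subject tables.

Input is a plain CSV with one row per subject. The six measurements
(glucose, sbp, dbp, triglycerides, hdl, waist — mg/dl, mmHg, cm) and sex
are mandatory; region, age, race and id are optional. Column names and
categorical labels are remappable through :class:`ColumnMapping`. Rows
that are unusable (missing/non-numeric/non-positive measurements,
sbp <= dbp, unrecognized sex) are rejected with a reason rather than
aborting the read; the first failing rule per row is reported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .scoring import (
    FactorThresholds,
    RmrsResult,
    SubjectRecord,
)

__all__ = [
    "ColumnMapping",
    "ValidationReport",
    "read_cohort",
    "resolve_thresholds",
    "write_scores",
    "load_threshold_config",
]

MEASUREMENTS = ("glucose", "sbp", "dbp", "triglycerides", "hdl", "waist")


@dataclass(frozen=True)
class ColumnMapping:
    """Logical field -> source column name, plus label dictionaries."""

    glucose: str = "glucose"
    sbp: str = "sbp"
    dbp: str = "dbp"
    triglycerides: str = "triglycerides"
    hdl: str = "hdl"
    waist: str = "waist"
    sex: str = "sex"
    region: str = "region"
    age: str = "age"
    race: str = "race"
    id: str = "id"
    sex_labels: dict = field(
        default_factory=lambda: {"male": "male", "m": "male", "female": "female", "f": "female"}
    )
    region_labels: dict = field(
        default_factory=lambda: {"korean": "korean", "american": "american"}
    )


@dataclass
class ValidationReport:
    n_read: int = 0
    n_valid: int = 0
    n_rejected: int = 0
    rejections: list[tuple[str, str]] = field(default_factory=list)

    def reject(self, row_id: str, reason: str) -> None:
        self.n_rejected += 1
        self.rejections.append((row_id, reason))


def _parse_row(
    row: pd.Series,
    mapping: ColumnMapping,
    row_id: str,
    default_region: str,
) -> tuple[SubjectRecord | None, str | None]:
    values = {}
    for fieldname in MEASUREMENTS:
        col = getattr(mapping, fieldname)
        raw = row.get(col)
        if raw is None or (isinstance(raw, float) and pd.isna(raw)) or str(raw).strip() == "":
            return None, f"missing {fieldname}"
        try:
            v = float(raw)
        except (TypeError, ValueError):
            return None, f"non-numeric {fieldname}"
        if not pd.notna(v) or v <= 0:
            return None, f"non-positive {fieldname}"
        values[fieldname] = v
    if values["sbp"] <= values["dbp"]:
        return None, "implausible bp (sbp <= dbp)"

    raw_sex = row.get(mapping.sex)
    sex = mapping.sex_labels.get(str(raw_sex).strip().lower())
    if sex is None:
        return None, f"unrecognized sex {raw_sex!r}"

    raw_region = row.get(mapping.region)
    if raw_region is None or pd.isna(raw_region) or str(raw_region).strip() == "":
        region = default_region
    else:
        region = mapping.region_labels.get(str(raw_region).strip().lower())
        if region is None:
            return None, f"unrecognized region {raw_region!r}"

    age = row.get(mapping.age)
    age = float(age) if age is not None and pd.notna(age) and str(age).strip() != "" else None
    race = row.get(mapping.race)
    race = str(race) if race is not None and pd.notna(race) and str(race).strip() != "" else None

    record = SubjectRecord(
        glucose=values["glucose"],
        sbp=values["sbp"],
        dbp=values["dbp"],
        triglycerides=values["triglycerides"],
        hdl=values["hdl"],
        waist=values["waist"],
        sex=sex,
        region=region,
        age=age,
        race=race,
        id=row_id,
    )
    return record, None


def read_cohort(
    path: str | Path,
    mapping: ColumnMapping | None = None,
    default_region: str = "korean",
    row_filter=None,
) -> tuple[list[SubjectRecord], ValidationReport]:
    """Read a subject CSV, returning valid records and a rejection report.

    ``row_filter``, if given, is a predicate on the raw pandas row applied
    before validation (e.g. study-specific exclusions); filtered rows are
    rejected with reason "filtered".
    """
    mapping = mapping or ColumnMapping()
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    for fieldname in (*MEASUREMENTS, "sex"):
        col = getattr(mapping, fieldname)
        if col not in df.columns:
            raise ValueError(f"mandatory column {col!r} not found in {path}")

    report = ValidationReport(n_read=len(df))
    records: list[SubjectRecord] = []
    for idx, row in df.iterrows():
        rid = str(row.get(mapping.id)) if mapping.id in df.columns and pd.notna(row.get(mapping.id)) else str(idx)
        if row_filter is not None and not row_filter(row):
            report.reject(rid, "filtered")
            continue
        record, reason = _parse_row(row, mapping, rid, default_region)
        if record is None:
            report.reject(rid, reason)
        else:
            records.append(record)
            report.n_valid += 1
    return records, report


def resolve_thresholds(
    sex: str,
    region: str = "korean",
    overrides: dict | None = None,
) -> FactorThresholds:
    """Sex/region-resolved diagnostic cutpoints with optional overrides."""
    return FactorThresholds.for_subject(sex, region, **(overrides or {}))


def load_threshold_config(path: str | Path) -> dict:
    """Load a JSON or YAML threshold-override config.

    Recognized keys: any FactorThresholds field name, plus
    ``diagnostic_threshold``.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        config = yaml.safe_load(text) or {}
    else:
        config = json.loads(text)
    if not isinstance(config, dict):
        raise ValueError(f"threshold config {path} must be a mapping")
    return config


SCORE_COLUMNS = (
    "s_gl",
    "s_bp",
    "s_tg",
    "s_hdl",
    "s_wc",
    "rmrs",
    "risk_factor_count",
    "mets_by_count",
    "mets_by_rmrs",
)


def scores_frame(
    records: Sequence[SubjectRecord],
    results: Sequence[RmrsResult],
    round_dp: int | None = None,
) -> pd.DataFrame:
    """Tabulate records and their scoring results."""
    if len(records) != len(results):
        raise ValueError("records and results must align")
    rows = []
    for rec, res in zip(records, results):
        s = res.scaled
        row = {
            "id": rec.id,
            "glucose": rec.glucose,
            "sbp": rec.sbp,
            "dbp": rec.dbp,
            "triglycerides": rec.triglycerides,
            "hdl": rec.hdl,
            "waist": rec.waist,
            "sex": rec.sex,
            "region": rec.region,
            "age": rec.age,
            "race": rec.race,
            "s_gl": s.s_gl,
            "s_bp": s.s_bp,
            "s_tg": s.s_tg,
            "s_hdl": s.s_hdl,
            "s_wc": s.s_wc,
            "rmrs": res.rmrs,
            "risk_factor_count": res.risk_factor_count,
            "mets_by_count": res.diagnosis_by_count,
            "mets_by_rmrs": res.diagnosis_by_rmrs,
        }
        if round_dp is not None:
            for col in ("s_gl", "s_bp", "s_tg", "s_hdl", "s_wc", "rmrs"):
                row[col] = round(row[col], round_dp)
        rows.append(row)
    columns = [
        "id", "glucose", "sbp", "dbp", "triglycerides", "hdl", "waist",
        "sex", "region", "age", "race", *SCORE_COLUMNS,
    ]
    return pd.DataFrame(rows, columns=columns)


def write_scores(
    records: Sequence[SubjectRecord],
    results: Sequence[RmrsResult],
    path: str | Path,
    round_dp: int | None = None,
) -> None:
    """Write a scored cohort CSV with a deterministic column order."""
    scores_frame(records, results, round_dp=round_dp).to_csv(path, index=False)
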