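"""Core domain types, tabular I/O, validation and quality mapping.

The pipeline operates on long-format measurement tables: one row per
(subject, parameter, reader) read.  Values are stored in conventional
echocardiographic units (m/s for peak TRV, mm for linear dimensions,
cm^2 for areas, % for fractional area change) and are never converted
inside the statistics layer.  Missing reads are encoded by the *absence*
of a row, never by sentinel values, because relative-yield accounting
depends on correct missingness.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("echoagree")

#: Right-heart parameters handled by the pipeline.
PARAMETERS = (
    "TRV",
    "RV_basal_diameter",
    "TAPSE",
    "RA_area",
    "RVEDA",
    "RVESA",
    "RVFAC",
)

DEFAULT_UNITS = {
    "TRV": "m/s",
    "RV_basal_diameter": "mm",
    "TAPSE": "mm",
    "RA_area": "cm^2",
    "RVEDA": "cm^2",
    "RVESA": "cm^2",
    "RVFAC": "%",
}

COHORTS = ("case_control", "referral")
GROUPS = ("healthy", "PAH", "unknown")
SEXES = ("F", "M")
QUALITY_CATEGORIES = ("good", "moderate", "low")

MEASUREMENT_COLUMNS = [
    "subject_id",
    "cohort",
    "group",
    "parameter",
    "reader",
    "value",
    "units",
    "quality_score",
    "age_years",
    "sex",
]

HEMODYNAMICS_COLUMNS = ["subject_id", "mpap_mmhg", "days_echo_to_rhc"]

_KEY = ["subject_id", "parameter", "reader"]

# Fixed collapse of the 5-point Likert image-quality scale.
_QUALITY_MAP = {1: "low", 2: "low", 3: "moderate", 4: "good", 5: "good"}


class SchemaError(ValueError):
    """A required column is missing or the file layout is wrong."""


class ValidationError(ValueError):
    """A record violates a table invariant (strict mode)."""


def quality_category(score) -> str:
    """Collapse a 1-5 Likert image-quality score to good/moderate/low.

    Scores 4-5 are *good*, 3 is *moderate*, 1-2 are *low*.
    """
    s = float(score)
    if not s.is_integer() or int(s) not in _QUALITY_MAP:
        raise ValueError(f"quality score must be an integer in 1..5, got {score!r}")
    return _QUALITY_MAP[int(s)]


class MeasurementTable:
    """Long-format collection of reads with a per-parameter units registry.

    Wraps a :class:`pandas.DataFrame` with columns ``MEASUREMENT_COLUMNS``
    and enforces at most one record per (subject, parameter, reader).
    """

    def __init__(self, df: pd.DataFrame, units: dict | None = None, n_dropped: int = 0):
        missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"measurement table missing column(s): {missing}")
        df = df[MEASUREMENT_COLUMNS].reset_index(drop=True)
        dup = df.duplicated(_KEY)
        if dup.any():
            key = df.loc[dup, _KEY].iloc[0].tolist()
            raise ValidationError(f"duplicate read for (subject, parameter, reader) = {tuple(key)}")
        self.df = df
        if units is None:
            units = {}
            for p, sub in df.groupby("parameter", sort=True):
                vals = sub["units"].dropna()
                units[p] = str(vals.iloc[0]) if len(vals) else DEFAULT_UNITS.get(p, "")
        self.units = units
        self.n_dropped = int(n_dropped)

    @classmethod
    def from_records(cls, records: Iterable[Mapping]) -> "MeasurementTable":
        """Build a table from dicts, filling schema defaults for omitted fields."""
        rows = []
        for r in records:
            row = {
                "cohort": "case_control",
                "group": "unknown",
                "quality_score": np.nan,
                "age_years": np.nan,
                "sex": np.nan,
                **dict(r),
            }
            row.setdefault("units", DEFAULT_UNITS.get(row.get("parameter", ""), ""))
            rows.append(row)
        return cls(pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS))

    def __len__(self) -> int:
        return len(self.df)

    def parameters(self) -> list[str]:
        return sorted(self.df["parameter"].unique())

    def readers(self) -> list[str]:
        return sorted(self.df["reader"].unique())

    def subjects(self) -> list[str]:
        return sorted(self.df["subject_id"].unique())


def _validity_mask(df: pd.DataFrame) -> tuple[pd.Series, list[str]]:
    """Vectorized record validation; returns (keep mask, reason strings)."""
    ok = pd.Series(True, index=df.index)
    problems: list[str] = []

    def flag(bad: pd.Series, why: str) -> None:
        nonlocal ok
        bad = bad.fillna(False).astype(bool)
        if bad.any():
            problems.extend(f"row {i}: {why}" for i in df.index[bad][:5])
            ok &= ~bad

    flag(~df["parameter"].isin(PARAMETERS), "unknown parameter")
    flag(~df["cohort"].isin(COHORTS), "unknown cohort")
    flag(~df["group"].isin(GROUPS), "unknown group")
    flag(df["sex"].notna() & ~df["sex"].isin(SEXES), "unknown sex")
    value = pd.to_numeric(df["value"], errors="coerce")
    flag(value.isna() | (value <= 0), "missing or nonpositive value")
    flag((df["parameter"] == "RVFAC") & (value >= 100), "RVFAC outside (0, 100)")
    q = pd.to_numeric(df["quality_score"], errors="coerce")
    flag(df["quality_score"].notna() & ~q.isin([1, 2, 3, 4, 5]), "quality score outside 1..5")
    age = pd.to_numeric(df["age_years"], errors="coerce")
    flag(df["age_years"].notna() & (age < 18), "age below 18")
    return ok, problems


def read_measurement_table(path, strict: bool = False) -> MeasurementTable:
    """Read and validate a long-format measurement CSV.

    In strict mode any invariant violation raises :class:`ValidationError`;
    otherwise offending rows are dropped with a logged warning and the drop
    count is available as ``table.n_dropped``.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {missing}")
    df = df[MEASUREMENT_COLUMNS]
    ok, problems = _validity_mask(df)
    dup = df.duplicated(_KEY, keep="first")
    if strict:
        if dup.any():
            key = df.loc[dup, _KEY].iloc[0].tolist()
            raise ValidationError(
                f"{path}: duplicate read for (subject, parameter, reader) = {tuple(key)}"
            )
        if not ok.all():
            raise ValidationError(f"{path}: invalid record(s): " + "; ".join(problems[:5]))
    keep = ok & ~dup
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning(
            "read_measurement_table(%s): dropped %d invalid row(s): %s",
            path,
            n_dropped,
            "; ".join(problems[:5]) or "duplicate keys",
        )
    return MeasurementTable(df[keep], n_dropped=n_dropped)


def write_measurement_table(table: MeasurementTable, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.df.to_csv(path, index=False)
    return path


def read_hemodynamics_table(path) -> pd.DataFrame:
    """Read the per-subject right-heart-catheterization table."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in HEMODYNAMICS_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {missing}")
    df = df[HEMODYNAMICS_COLUMNS]
    if df["subject_id"].duplicated().any():
        sid = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate hemodynamics record for subject {sid!r}")
    mpap = pd.to_numeric(df["mpap_mmhg"], errors="coerce")
    if (mpap.isna() | (mpap <= 0)).any():
        raise ValidationError(f"{path}: MPAP must be a positive number for every subject")
    return df.reset_index(drop=True)


def write_hemodynamics_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df[HEMODYNAMICS_COLUMNS].to_csv(path, index=False)
    return path


def _sanitize(obj):
    if isinstance(obj, Mapping):
        return {str(k): _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_sanitize(v) for v in obj.tolist()]
    if isinstance(obj, Path):
        return str(obj)
    return obj


def write_summary_report(results: Iterable, path) -> tuple[Path, Path]:
    """Write stage outputs as machine-readable JSON plus a text summary.

    Re-running on identical inputs (and seeds) produces byte-identical JSON:
    keys are sorted and floats use their shortest round-trip representation.
    Returns (json_path, text_path).
    """
    results = list(results)
    if not results:
        raise ValueError("write_summary_report: no results to write")
    payload = []
    for r in results:
        if is_dataclass(r) and not isinstance(r, type):
            payload.append({"type": type(r).__name__, **asdict(r)})
        elif isinstance(r, Mapping):
            payload.append(dict(r))
        else:
            raise TypeError(f"unsupported result object: {type(r).__name__}")
    payload = _sanitize(payload)

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n")

    lines = []
    for item in payload:
        kind = item.get("type", "result")
        fields = ", ".join(f"{k}={item[k]!r}" for k in sorted(item) if k != "type")
        lines.append(f"{kind}: {fields}")
    txt_path = Path(str(path) + ".txt")
    txt_path.write_text("\n".join(lines) + "\n")
    logger.info("wrote summary report: %s (%d result(s))", path, len(payload))
    return path, txt_path


def load_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}
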