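"""Readers, writers and schema validation for the pipeline's table formats.

CSV dialect is fixed for determinism: UTF-8, comma separated, mandatory
header row, "." decimal separator, ISO-8601 local timestamps (no timezone
arithmetic).  Structural problems (missing columns, bad types, duplicate
primary keys, negative ratings) raise :class:`AdmarkValidationError` listing
every offender; airings outside the daily sampling window are filtered out
and counted rather than raised.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import STRATA, PopulationTable
from .nutrient_profiling import PROCESSING_CATEGORIES

KJ_PER_KCAL = 4.184

AIRINGS_COLUMNS = [
    "ad_id", "version_id", "timestamp", "duration_s", "channel", "program",
    "product_ids",
] + [f"rating_{s}" for s in STRATA]

NUTRITION_COLUMNS = [
    "product_id", "energy_kcal", "free_sugars_g", "total_fat_g",
    "saturated_fat_g", "trans_fat_g", "sodium_mg", "has_noncaloric_sweetener",
    "processing_category",
]


class AdmarkValidationError(ValueError):
    """Raised on structural schema violations; carries every problem found."""

    def __init__(self, problems: List[str]):
        self.problems = list(problems)
        super().__init__("validation failed:\n" + "\n".join(f"  - {p}" for p in problems))


@dataclass
class ReadReport:
    """Row-level bookkeeping from a reader."""

    n_rows_read: int = 0
    n_rejected_window: int = 0
    rejected_rows: List[int] = field(default_factory=list)


def _require_columns(df: pd.DataFrame, required: List[str], what: str) -> List[str]:
    missing = [c for c in required if c not in df.columns]
    return [f"{what}: missing column {c!r}" for c in missing]


def read_airings(
    path: str | Path,
    year: Optional[int] = None,
    window: Tuple[int, int] = (6, 22),
) -> Tuple[pd.DataFrame, ReadReport]:
    """Read and validate an airings CSV.

    Instances starting outside ``window`` (or, if ``year`` is given, outside
    the calendar year) are dropped and counted in the report.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    problems = _require_columns(df, AIRINGS_COLUMNS, "airings")
    if problems:
        raise AdmarkValidationError(problems)

    df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    for i, row in df.iterrows():
        if pd.isna(row["timestamp"]):
            problems.append(f"airings row {i}: unparseable timestamp")
        if not row["duration_s"] > 0:
            problems.append(f"airings row {i}: duration_s must be > 0")
    for col in [f"rating_{s}" for s in STRATA]:
        bad = df.index[df[col].isna() | (df[col] < 0)]
        problems.extend(f"airings row {i}: {col} must be a number >= 0" for i in bad)
    if problems:
        raise AdmarkValidationError(problems)

    df["product_ids"] = [
        [] if (isinstance(v, float) and np.isnan(v)) else str(v).split(";")
        for v in df["product_ids"]
    ]
    report = ReadReport(n_rows_read=len(df))
    start, end = window
    hours = df["timestamp"].dt.hour + df["timestamp"].dt.minute / 60.0 \
        + df["timestamp"].dt.second / 3600.0
    in_window = (hours >= start) & (hours < end)
    if year is not None:
        in_window &= df["timestamp"].dt.year == year
    report.rejected_rows = list(df.index[~in_window])
    report.n_rejected_window = len(report.rejected_rows)
    return df[in_window].reset_index(drop=True), report


def write_airings(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["product_ids"] = [";".join(pl) for pl in out["product_ids"]]
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_nutrition(path: str | Path) -> pd.DataFrame:
    """Read and validate a nutrition CSV.

    An optional ``energy_unit`` column ("kcal" or "kJ") is auto-detected;
    kJ energies are converted to kcal (4.184 kJ/kcal).  ``energy_kcal`` may
    be empty to signal a missing nutrition record; nutrient amounts, when
    present, must be >= 0.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    problems = _require_columns(df, NUTRITION_COLUMNS, "nutrition")
    if problems:
        raise AdmarkValidationError(problems)
    dup = df.loc[df["product_id"].duplicated(), "product_id"]
    problems.extend(f"nutrition: duplicate product_id {p!r}" for p in sorted(dup.unique()))

    if "energy_unit" in df.columns:
        unit = df["energy_unit"].fillna("kcal").str.lower()
        bad = sorted(set(unit) - {"kcal", "kj"})
        problems.extend(f"nutrition: unknown energy_unit {u!r}" for u in bad)
        if not bad:
            kj = unit == "kj"
            df.loc[kj, "energy_kcal"] = df.loc[kj, "energy_kcal"] / KJ_PER_KCAL
            df = df.drop(columns="energy_unit")

    nutrient_cols = ["free_sugars_g", "total_fat_g", "saturated_fat_g",
                     "trans_fat_g", "sodium_mg", "energy_kcal"]
    for col in nutrient_cols:
        bad = df.index[df[col].notna() & (df[col] < 0)]
        problems.extend(f"nutrition row {i}: {col} must be >= 0" for i in bad)
    has_record = df["energy_kcal"].notna()
    bad_cat = df.index[
        has_record & ~df["processing_category"].isin(PROCESSING_CATEGORIES)
    ]
    problems.extend(
        f"nutrition row {i}: unknown processing_category "
        f"{df.loc[i, 'processing_category']!r}" for i in bad_cat
    )
    if problems:
        raise AdmarkValidationError(problems)
    df["has_noncaloric_sweetener"] = df["has_noncaloric_sweetener"].fillna(False).astype(bool)
    if "available_for_purchase" in df.columns:
        df["available_for_purchase"] = df["available_for_purchase"].fillna(True).astype(bool)
    return df


def write_nutrition(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_codings(path: str | Path) -> pd.DataFrame:
    """Read and validate an appeal-codings CSV (ad_id, coder_id, flags...)."""
    df = pd.read_csv(path, float_precision="round_trip")
    problems = _require_columns(df, ["ad_id", "coder_id"], "codings")
    if problems:
        raise AdmarkValidationError(problems)
    dup = df.loc[df.duplicated(subset=["ad_id", "coder_id"]), ["ad_id", "coder_id"]]
    problems.extend(
        f"codings: duplicate (ad_id, coder_id) = ({r.ad_id!r}, {r.coder_id!r})"
        for r in dup.itertuples()
    )
    flag_cols = [c for c in df.columns if c not in ("ad_id", "coder_id")]
    for col in flag_cols:
        bad = df.index[~df[col].isin([0, 1])]
        problems.extend(f"codings row {i}: {col} must be 0 or 1" for i in bad)
    if problems:
        raise AdmarkValidationError(problems)
    df[flag_cols] = df[flag_cols].astype(int)
    return df


def write_codings(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_populations(path: str | Path) -> PopulationTable:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return PopulationTable(**payload)


def write_populations(populations: PopulationTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(populations.as_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Bundle serialisation (deterministic)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        df = obj
        if "product_ids" in df.columns:
            df = df.copy()
            df["product_ids"] = [";".join(pl) for pl in df["product_ids"]]
        return df.to_dict(orient="records")
    if hasattr(obj, "as_dict"):
        return _jsonable(obj.as_dict())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and (np.isnan(obj) or np.isinf(obj)):
        return None if np.isnan(obj) else ("inf" if obj > 0 else "-inf")
    return obj


def bundle_to_json(bundle: Dict) -> str:
    """Serialise an analysis bundle to a deterministic JSON string."""

    def default(o):
        jo = _jsonable(o)
        if jo is o:
            return str(o)
        return jo

    return json.dumps(_jsonable(bundle), sort_keys=True, indent=2,
                      allow_nan=True, default=default)


def write_bundle(bundle: Dict, out_dir: str | Path) -> None:
    """Write results.json, per-table CSV files and a run log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = out / "tables"
    tables.mkdir(exist_ok=True)
    log_lines = []
    slim = {}
    for key, val in bundle.items():
        if isinstance(val, pd.DataFrame):
            df = val
            if "product_ids" in df.columns:
                df = df.copy()
                df["product_ids"] = [";".join(pl) for pl in df["product_ids"]]
            df.to_csv(tables / f"{key}.csv", index=False)
            log_lines.append(f"wrote tables/{key}.csv ({len(df)} rows)")
        else:
            slim[key] = val
            log_lines.append(f"recorded {key} in results.json")
    (out / "results.json").write_text(bundle_to_json(slim) + "\n", encoding="utf-8")
    (out / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
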