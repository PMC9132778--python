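"""Readers and writers for the flat-file formats the pipeline exchanges.

All tables are UTF-8 CSV.  A response table has one row per submitted
questionnaire: the facility metadata columns below plus one column per
indicator holding the chosen option label (empty cell = unanswered).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

RESPONSE_META_COLUMNS = [
    "response_id",
    "facility_name",
    "country_code",
    "who_region",
    "income_level",
    "facility_type",
    "facility_level",
    "latitude",
    "longitude",
    "submitted_at",
    "nationally_coordinated",
    "wave_label",
]

COUNTRY_COLUMNS = ["country_code", "name", "population", "who_region", "income_level"]

INCOME_LEVELS = ("low", "lower_middle", "upper_middle", "high")
WHO_REGIONS = (
    "africa",
    "americas",
    "eastern_mediterranean",
    "europe",
    "south_east_asia",
    "western_pacific",
)
FACILITY_TYPES = ("public", "private", "other")
FACILITY_LEVELS = ("primary", "secondary", "tertiary", "other")


def read_responses(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"response_id": str, "country_code": str})
    missing = [c for c in RESPONSE_META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"response table missing columns: {missing}")
    df["submitted_at"] = pd.to_datetime(df["submitted_at"])
    df["nationally_coordinated"] = df["nationally_coordinated"].astype(bool)
    bad_lat = df["latitude"].notna() & ~df["latitude"].between(-90, 90)
    bad_lon = df["longitude"].notna() & ~df["longitude"].between(-180, 180)
    if bad_lat.any() or bad_lon.any():
        raise ValueError("coordinates outside valid latitude/longitude ranges")
    return df


def write_responses(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_country_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"country_code": str})
    missing = [c for c in COUNTRY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"country table missing columns: {missing}")
    return df


def read_margins(path: str | Path) -> pd.DataFrame:
    """Raking margins: columns variable, category, target_proportion."""
    df = pd.read_csv(path, dtype={"variable": str, "category": str})
    need = {"variable", "category", "target_proportion"}
    if not need.issubset(df.columns):
        raise ValueError(f"margins table must have columns {sorted(need)}")
    return df


def write_margins(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
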