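"""Density-record tables: schema and delimited-text I/O.

A density record is one site-level estimate of population density
(animals/km^2) at a planar location, flagged island or mainland and
tagged by region (``native``, ``non-native``, or ``background``).
Records are carried as pandas DataFrames with the columns below;
``site_key`` groups repeated estimates of the same area.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

RECORD_COLUMNS = ["id", "x", "y", "density", "is_island", "region", "site_key"]

REGIONS = ("native", "non-native", "background")


class DataError(ValueError):
    """Raised for malformed or inconsistent record tables."""


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Check schema and invariants; returns the table unchanged."""
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise DataError(f"record table missing columns: {missing}")
    if (records["density"] < 0).any():
        raise DataError("density must be >= 0")
    bad_region = set(records["region"]) - set(REGIONS)
    if bad_region:
        raise DataError(f"unknown region tags: {sorted(bad_region)}")
    bg = records[records["region"] == "background"]
    if len(bg) and (bg["density"] != 0).any():
        raise DataError("background records must have density exactly 0")
    return records


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    validate_records(records)
    records.to_csv(path, sep="\t", index=False)


def read_records(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "site_key": str})
    df["is_island"] = df["is_island"].astype(bool)
    return validate_records(df)
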