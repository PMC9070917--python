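"""Reading and validation of taxi-trip records, zone boundaries and case counts.

Trip tables are handled as pandas DataFrames with a canonical column set
(:data:`TRIP_COLUMNS`); the CSV layout of a particular source is described by a
:class:`TripDialect`, with a shipped default matching the Chicago Data Portal
"Taxi Trips" export headers.  Community-area boundaries are read from GeoJSON
(one feature per area, shapely geometries).
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
from shapely.geometry import shape
from shapely.geometry.base import BaseGeometry

#: Canonical column order of an in-memory trip table.
TRIP_COLUMNS = [
    "trip_id",
    "pickup_time",
    "dropoff_time",
    "pickup_area",
    "dropoff_area",
    "trip_miles",
    "trip_seconds",
]

N_COMMUNITY_AREAS = 77


class TripSchemaError(ValueError):
    """A mandatory column is missing from a trip CSV."""


@dataclass(frozen=True)
class TripDialect:
    """Column names (and timestamp format) of a trip CSV source.

    ``timestamp_format`` of ``None`` lets pandas infer the format (ISO input);
    the default is the Chicago portal's ``03/11/2020 07:15:00 PM`` style.
    """

    trip_id: str = "Trip ID"
    pickup_time: str = "Trip Start Timestamp"
    dropoff_time: str = "Trip End Timestamp"
    pickup_area: str = "Pickup Community Area"
    dropoff_area: str = "Dropoff Community Area"
    trip_miles: str = "Trip Miles"
    trip_seconds: str = "Trip Seconds"
    timestamp_format: str | None = "%m/%d/%Y %I:%M:%S %p"

    def column_map(self) -> dict[str, str]:
        return {
            self.trip_id: "trip_id",
            self.pickup_time: "pickup_time",
            self.dropoff_time: "dropoff_time",
            self.pickup_area: "pickup_area",
            self.dropoff_area: "dropoff_area",
            self.trip_miles: "trip_miles",
            self.trip_seconds: "trip_seconds",
        }


#: Default dialect: Chicago Data Portal "Taxi Trips" export.
CHICAGO_PORTAL = TripDialect()

#: Dialect used for files this package writes itself (ISO timestamps).
CANONICAL = TripDialect(
    trip_id="trip_id",
    pickup_time="pickup_time",
    dropoff_time="dropoff_time",
    pickup_area="pickup_area",
    dropoff_area="dropoff_area",
    trip_miles="trip_miles",
    trip_seconds="trip_seconds",
    timestamp_format=None,
)


@dataclass
class IngestReport:
    """Row accounting for one :func:`read_trips` call."""

    total: int
    kept: int
    dropped: int
    missing_pickup_area: int
    missing_dropoff_area: int

    def as_dict(self) -> dict[str, int]:
        return {
            "total": self.total,
            "kept": self.kept,
            "dropped": self.dropped,
            "missing_pickup_area": self.missing_pickup_area,
            "missing_dropoff_area": self.missing_dropoff_area,
        }


@dataclass(frozen=True)
class CommunityArea:
    """One of the city's official zones: integer code, name and polygon."""

    code: int
    name: str
    geometry: BaseGeometry


def _parse_times(raw: pd.Series, fmt: str | None) -> pd.Series:
    if fmt is None:
        return pd.to_datetime(raw, errors="coerce")
    return pd.to_datetime(raw, format=fmt, errors="coerce")


def read_trips(
    path: str | Path, dialect: TripDialect = CHICAGO_PORTAL
) -> tuple[pd.DataFrame, IngestReport]:
    """Read a trip CSV into the canonical trip table.

    Rows whose pickup timestamp is absent or unparseable, or whose dropoff
    timestamp is present but unparseable, are dropped and counted in the
    report.  Missing community-area codes are retained as ``<NA>`` — the
    network builder decides what to do with them — as are area codes outside
    1..77 after being nulled.  Timestamps are treated as local civil time;
    daily aggregation only needs calendar dates, so no timezone arithmetic is
    performed.

    Returns the table and an :class:`IngestReport`.  Raises
    :class:`FileNotFoundError` for a missing file and
    :class:`TripSchemaError` naming the first missing mandatory column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trip file not found: {path}")
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    for src in dialect.column_map():
        if src not in raw.columns:
            raise TripSchemaError(f"mandatory column missing from {path.name}: {src!r}")
    df = raw.rename(columns=dialect.column_map())[TRIP_COLUMNS].copy()
    total = len(df)

    pickup_raw = df["pickup_time"].str.strip()
    dropoff_raw = df["dropoff_time"].str.strip()
    df["pickup_time"] = _parse_times(pickup_raw, dialect.timestamp_format)
    df["dropoff_time"] = _parse_times(dropoff_raw, dialect.timestamp_format)
    bad_pickup = df["pickup_time"].isna()
    bad_dropoff = (dropoff_raw != "") & df["dropoff_time"].isna()
    keep = ~(bad_pickup | bad_dropoff)
    df = df.loc[keep].reset_index(drop=True)

    for col in ("pickup_area", "dropoff_area"):
        codes = pd.to_numeric(df[col], errors="coerce").astype("Int64")
        codes[(codes < 1) | (codes > N_COMMUNITY_AREAS)] = pd.NA
        df[col] = codes
    df["trip_miles"] = pd.to_numeric(df["trip_miles"], errors="coerce").astype(float)
    df["trip_seconds"] = pd.to_numeric(df["trip_seconds"], errors="coerce").astype("Int64")

    report = IngestReport(
        total=total,
        kept=len(df),
        dropped=total - len(df),
        missing_pickup_area=int(df["pickup_area"].isna().sum()),
        missing_dropoff_area=int(df["dropoff_area"].isna().sum()),
    )
    return df, report


def write_trips(
    trips: pd.DataFrame, path: str | Path, dialect: TripDialect = CANONICAL
) -> None:
    """Write a canonical trip table as CSV in the given dialect."""
    out = trips.copy()
    fmt = dialect.timestamp_format or "%Y-%m-%d %H:%M:%S"
    for col in ("pickup_time", "dropoff_time"):
        out[col] = out[col].dt.strftime(fmt)
    inverse = {v: k for k, v in dialect.column_map().items()}
    out.rename(columns=inverse).to_csv(path, index=False)


def filter_window(trips: pd.DataFrame, start: dt.date, end: dt.date) -> pd.DataFrame:
    """Keep trips whose pickup date lies in ``[start, end]`` inclusive.

    Row order is preserved.  Raises :class:`ValueError` if ``start > end``.
    """
    if start > end:
        raise ValueError(f"window start {start} is after end {end}")
    days = trips["pickup_time"].dt.date
    return trips.loc[(days >= start) & (days <= end)].reset_index(drop=True)


_CODE_KEYS = ("area_numbe", "area_num_1", "area_number", "code", "area")
_NAME_KEYS = ("community", "name", "pri_neigh")


def read_boundaries(
    path: str | Path,
    code_key: str | None = None,
    name_key: str | None = None,
) -> list[CommunityArea]:
    """Read community-area polygons from a GeoJSON FeatureCollection.

    The feature property holding the area code is auto-detected among the
    keys the city portal uses (``area_numbe`` et al.) unless given explicitly.
    Codes must be unique.  Shapefile input is not supported; convert to
    GeoJSON first.
    """
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path.name}: expected a GeoJSON FeatureCollection")
    features = doc.get("features", [])
    areas: list[CommunityArea] = []
    for feat in features:
        props = feat.get("properties", {}) or {}
        ck = code_key or next((k for k in _CODE_KEYS if k in props), None)
        if ck is None or props.get(ck) in (None, ""):
            raise ValueError(f"{path.name}: feature without a recognizable area code")
        nk = name_key or next((k for k in _NAME_KEYS if k in props), None)
        areas.append(
            CommunityArea(
                code=int(props[ck]),
                name=str(props.get(nk, "")) if nk else "",
                geometry=shape(feat["geometry"]),
            )
        )
    codes = [a.code for a in areas]
    if len(set(codes)) != len(codes):
        dupes = sorted({c for c in codes if codes.count(c) > 1})
        raise ValueError(f"duplicate area codes in {path.name}: {dupes}")
    return sorted(areas, key=lambda a: a.code)


def read_cases(
    path: str | Path,
    area_col: str = "area_key",
    week_col: str = "week_start",
    cases_col: str = "cases",
    deaths_col: str = "deaths",
) -> pd.DataFrame:
    """Read weekly COVID case/death counts per area key (zip or area code).

    Counts are coerced to non-negative integers; negative entries are an
    error.  ``deaths <= cases`` is deliberately not enforced (cumulative
    conventions vary between sources).
    """
    df = pd.read_csv(path)
    for col in (area_col, week_col, cases_col, deaths_col):
        if col not in df.columns:
            raise TripSchemaError(f"mandatory column missing: {col!r}")
    out = pd.DataFrame(
        {
            "area_key": df[area_col].astype(str),
            "week_start": pd.to_datetime(df[week_col]).dt.date,
            "cases": pd.to_numeric(df[cases_col]).astype(int),
            "deaths": pd.to_numeric(df[deaths_col]).astype(int),
        }
    )
    if (out["cases"] < 0).any() or (out["deaths"] < 0).any():
        raise ValueError("negative case or death counts")
    return out


def empty_trip_table() -> pd.DataFrame:
    """An empty trip table with the canonical columns and dtypes."""
    return pd.DataFrame(
        {
            "trip_id": pd.Series(dtype=str),
            "pickup_time": pd.Series(dtype="datetime64[ns]"),
            "dropoff_time": pd.Series(dtype="datetime64[ns]"),
            "pickup_area": pd.Series(dtype="Int64"),
            "dropoff_area": pd.Series(dtype="Int64"),
            "trip_miles": pd.Series(dtype=float),
            "trip_seconds": pd.Series(dtype="Int64"),
        }
    )
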