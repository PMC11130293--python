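"""Spatial/administrative data model and tabular I/O.

All artifacts are UTF-8 CSV with a header row; dates are ISO-8601
(YYYY-MM-DD) and XDR timestamps ISO-8601, interpreted in a single study
timezone. Registries are plain :class:`pandas.DataFrame` objects with the
column schemas below; quarantine calendars get a small wrapper class that
canonicalises overlapping intervals.

CSV schemas
-----------
antennas.csv    antenna_id, lat, lon, comuna_id
comunas.csv     comuna_id, region_id, name, population, area_km2,
                income_decile, poverty_rate, rural_fraction, icvu,
                centroid_lat, centroid_lon
regions.csv     region_id, name, population, distance_to_origin_km
quarantine.csv  comuna_id, start_date, end_date      (half-open [start, end))
xdr.csv         device_id, timestamp, antenna_id
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

ANTENNA_COLUMNS = ["antenna_id", "lat", "lon", "comuna_id"]
COMUNA_COLUMNS = [
    "comuna_id", "region_id", "name", "population", "area_km2",
    "income_decile", "poverty_rate", "rural_fraction", "icvu",
    "centroid_lat", "centroid_lon",
]
REGION_COLUMNS = ["region_id", "name", "population", "distance_to_origin_km"]
QUARANTINE_COLUMNS = ["comuna_id", "start_date", "end_date"]
XDR_COLUMNS = ["device_id", "timestamp", "antenna_id"]


def _require_columns(frame: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}")


def _row(i: int) -> str:
    # 1-based data-row number, matching what a user sees below the CSV header
    return f"data row {i + 1}"


# ---------------------------------------------------------------------------
# antennas

def validate_antennas(antennas: pd.DataFrame) -> pd.DataFrame:
    _require_columns(antennas, ANTENNA_COLUMNS, "antenna registry")
    antennas = antennas.reset_index(drop=True)
    dup = antennas["antenna_id"][antennas["antenna_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(
            f"duplicate antenna_id(s): {sorted(dup.astype(str).unique())}")
    bad_lat = antennas.index[~antennas["lat"].between(-90, 90)]
    if len(bad_lat):
        i = int(bad_lat[0])
        raise ValidationError(
            f"latitude {antennas.at[i, 'lat']} out of [-90, 90] at {_row(i)}")
    bad_lon = antennas.index[~antennas["lon"].between(-180, 180)]
    if len(bad_lon):
        i = int(bad_lon[0])
        raise ValidationError(
            f"longitude {antennas.at[i, 'lon']} out of [-180, 180] at {_row(i)}")
    return antennas


def read_antennas(path) -> pd.DataFrame:
    """Read and validate an antenna registry CSV."""
    return validate_antennas(pd.read_csv(path, dtype={"antenna_id": str, "comuna_id": str}))


def write_antennas(antennas: pd.DataFrame, path) -> None:
    antennas[ANTENNA_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# comunas

def validate_comunas(comunas: pd.DataFrame,
                     regions: pd.DataFrame | None = None) -> pd.DataFrame:
    required = [c for c in COMUNA_COLUMNS if c != "icvu"]
    _require_columns(comunas, required, "comuna registry")
    comunas = comunas.reset_index(drop=True)
    if "icvu" not in comunas.columns:
        comunas["icvu"] = np.nan  # index covers urban comunas only; absent is legal
    dup = comunas["comuna_id"][comunas["comuna_id"].duplicated()]
    if not dup.empty:
        raise ValidationError(f"duplicate comuna_id(s): {sorted(dup.astype(str).unique())}")
    bad = comunas.index[comunas["population"] < 1]
    if len(bad):
        i = int(bad[0])
        raise ValidationError(f"population must be >= 1 at {_row(i)}")
    bad = comunas.index[comunas["area_km2"] <= 0]
    if len(bad):
        i = int(bad[0])
        raise ValidationError(f"area_km2 must be > 0 at {_row(i)}")
    for col in ("poverty_rate", "rural_fraction"):
        bad = comunas.index[~comunas[col].between(0, 1)]
        if len(bad):
            i = int(bad[0])
            raise ValidationError(f"{col} out of [0, 1] at {_row(i)}")
    if regions is not None:
        unknown = set(comunas["region_id"]) - set(regions["region_id"])
        if unknown:
            raise ValidationError(f"unknown region_id(s): {sorted(map(str, unknown))}")
    comunas["density"] = comunas["population"] / comunas["area_km2"]
    return comunas


def read_comunas(path, regions: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read and validate a comuna attribute table; attaches persons/km2 density."""
    try:
        frame = pd.read_csv(path, dtype={"comuna_id": str, "region_id": str})
    except pd.errors.EmptyDataError:
        logger.warning("comuna registry %s is empty", path)
        frame = pd.DataFrame(columns=COMUNA_COLUMNS)
    if frame.empty:
        logger.warning("comuna registry %s has no rows", path)
        frame = frame.reindex(columns=COMUNA_COLUMNS)
        frame["density"] = pd.Series(dtype=float)
        return frame
    return validate_comunas(frame, regions)


def write_comunas(comunas: pd.DataFrame, path) -> None:
    comunas[COMUNA_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# regions

def validate_regions(regions: pd.DataFrame) -> pd.DataFrame:
    _require_columns(regions, REGION_COLUMNS, "region registry")
    regions = regions.reset_index(drop=True)
    bad = regions.index[regions["population"] < 1]
    if len(bad):
        raise ValidationError(f"region population must be >= 1 at {_row(int(bad[0]))}")
    bad = regions.index[regions["distance_to_origin_km"] < 0]
    if len(bad):
        raise ValidationError(f"negative distance_to_origin_km at {_row(int(bad[0]))}")
    zero = regions.index[regions["distance_to_origin_km"] == 0]
    if len(zero) > 1:
        raise ValidationError(
            "distance_to_origin_km may be 0 only for the focal region itself")
    return regions


def read_regions(path) -> pd.DataFrame:
    return validate_regions(pd.read_csv(path, dtype={"region_id": str}))


def write_regions(regions: pd.DataFrame, path) -> None:
    regions[REGION_COLUMNS].to_csv(path, index=False)


def focal_region_id(regions: pd.DataFrame) -> str:
    """The focal (origin) region: the one at distance zero."""
    zero = regions.loc[regions["distance_to_origin_km"] == 0, "region_id"]
    if zero.empty:
        raise ValidationError("no region with distance_to_origin_km == 0")
    return str(zero.iloc[0])


def check_referential_integrity(antennas: pd.DataFrame, comunas: pd.DataFrame,
                                regions: pd.DataFrame) -> None:
    """Raise unless every antenna's comuna and every comuna's region resolve."""
    orphans = set(antennas["comuna_id"]) - set(comunas["comuna_id"])
    if orphans:
        raise ValidationError(
            f"antenna comuna_id(s) not in comuna registry: {sorted(map(str, orphans))}")
    orphans = set(comunas["region_id"]) - set(regions["region_id"])
    if orphans:
        raise ValidationError(
            f"comuna region_id(s) not in region registry: {sorted(map(str, orphans))}")


# ---------------------------------------------------------------------------
# quarantine calendar

@dataclass(frozen=True)
class QuarantineCalendar:
    """Per-comuna quarantine periods as merged half-open [start, end) date intervals."""

    intervals: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=QUARANTINE_COLUMNS))

    @classmethod
    def from_intervals(cls, intervals: pd.DataFrame) -> "QuarantineCalendar":
        """Canonicalise raw (comuna_id, start_date, end_date) rows.

        Overlapping or touching intervals of the same comuna are merged;
        a start >= end raises.
        """
        _require_columns(intervals, QUARANTINE_COLUMNS, "quarantine calendar")
        iv = intervals.copy()
        iv["start_date"] = pd.to_datetime(iv["start_date"]).dt.normalize()
        iv["end_date"] = pd.to_datetime(iv["end_date"]).dt.normalize()
        if (iv["start_date"] >= iv["end_date"]).any():
            raise ValidationError("quarantine interval with start_date >= end_date")
        merged = []
        for comuna, grp in iv.sort_values(["comuna_id", "start_date"]).groupby(
                "comuna_id", sort=True):
            cur_s = cur_e = None
            for s, e in zip(grp["start_date"], grp["end_date"]):
                if cur_s is None:
                    cur_s, cur_e = s, e
                elif s <= cur_e:  # overlap or touch: merge
                    cur_e = max(cur_e, e)
                else:
                    merged.append((comuna, cur_s, cur_e))
                    cur_s, cur_e = s, e
            merged.append((comuna, cur_s, cur_e))
        out = pd.DataFrame(merged, columns=QUARANTINE_COLUMNS)
        return cls(out)

    def is_in_quarantine(self, comuna_id: str, date) -> bool:
        """True iff *date* falls inside a (merged) interval of *comuna_id*."""
        d = pd.Timestamp(date).normalize()
        grp = self.intervals[self.intervals["comuna_id"] == comuna_id]
        if grp.empty:
            logger.warning("comuna %s has no quarantine intervals on record", comuna_id)
            return False
        return bool(((grp["start_date"] <= d) & (d < grp["end_date"])).any())

    def mask(self, comuna_ids: pd.Series, dates: pd.Series) -> np.ndarray:
        """Vectorised membership test for parallel (comuna, date) pairs."""
        dates = pd.to_datetime(pd.Series(dates).reset_index(drop=True)).dt.normalize()
        comuna_ids = pd.Series(comuna_ids).reset_index(drop=True).astype(str)
        out = np.zeros(len(dates), dtype=bool)
        for comuna, grp in self.intervals.groupby("comuna_id"):
            sel = (comuna_ids == comuna).to_numpy()
            if not sel.any():
                continue
            starts = grp["start_date"].to_numpy()
            ends = grp["end_date"].to_numpy()
            d = dates.to_numpy()[sel]
            hit = np.zeros(len(d), dtype=bool)
            for s, e in zip(starts, ends):
                hit |= (d >= s) & (d < e)
            out[sel] = hit
        return out


def read_quarantine(path) -> QuarantineCalendar:
    try:
        frame = pd.read_csv(path, dtype={"comuna_id": str})
    except pd.errors.EmptyDataError:
        logger.warning("quarantine calendar %s is empty", path)
        return QuarantineCalendar()
    if frame.empty:
        return QuarantineCalendar()
    return QuarantineCalendar.from_intervals(frame)


def write_quarantine(calendar: QuarantineCalendar, path) -> None:
    iv = calendar.intervals.copy()
    for col in ("start_date", "end_date"):
        iv[col] = pd.to_datetime(iv[col]).dt.date
    iv.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# XDR streams

def read_xdr(path, tz: str | None = None) -> pd.DataFrame:
    """Read an XDR event table.

    Timestamps are parsed as written; when *tz* is given, offset-aware
    timestamps are converted to that study timezone and returned naive.
    Device and antenna ids come back as categoricals (the streams are long,
    the alphabets small).
    """
    frame = pd.read_csv(path, dtype={"device_id": "category", "antenna_id": "category"})
    _require_columns(frame, XDR_COLUMNS, "xdr stream")
    ts = pd.to_datetime(frame["timestamp"], format="ISO8601")
    if ts.dt.tz is not None:
        if tz is not None:
            ts = ts.dt.tz_convert(tz)
        ts = ts.dt.tz_localize(None)
    frame["timestamp"] = ts
    return frame


def write_xdr(events: pd.DataFrame, path) -> None:
    out = events[XDR_COLUMNS].copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)
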