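"""Weekly home-location detection from XDR events.

A device's home antenna for a week is its most used antenna during
night-time on weekdays; its home comuna is that antenna's comuna. Weeks with
no qualifying ping are absent (no row), and absence at the baseline week
excludes the device downstream.

Conventions (the underlying night-tower heuristic fixes none of these):

* night window 22:00-06:00 study-local; a ping before 06:00 is attributed
  to the previous evening's date, so 01:00 Saturday counts as Friday night;
* weekdays are Monday-Friday of the attributed evening;
* ties are broken toward the lexicographically smallest antenna_id;
* weeks are Monday-start calendar weeks indexed from the study start
  (see :mod:`migflow.weeks`).
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

from . import weeks
from .errors import ValidationError

NIGHT_WINDOW = (22, 6)
WEEKDAYS = (0, 1, 2, 3, 4)  # Monday..Friday

__all__ = ["NIGHT_WINDOW", "WEEKDAYS", "night_attribution", "weekly_homes",
           "weekly_home", "baseline_homes", "baseline_home"]


def night_attribution(timestamps: pd.Series,
                      night_window: tuple[int, int] = NIGHT_WINDOW,
                      weekdays: tuple[int, ...] = WEEKDAYS
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Qualify events as weekday-night pings.

    Returns ``(mask, evening_date)``: which events fall in the night window
    on a qualifying weekday, and the evening date each night span is
    attributed to (for windows spanning midnight, early-morning hours belong
    to the previous evening).
    """
    ts = pd.to_datetime(timestamps)
    hour = ts.dt.hour.to_numpy()
    start, end = night_window
    date = ts.dt.normalize().to_numpy()
    if start > end:  # spans midnight
        in_night = (hour >= start) | (hour < end)
        evening = np.where(hour < end, date - np.timedelta64(1, "D"), date)
    else:
        in_night = (hour >= start) & (hour < end)
        evening = date
    dow = pd.DatetimeIndex(evening).dayofweek.to_numpy()
    mask = in_night & np.isin(dow, list(weekdays))
    return mask, evening


def weekly_homes(events: pd.DataFrame, antennas: pd.DataFrame,
                 study_start: dt.date, study_end: dt.date,
                 night_window: tuple[int, int] = NIGHT_WINDOW,
                 weekdays: tuple[int, ...] = WEEKDAYS,
                 min_weeks: int = 1) -> pd.DataFrame:
    """Per-device weekly home comunas for every device in *events*.

    Returns a long table (device_id, week_index, home_comuna_id) containing
    only the (device, week) pairs with at least one qualifying ping; missing
    pairs are absent weeks. Devices assigned in fewer than *min_weeks* weeks
    are dropped entirely.
    """
    dev_codes, dev_cats = pd.factorize(events["device_id"], sort=True)
    ant_cats = pd.Index(antennas["antenna_id"])
    ant_codes = ant_cats.get_indexer(pd.Index(events["antenna_id"]))
    if (ant_codes < 0).any():
        unknown = sorted(pd.Index(events["antenna_id"])[ant_codes < 0]
                         .astype(str).unique())
        raise ValidationError(f"events reference unknown antenna id(s): {unknown}")

    mask, evening = night_attribution(events["timestamp"], night_window, weekdays)
    wk = weeks.week_index(evening, study_start)
    n_weeks = weeks.n_study_weeks(study_start, study_end)
    mask &= (wk >= 0) & (wk < n_weeks)

    counts = pd.DataFrame({
        "dev": dev_codes[mask], "week": wk[mask], "ant": ant_codes[mask],
    }).groupby(["dev", "week", "ant"], sort=False).size().reset_index(name="n")

    # lexicographic antenna rank for deterministic tie-breaking
    lex_rank = np.empty(len(ant_cats), dtype=np.int64)
    lex_rank[np.argsort(ant_cats.to_numpy().astype(str))] = np.arange(len(ant_cats))
    counts["rank"] = lex_rank[counts["ant"]]
    counts = counts.sort_values(["dev", "week", "n", "rank"],
                                ascending=[True, True, False, True])
    top = counts.drop_duplicates(["dev", "week"], keep="first")

    comuna_of_ant = antennas.set_index("antenna_id")["comuna_id"]
    out = pd.DataFrame({
        "device_id": dev_cats.take(top["dev"].to_numpy()),
        "week_index": top["week"].to_numpy(),
        "home_comuna_id": comuna_of_ant.to_numpy()[top["ant"].to_numpy()],
    }).sort_values(["device_id", "week_index"], ignore_index=True)

    if min_weeks > 1:
        ok = out.groupby("device_id")["week_index"].transform("size") >= min_weeks
        out = out[ok].reset_index(drop=True)
    return out


def weekly_home(events: pd.DataFrame, antennas: pd.DataFrame,
                study_start: dt.date, study_end: dt.date,
                night_window: tuple[int, int] = NIGHT_WINDOW,
                weekdays: tuple[int, ...] = WEEKDAYS) -> pd.Series:
    """Home series of a single device: week_index -> home_comuna_id.

    Absent weeks are simply missing from the index.
    """
    if events["device_id"].nunique() > 1:
        raise ValueError("weekly_home expects events of a single device")
    table = weekly_homes(events, antennas, study_start, study_end,
                         night_window, weekdays)
    return table.set_index("week_index")["home_comuna_id"]


def baseline_homes(homes: pd.DataFrame, baseline_week: int,
                   comunas: pd.DataFrame,
                   n_weeks: int | None = None) -> pd.DataFrame:
    """Baseline home comuna and region per device.

    Devices absent at the baseline week are excluded (no row). Raises if
    *baseline_week* lies outside the study window (when *n_weeks* given).
    """
    if n_weeks is not None and not (0 <= baseline_week < n_weeks):
        raise ValueError(f"baseline week {baseline_week} outside study window "
                         f"of {n_weeks} weeks")
    base = homes.loc[homes["week_index"] == baseline_week,
                     ["device_id", "home_comuna_id"]].copy()
    region_of = comunas.set_index("comuna_id")["region_id"]
    base["region_id"] = region_of.reindex(base["home_comuna_id"]).to_numpy()
    return base.reset_index(drop=True)


def baseline_home(series: pd.Series, baseline_week: int,
                  comunas: pd.DataFrame,
                  n_weeks: int | None = None) -> tuple[str, str] | None:
    """Baseline (comuna, region) of a single-device home series, or None if absent."""
    if n_weeks is not None and not (0 <= baseline_week < n_weeks):
        raise ValueError(f"baseline week {baseline_week} outside study window")
    if baseline_week not in series.index:
        return None
    comuna = series.loc[baseline_week]
    region = comunas.set_index("comuna_id")["region_id"].loc[comuna]
    return str(comuna), str(region)
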