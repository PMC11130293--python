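"""Daily mobility indices per comuna and their reduction vs the baseline week.

A movement is any transition between two different antennas in a device's
time-ordered event stream. Transitions are internal when both antennas sit
in the same comuna, external otherwise, and are attributed to the calendar
date of the second event (so a span across midnight belongs to the morning).

The per-comuna index for a day is the mean number of transitions per active
homed device: transitions of all devices homed in the comuna at the
baseline week, divided by the number of those devices with any event that
day. Home attribution uses the baseline home, so long-term migrants keep
contributing to their origin comuna's stratum; weekly attribution can be
had by passing a different homes table. Raw daily totals are available via
``normalize=False``.
"""

from __future__ import annotations

import datetime as dt
import logging
import warnings

import numpy as np
import pandas as pd

from . import weeks
from .errors import ValidationError
from .geography import QuarantineCalendar

logger = logging.getLogger(__name__)

__all__ = ["count_transitions", "daily_active", "mobility_index",
           "reduction_vs_baseline", "stratify_by_quarantine",
           "quarantine_summary", "compute_mobility"]


def count_transitions(events: pd.DataFrame,
                      antennas: pd.DataFrame) -> pd.DataFrame:
    """Antenna transitions per device from a (sortable) event stream.

    Returns one row per consecutive event pair at different antennas:
    device_id, timestamp (second event), date, from_comuna, to_comuna,
    internal (same-comuna flag). Consecutive events at one antenna emit
    nothing; devices with a single event yield no rows.
    """
    ant_idx = pd.Index(antennas["antenna_id"])
    ant_codes = ant_idx.get_indexer(pd.Index(events["antenna_id"]))
    if (ant_codes < 0).any():
        unknown = sorted(pd.Index(events["antenna_id"])[ant_codes < 0]
                         .astype(str).unique())
        raise ValidationError(f"events reference unknown antenna id(s): {unknown}")
    dev_codes, dev_cats = pd.factorize(events["device_id"], sort=True)
    ts = pd.to_datetime(events["timestamp"]).to_numpy()

    order = np.lexsort((ts, dev_codes))
    dev_s, ts_s, ant_s = dev_codes[order], ts[order], ant_codes[order]
    same_dev = dev_s[1:] == dev_s[:-1]
    changed = ant_s[1:] != ant_s[:-1]
    tr = same_dev & changed

    comuna_of = pd.Categorical(antennas["comuna_id"])
    from_c = comuna_of.codes[ant_s[:-1][tr]]
    to_c = comuna_of.codes[ant_s[1:][tr]]
    out = pd.DataFrame({
        "device_id": dev_cats.take(dev_s[1:][tr]),
        "timestamp": ts_s[1:][tr],
        "from_comuna": pd.Categorical.from_codes(from_c, comuna_of.categories),
        "to_comuna": pd.Categorical.from_codes(to_c, comuna_of.categories),
    })
    out["internal"] = from_c == to_c
    out["date"] = out["timestamp"].dt.normalize()
    return out


def daily_active(events: pd.DataFrame) -> pd.DataFrame:
    """Distinct (device_id, date) pairs with at least one event."""
    out = pd.DataFrame({
        "device_id": events["device_id"],
        "date": pd.to_datetime(events["timestamp"]).dt.normalize(),
    }).drop_duplicates()
    return out.reset_index(drop=True)


def mobility_index(transitions: pd.DataFrame, homes: pd.DataFrame,
                   active: pd.DataFrame,
                   study_start: dt.date | None = None,
                   study_end: dt.date | None = None,
                   normalize: bool = True) -> pd.DataFrame:
    """Daily internal/external/total mobility per comuna.

    *homes* maps device_id -> home_comuna_id (e.g. baseline homes);
    devices without a home are excluded. *active* is the output of
    :func:`daily_active` and provides the per-day denominator. Days inside
    the study window with active homed devices but no transitions are 0;
    days with no active homed device are missing (NaN).
    """
    home_of = homes.set_index("device_id")["home_comuna_id"]

    act = active.copy()
    act["comuna_id"] = home_of.reindex(act["device_id"].to_numpy()).to_numpy()
    act = act.dropna(subset=["comuna_id"])
    denom = act.groupby(["comuna_id", "date"], observed=True).size()

    tr = transitions.copy()
    tr["comuna_id"] = home_of.reindex(tr["device_id"].to_numpy()).to_numpy()
    tr = tr.dropna(subset=["comuna_id"])
    grp = tr.groupby(["comuna_id", "date"], observed=True)["internal"]
    internal = grp.sum()
    total = grp.size()

    if study_start is not None and study_end is not None:
        dates = pd.date_range(study_start, study_end, freq="D")
    else:
        dates = pd.DatetimeIndex(sorted(act["date"].unique()))
    grid = pd.MultiIndex.from_product(
        [pd.Index(sorted(home_of.dropna().unique()), name="comuna_id"), dates],
        names=["comuna_id", "date"])
    denom = denom.reindex(grid, fill_value=0)
    internal = internal.reindex(grid, fill_value=0).astype(float)
    total = total.reindex(grid, fill_value=0).astype(float)
    external = total - internal

    out = pd.DataFrame({"n_active": denom}, index=grid).reset_index()
    if normalize:
        d = denom.to_numpy().astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            out["internal"] = np.where(d > 0, internal.to_numpy() / d, np.nan)
            out["external"] = np.where(d > 0, external.to_numpy() / d, np.nan)
            out["total"] = np.where(d > 0, total.to_numpy() / d, np.nan)
    else:
        out["internal"], out["external"], out["total"] = (
            internal.to_numpy(), external.to_numpy(), total.to_numpy())
    return out


def reduction_vs_baseline(series: pd.DataFrame, baseline_week: int,
                          study_start: dt.date) -> pd.DataFrame:
    """Percentage-point reduction of each index vs the baseline-week mean.

    For each comuna and each of internal/external/total, the reduction on a
    day is 100 * (baseline_mean - value) / baseline_mean; positive values
    mean less movement than in the baseline week. Comunas whose baseline
    mean is zero (or undefined) get NaN reductions, with a warning.
    """
    base_dates = weeks.week_dates(baseline_week, study_start)
    base = series[series["date"].isin(base_dates)]
    means = base.groupby("comuna_id", observed=True)[
        ["internal", "external", "total"]].mean()
    if ((means <= 0) | means.isna()).any().any():
        warnings.warn("comuna(s) with zero/undefined baseline mean: "
                      "reductions reported as missing")
    out = series.copy()
    for col in ("internal", "external", "total"):
        m = means[col].where(means[col] > 0).reindex(
            out["comuna_id"].to_numpy()).to_numpy()
        out[f"reduction_{col}_pp"] = 100.0 * (m - out[col].to_numpy()) / m
    return out


def stratify_by_quarantine(series: pd.DataFrame,
                           calendar: QuarantineCalendar) -> pd.DataFrame:
    """Flag each (comuna, day) row with its quarantine status."""
    out = series.copy()
    out["in_quarantine"] = calendar.mask(out["comuna_id"], out["date"])
    return out


def quarantine_summary(series: pd.DataFrame) -> pd.DataFrame:
    """Mean of each index and reduction per comuna and quarantine stratum."""
    cols = [c for c in series.columns
            if c in ("internal", "external", "total")
            or c.startswith("reduction_")]
    return (series.groupby(["comuna_id", "in_quarantine"], observed=True)[cols]
            .mean().reset_index())


def compute_mobility(events: pd.DataFrame, antennas: pd.DataFrame,
                     homes: pd.DataFrame, study_start: dt.date,
                     study_end: dt.date, baseline_week: int,
                     calendar: QuarantineCalendar | None = None
                     ) -> pd.DataFrame:
    """Transitions -> daily indices -> baseline reductions -> quarantine flag."""
    transitions = count_transitions(events, antennas)
    active = daily_active(events)
    series = mobility_index(transitions, homes, active, study_start, study_end)
    series = reduction_vs_baseline(series, baseline_week, study_start)
    if calendar is not None:
        series = stratify_by_quarantine(series, calendar)
    return series
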