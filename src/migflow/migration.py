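"""Long-term migration calls, origin-destination matrices and flow analytics.

A device migrated when the statistical mode of its weekly home over the four
November weeks lies in a different *region* than its baseline (March) home.
Devices absent at baseline, or absent in all four November weeks, are
excluded from both numerator and denominator. The comuna-level destination
is retained for origin-destination analytics even though the migration call
itself is region-level.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = ["ODMatrix", "call_migrations", "build_od_matrix",
           "observed_devices", "emigration_percentage", "net_migration_rate",
           "net_migration_rates", "net_flow_balance",
           "validate_against_reference"]


@dataclass
class ODMatrix:
    """Origin x destination migrant counts for one study year.

    ``counts`` has origin comunas on the index and destination comunas on
    the columns; only migrated devices are counted. Row marginals M(x) are
    the per-origin totals.
    """

    counts: pd.DataFrame
    year: str = "T"
    scaling_factor: float | None = field(default=None)  # optional devices->persons

    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def aligned_with(self, other: "ODMatrix") -> tuple[pd.DataFrame, pd.DataFrame]:
        """Outer-align two count matrices, missing cells as zero."""
        idx = self.counts.index.union(other.counts.index)
        cols = self.counts.columns.union(other.counts.columns)
        a = self.counts.reindex(index=idx, columns=cols, fill_value=0)
        b = other.counts.reindex(index=idx, columns=cols, fill_value=0)
        return a, b

    def to_regions(self, comunas: pd.DataFrame) -> pd.DataFrame:
        """Aggregate counts to region x region."""
        region_of = comunas.set_index("comuna_id")["region_id"]
        long = self.counts.stack()
        long = long[long > 0].reset_index()
        long.columns = ["origin", "destination", "n"]
        long["origin"] = region_of.reindex(long["origin"]).to_numpy()
        long["destination"] = region_of.reindex(long["destination"]).to_numpy()
        return long.pivot_table(index="origin", columns="destination",
                                values="n", aggfunc="sum", fill_value=0)


def call_migrations(homes: pd.DataFrame, baseline_week: int,
                    november_weeks: list[int],
                    comunas: pd.DataFrame) -> pd.DataFrame:
    """Call long-term migration for every device in a weekly home table.

    The November home is the mode over the non-absent November weeks, ties
    broken toward the smallest comuna_id. Devices absent at baseline or in
    all November weeks are excluded. Returns one row per retained device:
    device_id, origin_comuna_id, origin_region_id, november_home_comuna_id,
    november_region_id, migrated.
    """
    unknown = set(homes["home_comuna_id"]) - set(comunas["comuna_id"])
    if unknown:
        raise ValidationError(f"home comunas not in registry: {sorted(map(str, unknown))}")
    region_of = comunas.set_index("comuna_id")["region_id"]

    base = homes[homes["week_index"] == baseline_week]
    nov = homes[homes["week_index"].isin(november_weeks)]
    # mode with deterministic tie-break: most weeks, then smallest comuna_id
    tally = (nov.groupby(["device_id", "home_comuna_id"], observed=True)
             .size().reset_index(name="n_weeks"))
    tally = tally.sort_values(
        ["device_id", "n_weeks", "home_comuna_id"],
        ascending=[True, False, True], kind="mergesort")
    nov_mode = tally.drop_duplicates("device_id", keep="first")

    calls = base.merge(nov_mode[["device_id", "home_comuna_id"]],
                       on="device_id", suffixes=("_base", "_nov"))
    calls = calls.rename(columns={
        "home_comuna_id_base": "origin_comuna_id",
        "home_comuna_id_nov": "november_home_comuna_id"})
    calls["origin_region_id"] = region_of.reindex(
        calls["origin_comuna_id"]).to_numpy()
    calls["november_region_id"] = region_of.reindex(
        calls["november_home_comuna_id"]).to_numpy()
    calls["migrated"] = calls["origin_region_id"] != calls["november_region_id"]
    cols = ["device_id", "origin_comuna_id", "origin_region_id",
            "november_home_comuna_id", "november_region_id", "migrated"]
    return calls[cols].sort_values("device_id", ignore_index=True)


def build_od_matrix(calls: pd.DataFrame, year: str = "T") -> ODMatrix:
    """Count migrated devices by (origin comuna, November home comuna)."""
    mig = calls[calls["migrated"]]
    counts = pd.crosstab(mig["origin_comuna_id"], mig["november_home_comuna_id"])
    counts.index.name = "origin"
    counts.columns.name = "destination"
    return ODMatrix(counts=counts.astype(np.int64), year=year)


def observed_devices(calls: pd.DataFrame) -> pd.Series:
    """Devices observed (callable) per origin comuna: the emigration denominator."""
    return calls.groupby("origin_comuna_id", observed=True).size()


def emigration_percentage(od: ODMatrix, devices_observed: pd.Series) -> pd.Series:
    """Percentage of observed devices per origin that emigrated: 100 * M(x)/n(x).

    Origins with zero observed devices come back as NaN with a warning;
    origins observed but absent from the matrix are 0%.
    """
    m = od.row_totals().reindex(devices_observed.index, fill_value=0)
    if (devices_observed <= 0).any():
        warnings.warn("origins with zero observed devices reported as missing")
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * m / devices_observed.where(devices_observed > 0)
    return pct


def net_migration_rate(inflow: float, outflow: float, population: float,
                       per: float = 1000.0) -> float:
    """Net migration rate: per * (inflow - outflow) / population."""
    if population <= 0:
        raise ValidationError("population must be positive")
    return per * (inflow - outflow) / population


def net_migration_rates(calls: pd.DataFrame, comunas: pd.DataFrame,
                        per: float = 1000.0) -> pd.DataFrame:
    """Per-comuna inflow, outflow and net migration rate (default per 1000).

    Inflow counts migrated devices whose November home is the comuna;
    outflow counts migrated devices originating there.
    """
    mig = calls[calls["migrated"]]
    idx = comunas["comuna_id"]
    inflow = mig.groupby("november_home_comuna_id", observed=True).size() \
        .reindex(idx, fill_value=0)
    outflow = mig.groupby("origin_comuna_id", observed=True).size() \
        .reindex(idx, fill_value=0)
    pop = comunas.set_index("comuna_id")["population"].reindex(idx)
    rate = per * (inflow.to_numpy() - outflow.to_numpy()) / pop.to_numpy()
    return pd.DataFrame({
        "comuna_id": idx.to_numpy(), "inflow": inflow.to_numpy(),
        "outflow": outflow.to_numpy(), "net_migration_rate": rate,
    })


def net_flow_balance(calls: pd.DataFrame) -> int:
    """Sum of (inflow - outflow) over all comunas; 0 in a closed system."""
    mig = calls[calls["migrated"]]
    inflow = mig.groupby("november_home_comuna_id", observed=True).size()
    outflow = mig.groupby("origin_comuna_id", observed=True).size()
    idx = inflow.index.union(outflow.index)
    return int((inflow.reindex(idx, fill_value=0)
                - outflow.reindex(idx, fill_value=0)).sum())


def _pearson(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    n = len(a)
    if n < 3 or np.std(a) == 0 or np.std(b) == 0:
        return float("nan"), max(n - 2, 0)
    r = stats.pearsonr(a, b).statistic
    return float(r), n - 2


def validate_against_reference(od: ODMatrix, reference: ODMatrix,
                               comunas: pd.DataFrame,
                               focal_region: str) -> pd.DataFrame:
    """Correlate recovered flows with a reference at four aggregation levels.

    Mirrors a census-validation workflow: emigration (focal region ->
    elsewhere) and immigration (elsewhere -> focal region) flows are
    compared by Pearson r at region<->focal, comunas<->focal (whole),
    country<->focal-comunas, and comuna<->comuna granularity. Only
    movements crossing the focal-region boundary are considered. At the
    finest level, pairs where both sources are zero are dropped.

    Returns a table (level, direction, r, df, n).
    """
    region_of = comunas.set_index("comuna_id")["region_id"]
    a, b = od.aligned_with(reference)
    origin_in = region_of.reindex(a.index).to_numpy() == focal_region
    dest_in = region_of.reindex(a.columns).to_numpy() == focal_region

    def emi(m):  # focal-origin rows, outside destinations
        return m.loc[origin_in, ~dest_in]

    def imm(m):  # outside origins, focal destinations
        return m.loc[~origin_in, dest_in]

    rows = []
    for direction, fa, fb in (("emigration", emi(a), emi(b)),
                              ("immigration", imm(a), imm(b))):
        outside_axis = 1 if direction == "immigration" else 0
        # region <-> focal: aggregate outside side to regions, focal side wholly
        out_regions = region_of.reindex(
            fa.columns if direction == "emigration" else fa.index).to_numpy()
        ra = pd.Series(fa.sum(axis=outside_axis).to_numpy(),
                       index=out_regions).groupby(level=0).sum()
        rb = pd.Series(fb.sum(axis=outside_axis).to_numpy(),
                       index=out_regions).groupby(level=0).sum()
        r, dof = _pearson(ra.to_numpy(dtype=float), rb.to_numpy(dtype=float))
        rows.append(("regions<->focal", direction, r, dof, len(ra)))
        # comunas <-> focal: outside comunas vs the focal region as a whole
        ca = fa.sum(axis=outside_axis)
        cb = fb.sum(axis=outside_axis)
        r, dof = _pearson(ca.to_numpy(dtype=float), cb.to_numpy(dtype=float))
        rows.append(("comunas<->focal", direction, r, dof, len(ca)))
        # country <-> focal comunas: each focal comuna vs the rest of the country
        fa_c = fa.sum(axis=1 - outside_axis)
        fb_c = fb.sum(axis=1 - outside_axis)
        r, dof = _pearson(fa_c.to_numpy(dtype=float), fb_c.to_numpy(dtype=float))
        rows.append(("country<->focal-comunas", direction, r, dof, len(fa_c)))
        # comuna <-> comuna: pairwise flows, all-zero pairs dropped
        pa = fa.to_numpy(dtype=float).ravel()
        pb = fb.to_numpy(dtype=float).ravel()
        keep = (pa > 0) | (pb > 0)
        r, dof = _pearson(pa[keep], pb[keep])
        rows.append(("comuna<->comuna", direction, r, dof, int(keep.sum())))
    return pd.DataFrame(rows, columns=["level", "direction", "r", "df", "n"])
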