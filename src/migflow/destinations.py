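"""Destination-choice analytics across years and socioeconomic strata.

All operations act on emigration origin-destination matrices: origins on
the rows, destinations on the columns (use :func:`emigration_submatrix` to
restrict a country-wide matrix to focal-region origins and outside
destinations before comparing years).

The 1-Wasserstein divergence between two destination distributions needs a
ground coordinate embedding destinations on a line; the default is the
destination comuna's average income decile, with rurality, density or any
numeric comuna attribute selectable instead. The z-score significance
filter standardizes the difference matrix over all cells by default
(grand mean and SD); per-origin standardization is available.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .migration import ODMatrix

logger = logging.getLogger(__name__)

__all__ = ["emigration_submatrix", "destination_distribution", "od_difference",
           "zscore_filter_destinations", "wasserstein_divergence",
           "divergences_by_origin", "RuralityChange", "delta_rurality",
           "WeightedAttribute", "weighted_destination_attribute",
           "gravity_rank", "host_region_impact", "decile_binned_od"]


def emigration_submatrix(od: ODMatrix, comunas: pd.DataFrame,
                         focal_region: str) -> ODMatrix:
    """Restrict to flows from focal-region comunas to outside destinations."""
    region_of = comunas.set_index("comuna_id")["region_id"]
    rows = region_of.reindex(od.counts.index).to_numpy() == focal_region
    cols = region_of.reindex(od.counts.columns).to_numpy() != focal_region
    return ODMatrix(counts=od.counts.loc[rows, cols], year=od.year)


def destination_distribution(od: ODMatrix, origin: str) -> pd.Series:
    """Probability vector p_x(y) = m(x,y)/M(x) over destinations; NaN if M(x)=0."""
    row = od.counts.loc[origin].astype(float)
    total = row.sum()
    if total == 0:
        return row * np.nan
    return row / total


def od_difference(od_a: ODMatrix, od_b: ODMatrix,
                  as_percentage: bool = True) -> pd.DataFrame:
    """Cellwise destination-share change from year A to year B.

    Default units are percentage points of each origin's emigration
    (100 * (p_B - p_A)); origins with no emigrants in a year have undefined
    shares and come back as NaN rows. With ``as_percentage=False`` returns
    the raw count difference instead.
    """
    a, b = od_a.aligned_with(od_b)
    if not as_percentage:
        return b - a
    pa = 100.0 * a.div(a.sum(axis=1).replace(0, np.nan), axis=0)
    pb = 100.0 * b.div(b.sum(axis=1).replace(0, np.nan), axis=0)
    return pb - pa


def zscore_filter_destinations(diff: pd.DataFrame, threshold: float = 1.96,
                               mode: str = "global") -> list[str]:
    """Destinations with at least one standardized cell above *threshold*.

    ``mode="global"`` standardizes over all finite cells of the difference
    matrix (grand mean, sample SD); ``mode="per_origin"`` standardizes each
    origin's row separately. Zero variance retains nothing, with a warning.
    """
    vals = diff.to_numpy(dtype=float)
    if mode == "global":
        finite = vals[np.isfinite(vals)]
        sd = finite.std(ddof=1) if finite.size > 1 else 0.0
        if sd == 0 or not np.isfinite(sd):
            warnings.warn("difference matrix has zero variance; nothing retained")
            return []
        z = (vals - finite.mean()) / sd
    elif mode == "per_origin":
        mean = np.nanmean(vals, axis=1, keepdims=True)
        sd = np.nanstd(vals, axis=1, ddof=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (vals - mean) / sd
        if np.all(~np.isfinite(z)):
            warnings.warn("all origins have zero variance; nothing retained")
            return []
    else:
        raise ValueError(f"unknown z-score mode {mode!r}")
    keep = np.nansum(z > threshold, axis=0) > 0
    return [str(c) for c in diff.columns[keep]]


def wasserstein_divergence(p_a: pd.Series, p_b: pd.Series,
                           ground_coordinate: pd.Series) -> float:
    """Exact 1-Wasserstein distance between two destination distributions.

    Both distributions must live on the same destination set;
    *ground_coordinate* maps each destination to a scalar position. Either
    distribution undefined (zero or NaN mass) yields NaN.
    """
    if not p_a.index.equals(p_b.index):
        raise ValidationError("distributions defined over different destinations")
    coords = ground_coordinate.reindex(p_a.index)
    wa, wb = p_a.to_numpy(dtype=float), p_b.to_numpy(dtype=float)
    keep = coords.notna().to_numpy()
    wa, wb, xs = wa[keep], wb[keep], coords.to_numpy(dtype=float)[keep]
    if wa.sum() <= 0 or wb.sum() <= 0 or np.isnan(wa).any() or np.isnan(wb).any():
        return float("nan")
    return float(stats.wasserstein_distance(xs, xs, wa, wb))


def divergences_by_origin(od_a: ODMatrix, od_b: ODMatrix, comunas: pd.DataFrame,
                          coordinate: str = "income_decile") -> pd.Series:
    """Per-origin 1-Wasserstein divergence of year B's destination mix vs year A."""
    a, b = od_a.aligned_with(od_b)
    coords = comunas.set_index("comuna_id")[coordinate]
    out = {}
    for origin in a.index:
        out[origin] = wasserstein_divergence(
            a.loc[origin].astype(float) / max(a.loc[origin].sum(), 1),
            b.loc[origin].astype(float) / max(b.loc[origin].sum(), 1),
            coords) if a.loc[origin].sum() > 0 and b.loc[origin].sum() > 0 \
            else float("nan")
    return pd.Series(out, name="wasserstein")


@dataclass
class RuralityChange:
    """Emigrant-weighted mean destination rurality per year, and its change."""

    origin: str
    r_year: float     # R^T_x, year under study
    r_baseline: float  # R^T0_x, baseline year
    delta: float      # R^T_x - R^T0_x


def _weighted_mean_rurality(od: ODMatrix, comunas: pd.DataFrame,
                            origin: str) -> float:
    if origin not in od.counts.index:
        return float("nan")
    row = od.counts.loc[origin].astype(float)
    total = row.sum()
    if total == 0:
        return float("nan")
    r = comunas.set_index("comuna_id")["rural_fraction"].reindex(row.index)
    return float((row * r).sum() / total)


def delta_rurality(od_year: ODMatrix, od_baseline: ODMatrix,
                   comunas: pd.DataFrame, origin: str) -> RuralityChange:
    """Change in emigrant-weighted destination rurality vs the baseline year.

    R_x for a year is the mean rural household fraction of the destinations,
    weighted by the share of x's emigrants choosing each destination; the
    change is R_x(year) - R_x(baseline). Either year without emigrants from
    *origin* gives NaN.
    """
    r_t = _weighted_mean_rurality(od_year, comunas, origin)
    r_t0 = _weighted_mean_rurality(od_baseline, comunas, origin)
    return RuralityChange(origin=origin, r_year=r_t, r_baseline=r_t0,
                          delta=r_t - r_t0)


class WeightedAttribute(NamedTuple):
    value: float
    coverage: float  # fraction of emigrant weight carrying the attribute


def weighted_destination_attribute(od: ODMatrix, comunas: pd.DataFrame,
                                   origin: str,
                                   attribute: str) -> WeightedAttribute:
    """Emigrant-share-weighted mean of a destination attribute.

    For ``attribute="icvu"`` the value is the weighted mean *difference*
    icvu(destination) - icvu(origin); destinations outside the urban
    quality-of-life index's coverage are dropped and the weights
    renormalized, with the retained weight fraction reported as coverage.
    Other attributes (``density``, ``rural_fraction``, ...) are weighted
    means of the destination values, handled the same way for missing data.
    """
    if origin not in od.counts.index:
        return WeightedAttribute(float("nan"), 0.0)
    row = od.counts.loc[origin].astype(float)
    total = row.sum()
    if total == 0:
        return WeightedAttribute(float("nan"), 0.0)
    attrs = comunas.set_index("comuna_id")[attribute].reindex(row.index)
    if attribute == "icvu":
        origin_val = comunas.set_index("comuna_id")["icvu"].get(origin, np.nan)
        if pd.isna(origin_val):
            return WeightedAttribute(float("nan"), 0.0)
        attrs = attrs - origin_val
    ok = attrs.notna()
    covered = row[ok].sum()
    if covered == 0:
        return WeightedAttribute(float("nan"), 0.0)
    value = float((row[ok] * attrs[ok]).sum() / covered)
    return WeightedAttribute(value, float(covered / total))


def gravity_rank(regions: pd.DataFrame) -> pd.DataFrame:
    """Regions ordered by gravity score population / distance-to-origin.

    The focal region (distance 0) is excluded; a zero distance on any other
    region is an error.
    """
    out = regions.copy()
    focal = out["distance_to_origin_km"] == 0
    out = out[~focal]
    if (out["distance_to_origin_km"] <= 0).any():
        raise ValidationError("non-focal region with non-positive distance")
    out = out.assign(gravity=out["population"] / out["distance_to_origin_km"])
    return out.sort_values("gravity", ascending=False, ignore_index=True)


def host_region_impact(od_a: ODMatrix, od_b: ODMatrix, comunas: pd.DataFrame,
                       regions: pd.DataFrame, focal_region: str) -> pd.DataFrame:
    """Arrivals from the focal region as a percentage of each host population.

    For both years, aggregates focal-origin emigration flows by destination
    region and divides by the host region's population (x100); the
    difference column is year B minus year A.
    """
    if (regions["population"] <= 0).any():
        raise ValidationError("region population must be positive")
    pops = regions.set_index("region_id")["population"]

    def arrivals(od: ODMatrix) -> pd.Series:
        emi = emigration_submatrix(od, comunas, focal_region)
        region_of = comunas.set_index("comuna_id")["region_id"]
        dest_region = region_of.reindex(emi.counts.columns).to_numpy()
        return pd.Series(emi.counts.sum(axis=0).to_numpy(),
                         index=dest_region).groupby(level=0).sum()

    hosts = pops.index[pops.index != focal_region]
    pct_a = 100.0 * arrivals(od_a).reindex(hosts, fill_value=0) / pops[hosts]
    pct_b = 100.0 * arrivals(od_b).reindex(hosts, fill_value=0) / pops[hosts]
    return pd.DataFrame({"region_id": hosts, "pct_year_a": pct_a.to_numpy(),
                         "pct_year_b": pct_b.to_numpy(),
                         "difference": (pct_b - pct_a).to_numpy()})


def decile_binned_od(od: ODMatrix, comunas: pd.DataFrame) -> pd.DataFrame:
    """10x10 flow matrix binned by income decile, columns normalized.

    Rows are destination deciles, columns origin deciles (average deciles
    are rounded to integer bins 1..10); each nonempty column is divided by
    its sum. Empty origin-decile columns stay zero, with a warning.
    """
    dec = comunas.set_index("comuna_id")["income_decile"]
    missing = (set(od.counts.index) | set(od.counts.columns)) - set(dec.index)
    if missing:
        raise ValidationError(f"comunas without income decile: {sorted(map(str, missing))}")
    long = od.counts.stack().reset_index()
    long.columns = ["origin", "destination", "n"]
    long["o_dec"] = np.clip(np.round(dec.reindex(long["origin"]).to_numpy()), 1, 10)
    long["d_dec"] = np.clip(np.round(dec.reindex(long["destination"]).to_numpy()), 1, 10)
    mat = long.pivot_table(index="d_dec", columns="o_dec", values="n",
                           aggfunc="sum", fill_value=0)
    mat = mat.reindex(index=range(1, 11), columns=range(1, 11), fill_value=0)
    mat.index.name, mat.columns.name = "destination_decile", "origin_decile"
    sums = mat.sum(axis=0)
    if (sums == 0).any():
        warnings.warn("empty origin-decile column(s) left as zeros")
    return mat.div(sums.replace(0, np.nan), axis=1).fillna(0.0)
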