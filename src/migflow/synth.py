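"""Synthetic XDR scenario generator with planted ground truth.

The generator emulates, at desk scale, the structure of a national
mobile-network event stream: devices anchor at antennas of their home comuna
at night, disperse during the day, a configurable fraction relocates to
another region partway through the study window, and after a shock date
daily movement contracts by an income-decile-graded factor. Every planted
quantity (true home, relocation week and destination, per-comuna emigration
fraction, expected daily transition counts) is returned as
:class:`GroundTruth` so each downstream stage has a recoverable target.

Model of one device-day
-----------------------
Night window (22:00-06:00, attributed to the evening's date): ping count is
Poisson(8 * night_ping_rate); each ping lands on the device's current
primary home antenna, except with probability ``noise_fraction`` on a
uniformly random antenna (tower noise).

Day window (06:00-22:00): the device emits Poisson(16 * day_ping_rate)
"anchor" pings at its primary antenna, plus short excursions. Each of the
N+1 gaps of the anchor sequence independently hosts a single-ping excursion
with probability ``day_excursion_rate * s / (N+1)``, where ``s`` is 1 before
the shock date and ``1 - reduction(decile)`` afterwards. An excursion ping
sits at a different antenna (another comuna with probability
``external_excursion_fraction``, else another antenna of the home comuna),
so it contributes exactly two antenna transitions (out and back). The
expected number of daily transitions is therefore
``2 * day_excursion_rate * s`` up to a small truncation correction on days
with very few anchor pings, which makes the planted mobility reduction
exactly recoverable from transition counts when ``noise_fraction`` is 0.

Relocations are region-level: a migrating device switches its primary
antenna to one in the destination comuna at the start of its relocation
week, drawn strictly after the baseline week and early enough that all four
November weeks are spent at the destination.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import weeks
from .errors import ConfigError
from .geography import QuarantineCalendar

logger = logging.getLogger(__name__)

NIGHT_HOURS = 8   # 22:00-06:00
DAY_HOURS = 16    # 06:00-22:00

__all__ = [
    "ScenarioConfig", "Geography", "GroundTruth", "Scenario",
    "generate_geography", "generate_xdr", "generate_quarantine",
    "simulate_scenario", "write_scenario",
]


def _default_reduction() -> dict[int, float]:
    # richer comunas reduce movement more after the shock
    return {d: round(0.10 + 0.05 * (d - 1), 3) for d in range(1, 11)}


class ScenarioConfig(BaseModel):
    """Parameters of one synthetic study year."""

    n_regions: int = Field(default=6, ge=2)
    n_comunas_per_region: int = Field(default=8, ge=1)
    n_antennas_per_comuna: int = Field(default=3, ge=1)
    n_devices: int = Field(default=2000, ge=1)
    study_start: dt.date = dt.date(2020, 3, 1)
    study_end: dt.date = dt.date(2020, 11, 30)
    baseline_week_index: int | None = None  # default: second full week of March
    migration_fraction: float = Field(default=0.10, ge=0.0, le=1.0)
    migration_income_slope: float = 0.15   # log-linear, per decile step
    migration_comuna_sd: float = Field(default=0.25, ge=0.0)  # lognormal sd
    within_region_move_fraction: float = Field(default=0.0, ge=0.0, le=1.0)
    night_ping_rate: float = Field(default=0.5, gt=0.0)   # pings per hour
    day_ping_rate: float = Field(default=0.5, gt=0.0)     # anchor pings per hour
    day_excursion_rate: float = Field(default=2.0, ge=0.0)  # excursions per day
    external_excursion_fraction: float = Field(default=0.3, ge=0.0, le=1.0)
    mobility_shock_date: dt.date = dt.date(2020, 3, 16)
    mobility_reduction_by_decile: dict[int, float] = Field(
        default_factory=_default_reduction)
    noise_fraction: float = Field(default=0.05, ge=0.0, le=1.0)
    quarantine_probability: float = Field(default=0.6, ge=0.0, le=1.0)
    rng_seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "ScenarioConfig":
        if not (self.study_start < self.mobility_shock_date < self.study_end):
            raise ConfigError(
                "require study_start < mobility_shock_date < study_end")
        if self.n_regions * self.n_comunas_per_region < 2:
            raise ConfigError("need at least 2 comunas (and >= 2 regions)")
        for d, r in self.mobility_reduction_by_decile.items():
            if not (1 <= d <= 10) or not (0.0 <= r <= 1.0):
                raise ConfigError(
                    f"mobility_reduction_by_decile[{d}]={r} out of range")
        return self

    @property
    def baseline_week(self) -> int:
        if self.baseline_week_index is not None:
            return self.baseline_week_index
        return weeks.baseline_week_index(self.study_start)

    @property
    def november_weeks(self) -> list[int]:
        return weeks.november_week_indices(self.study_start)

    @property
    def n_days(self) -> int:
        return (self.study_end - self.study_start).days + 1

    @property
    def n_weeks(self) -> int:
        return weeks.n_study_weeks(self.study_start, self.study_end)


@dataclass
class Geography:
    """Synthetic antennas/comunas/regions registries (geography_io schemas)."""

    antennas: pd.DataFrame
    comunas: pd.DataFrame
    regions: pd.DataFrame
    focal_region_id: str


@dataclass
class GroundTruth:
    """Planted truth of one scenario realization."""

    devices: pd.DataFrame       # per-device true home, decile, relocation
    emigration: pd.DataFrame    # per-comuna expected and realized fractions
    daily_mobility: pd.DataFrame  # per-comuna-per-day expected transitions/device
    config: ScenarioConfig


@dataclass
class Scenario:
    geography: Geography
    events: pd.DataFrame
    ground_truth: GroundTruth
    quarantine: QuarantineCalendar


def _haversine_km(lat1, lon1, lat2, lon2):
    r = 6371.0
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp, dl = p2 - p1, np.radians(lon2) - np.radians(lon1)
    a = np.sin(dp / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    return 2 * r * np.arcsin(np.sqrt(a))


def generate_geography(config: ScenarioConfig,
                       rng: np.random.Generator | None = None) -> Geography:
    """Draw a synthetic geography: one dense focal (metropolitan) region plus
    sparser host regions, comuna covariates with deciles 1-10 represented and
    rurality anti-correlated with density, and antennas around each centroid."""
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    n_reg, n_per = config.n_regions, config.n_comunas_per_region
    n_com = n_reg * n_per
    k = config.n_antennas_per_comuna

    region_ids = [f"R{i + 1:02d}" for i in range(n_reg)]
    reg_lat = np.concatenate([[-33.45], rng.uniform(-53.0, -18.0, n_reg - 1)])
    reg_lon = np.concatenate([[-70.66], rng.uniform(-73.0, -68.0, n_reg - 1)])
    dist = _haversine_km(reg_lat[0], reg_lon[0], reg_lat, reg_lon)
    dist[0] = 0.0

    comuna_ids = [f"C{i + 1:03d}" for i in range(n_com)]
    com_region = np.repeat(np.arange(n_reg), n_per)
    base_decile = (np.arange(n_com) % 10) + 1
    base_decile = rng.permutation(base_decile)
    income_decile = np.clip(base_decile + rng.uniform(-0.3, 0.3, n_com), 1.0, 10.0)
    log_density = np.where(com_region == 0,
                           rng.normal(3.3, 0.4, n_com),
                           rng.normal(2.0, 0.7, n_com))
    area = np.exp(rng.normal(np.log(80.0), 0.5, n_com))
    population = np.maximum(500, np.round(10.0 ** log_density * area)).astype(np.int64)
    rural = np.clip((2.8 - log_density) / 2.5 + rng.normal(0, 0.05, n_com), 0.0, 1.0)
    poverty = np.clip(0.35 - 0.03 * income_decile + rng.normal(0, 0.03, n_com), 0.0, 1.0)
    icvu = np.where(rural < 0.4,
                    40.0 + 3.0 * income_decile + rng.normal(0, 3.0, n_com),
                    np.nan)
    cen_lat = reg_lat[com_region] + rng.normal(0, 0.5, n_com)
    cen_lon = reg_lon[com_region] + rng.normal(0, 0.5, n_com)

    comunas = pd.DataFrame({
        "comuna_id": comuna_ids,
        "region_id": [region_ids[r] for r in com_region],
        "name": [f"Comuna {cid}" for cid in comuna_ids],
        "population": population,
        "area_km2": np.round(area, 3),
        "income_decile": np.round(income_decile, 3),
        "poverty_rate": np.round(poverty, 4),
        "rural_fraction": np.round(rural, 4),
        "icvu": np.round(icvu, 2),
        "centroid_lat": np.round(cen_lat, 5),
        "centroid_lon": np.round(cen_lon, 5),
    })
    comunas["density"] = comunas["population"] / comunas["area_km2"]

    antennas = pd.DataFrame({
        "antenna_id": [f"A{i + 1:05d}" for i in range(n_com * k)],
        "lat": np.round(np.repeat(cen_lat, k) + rng.normal(0, 0.02, n_com * k), 5),
        "lon": np.round(np.repeat(cen_lon, k) + rng.normal(0, 0.02, n_com * k), 5),
        "comuna_id": np.repeat(comuna_ids, k),
    })

    regions = pd.DataFrame({
        "region_id": region_ids,
        "name": ["Focal Metropolitan" if i == 0 else f"Region {rid}"
                 for i, rid in enumerate(region_ids)],
        "population": comunas.groupby("region_id", sort=False)["population"]
                             .sum().reindex(region_ids).to_numpy(),
        "distance_to_origin_km": np.round(dist, 1),
    })
    return Geography(antennas=antennas, comunas=comunas, regions=regions,
                     focal_region_id=region_ids[0])


def _plant_devices(config: ScenarioConfig, geography: Geography,
                   rng: np.random.Generator):
    """Assign devices to home comunas and draw relocation ground truth."""
    com = geography.comunas
    n_com = len(com)
    pop = com["population"].to_numpy(dtype=float)
    home_c = rng.choice(n_com, size=config.n_devices, p=pop / pop.sum())
    decile = com["income_decile"].to_numpy()[home_c]
    decile_int = np.clip(np.round(decile).astype(int), 1, 10)

    # planted emigration probability per comuna: log-linear income gradient
    # with a lognormal comuna-level effect; identically zero when the base
    # migration fraction is zero
    u_c = rng.normal(0.0, config.migration_comuna_sd, n_com)
    p_com = np.clip(
        config.migration_fraction
        * np.exp(config.migration_income_slope
                 * (com["income_decile"].to_numpy() - 5.5) + u_c),
        0.0, 0.9)
    migrated = rng.random(config.n_devices) < p_com[home_c]

    # destination region by gravity from the focal metropolitan centre
    reg_ids = geography.regions["region_id"].to_numpy()
    reg_pop = geography.regions["population"].to_numpy(dtype=float)
    reg_dist = np.maximum(geography.regions["distance_to_origin_km"].to_numpy(), 50.0)
    gravity = reg_pop / reg_dist
    com_region_code = geography.regions.reset_index().set_index("region_id") \
        .loc[com["region_id"], "index"].to_numpy()

    dest_c = np.full(config.n_devices, -1, dtype=np.int64)
    rel_week = np.full(config.n_devices, -1, dtype=np.int64)
    nov0 = min(config.november_weeks)
    lo, hi = config.baseline_week + 1, nov0  # relocation week in [lo, hi)
    if hi <= lo:
        raise ConfigError("study window leaves no week for relocations "
                          "between baseline and November")
    mig_idx = np.flatnonzero(migrated)
    if len(mig_idx):
        origin_region = com_region_code[home_c[mig_idx]]
        # sample destination region != origin, then comuna by population
        w = np.tile(gravity, (len(mig_idx), 1))
        w[np.arange(len(mig_idx)), origin_region] = 0.0
        w /= w.sum(axis=1, keepdims=True)
        cum = np.cumsum(w, axis=1)
        dest_region = (rng.random(len(mig_idx))[:, None] < cum).argmax(axis=1)
        for r in np.unique(dest_region):
            sel = mig_idx[dest_region == r]
            in_r = np.flatnonzero(com_region_code == r)
            p_r = pop[in_r] / pop[in_r].sum()
            dest_c[sel] = rng.choice(in_r, size=len(sel), p=p_r)
        rel_week[mig_idx] = rng.integers(lo, hi, size=len(mig_idx))

    # optional within-region confounder moves (not migrations)
    if config.within_region_move_fraction > 0:
        cand = np.flatnonzero(~migrated)
        movers = cand[rng.random(len(cand)) < config.within_region_move_fraction]
        for i in movers:
            in_r = np.flatnonzero(com_region_code == com_region_code[home_c[i]])
            in_r = in_r[in_r != home_c[i]]
            if len(in_r):
                dest_c[i] = rng.choice(in_r)
                rel_week[i] = rng.integers(lo, hi)

    return home_c, decile, decile_int, migrated, dest_c, rel_week, p_com


def generate_xdr(config: ScenarioConfig, geography: Geography,
                 rng: np.random.Generator | None = None
                 ) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the event stream and its ground truth.

    Returns an event table (device_id, timestamp, antenna_id; categorical
    ids, naive study-local timestamps, sorted by device then time) and the
    :class:`GroundTruth` for the same realization.
    """
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    n_dev, n_days = config.n_devices, config.n_days
    k = config.n_antennas_per_comuna
    com = geography.comunas
    n_com = len(com)
    n_ant = len(geography.antennas)

    # antenna code = row position; codes of comuna c are c*k .. c*k+k-1
    # (generate_geography emits antennas grouped by comuna in id order)
    ant_comuna = pd.Categorical(geography.antennas["comuna_id"],
                                categories=com["comuna_id"]).codes
    if not np.array_equal(ant_comuna, np.repeat(np.arange(n_com), k)):
        raise ConfigError("geography must come from generate_geography")

    (home_c, decile, decile_int, migrated, dest_c, rel_week, p_com) = \
        _plant_devices(config, geography, rng)

    primary0 = home_c * k + rng.integers(0, k, n_dev)
    has_dest = dest_c >= 0
    primary1 = np.where(has_dest, dest_c * k + rng.integers(0, k, n_dev), primary0)

    day_dates = pd.date_range(config.study_start, config.study_end, freq="D")
    week_of_day = weeks.week_index(day_dates, config.study_start)
    shock_idx = (config.mobility_shock_date - config.study_start).days

    moved = has_dest[:, None] & (week_of_day[None, :] >= rel_week[:, None])
    cur_primary = np.where(moved, primary1[:, None], primary0[:, None]).astype(np.int32)
    del moved

    red = np.zeros(11)
    for d, r in config.mobility_reduction_by_decile.items():
        red[d] = r
    post = np.arange(n_days) >= shock_idx
    # per-device-day excursion scale: 1 pre-shock, 1 - reduction(decile) after
    scale = np.where(post[None, :], (1.0 - red[decile_int])[:, None], 1.0)

    n_dd = n_dev * n_days

    # --- night pings -------------------------------------------------------
    m = rng.poisson(config.night_ping_rate * NIGHT_HOURS, n_dd)
    ev_dd = np.repeat(np.arange(n_dd, dtype=np.int64), m)
    nev = len(ev_dd)
    n_dev_idx = (ev_dd // n_days).astype(np.int32)
    n_day_idx = (ev_dd % n_days).astype(np.int32)
    del ev_dd
    night_ant = cur_primary[n_dev_idx, n_day_idx]
    if config.noise_fraction > 0:
        noisy = rng.random(nev) < config.noise_fraction
        night_ant[noisy] = rng.integers(0, n_ant, int(noisy.sum())).astype(np.int32)
    night_t = n_day_idx.astype(np.int64) * 86400 + rng.integers(
        22 * 3600, 30 * 3600, nev)

    # --- day pings: anchors + gap excursions -------------------------------
    n_anchor = rng.poisson(config.day_ping_rate * DAY_HOURS, n_dd)
    a_dd = np.repeat(np.arange(n_dd, dtype=np.int64), n_anchor)
    offs = np.cumsum(n_anchor) - n_anchor
    a_key = (np.arange(len(a_dd)) - np.repeat(offs, n_anchor) + 1).astype(np.float64)

    gaps = n_anchor + 1
    p_gap = np.clip(config.day_excursion_rate * scale.ravel() / gaps, 0.0, 1.0)
    g_dd = np.repeat(np.arange(n_dd, dtype=np.int64), gaps)
    goffs = np.cumsum(gaps) - gaps
    g_idx = np.arange(len(g_dd)) - np.repeat(goffs, gaps)
    hit = rng.random(len(g_dd)) < np.repeat(p_gap, gaps)
    e_dd = g_dd[hit]
    e_key = g_idx[hit] + 0.5
    del g_dd, g_idx, hit

    e_dev = (e_dd // n_days).astype(np.int32)
    e_day = (e_dd % n_days).astype(np.int32)
    e_home = (cur_primary[e_dev, e_day] // k).astype(np.int64)
    e_prim_off = cur_primary[e_dev, e_day] - e_home * k
    nexc = len(e_dd)
    external = rng.random(nexc) < config.external_excursion_fraction
    if k == 1:
        external[:] = True  # single-antenna comunas cannot host internal trips
    c = rng.integers(0, n_com - 1, nexc)
    c += c >= e_home
    ext_ant = c * k + rng.integers(0, k, nexc)
    o = rng.integers(0, max(k - 1, 1), nexc)
    o += o >= e_prim_off
    int_ant = e_home * k + o
    e_ant = np.where(external, ext_ant, int_ant).astype(np.int32)
    internal_exc = ~external

    d_dd = np.concatenate([a_dd, e_dd])
    d_key = np.concatenate([a_key, e_key])
    a_dev = (a_dd // n_days).astype(np.int32)
    a_day = (a_dd % n_days).astype(np.int32)
    d_ant = np.concatenate([cur_primary[a_dev, a_day], e_ant])
    del a_dd, a_key, e_dd, e_key

    order = np.lexsort((d_key, d_dd))
    u = rng.integers(6 * 3600, 22 * 3600, len(d_dd))
    order_u = np.lexsort((u, d_dd))
    t_day = np.empty(len(d_dd), dtype=np.int64)
    t_day[order] = u[order_u]
    t_day += (d_dd % n_days) * 86400
    d_dev = (d_dd // n_days).astype(np.int32)
    del d_dd, order, order_u, u

    # --- assemble ----------------------------------------------------------
    dev_all = np.concatenate([n_dev_idx, d_dev])
    t_all = np.concatenate([night_t, t_day])
    ant_all = np.concatenate([night_ant, d_ant])
    del n_dev_idx, d_dev, night_t, t_day, night_ant, d_ant
    srt = np.lexsort((t_all, dev_all))

    device_ids = [f"D{i + 1:06d}" for i in range(n_dev)]
    events = pd.DataFrame({
        "device_id": pd.Categorical.from_codes(dev_all[srt], categories=device_ids),
        "timestamp": pd.Timestamp(config.study_start)
        + pd.to_timedelta(t_all[srt], unit="s"),
        "antenna_id": pd.Categorical.from_codes(
            ant_all[srt], categories=geography.antennas["antenna_id"]),
    })
    del dev_all, t_all, ant_all, srt

    # --- ground truth ------------------------------------------------------
    comuna_ids = com["comuna_id"].to_numpy()
    region_of = com["region_id"].to_numpy()
    devices = pd.DataFrame({
        "device_id": device_ids,
        "home_comuna_id": comuna_ids[home_c],
        "home_region_id": region_of[home_c],
        "income_decile": decile,
        "decile": decile_int,
        "migrated": migrated,
        "relocation_week": np.where(migrated, rel_week, -1),
        "dest_comuna_id": np.where(migrated, comuna_ids[np.maximum(dest_c, 0)], ""),
        "dest_region_id": np.where(migrated, region_of[np.maximum(dest_c, 0)], ""),
    })
    grp = devices.groupby("home_comuna_id")
    emigration = pd.DataFrame({
        "comuna_id": comuna_ids,
        "expected_fraction": p_com,
        "realized_fraction": grp["migrated"].mean().reindex(comuna_ids).to_numpy(),
        "n_devices": grp.size().reindex(comuna_ids).fillna(0).astype(int).to_numpy(),
    })
    com_dec = np.clip(np.round(com["income_decile"].to_numpy()).astype(int), 1, 10)
    com_scale = np.where(post[None, :], (1.0 - red[com_dec])[:, None], 1.0)
    exp_total = 2.0 * config.day_excursion_rate * com_scale
    p_ext = 1.0 if k == 1 else config.external_excursion_fraction
    daily = pd.DataFrame({
        "comuna_id": np.repeat(comuna_ids, n_days),
        "date": np.tile(day_dates, n_com),
        "expected_transitions": exp_total.ravel(),
        "expected_internal": (exp_total * (1.0 - p_ext)).ravel(),
        "expected_external": (exp_total * p_ext).ravel(),
    })
    gt = GroundTruth(devices=devices, emigration=emigration,
                     daily_mobility=daily, config=config)
    return events, gt


def generate_quarantine(config: ScenarioConfig, geography: Geography,
                        rng: np.random.Generator | None = None
                        ) -> QuarantineCalendar:
    """Draw per-comuna quarantine intervals inside the post-shock period."""
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    rows = []
    post_days = (config.study_end - config.mobility_shock_date).days
    for cid in geography.comunas["comuna_id"]:
        if rng.random() >= config.quarantine_probability or post_days < 15:
            continue
        start_off = int(rng.integers(0, max(post_days - 14, 1)))
        length = int(rng.integers(14, min(90, post_days - start_off) + 1))
        start = config.mobility_shock_date + dt.timedelta(days=start_off)
        rows.append((cid, start, start + dt.timedelta(days=length)))
    if not rows:
        return QuarantineCalendar()
    return QuarantineCalendar.from_intervals(
        pd.DataFrame(rows, columns=["comuna_id", "start_date", "end_date"]))


def simulate_scenario(config: ScenarioConfig) -> Scenario:
    """Run the full generator under one RNG seeded from ``config.rng_seed``."""
    rng = np.random.default_rng(config.rng_seed)
    geography = generate_geography(config, rng)
    events, ground_truth = generate_xdr(config, geography, rng)
    quarantine = generate_quarantine(config, geography, rng)
    return Scenario(geography=geography, events=events,
                    ground_truth=ground_truth, quarantine=quarantine)


def write_scenario(scenario: Scenario, outdir) -> list[Path]:
    """Write all geography_io CSVs plus the ground-truth tables."""
    from . import geography as gio
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gio.write_antennas(scenario.geography.antennas, outdir / "antennas.csv")
    gio.write_comunas(scenario.geography.comunas, outdir / "comunas.csv")
    gio.write_regions(scenario.geography.regions, outdir / "regions.csv")
    gio.write_quarantine(scenario.quarantine, outdir / "quarantine.csv")
    gio.write_xdr(scenario.events, outdir / "xdr.csv")
    gt = scenario.ground_truth
    gt.devices.to_csv(outdir / "ground_truth_devices.csv", index=False)
    gt.emigration.to_csv(outdir / "ground_truth_emigration.csv", index=False)
    daily = gt.daily_mobility.copy()
    daily["date"] = pd.to_datetime(daily["date"]).dt.date
    daily.to_csv(outdir / "ground_truth_mobility.csv", index=False)
    return sorted(outdir.glob("*.csv"))
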