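"""End-to-end orchestration: simulate -> homes -> migrate -> destinations ->
mobility -> stratify, with a manifest of outputs and a summary report.

Two modes share the same stages:

* **simulate mode** (default): a :class:`~migflow.synth.ScenarioConfig`
  describes the study year; a second, "pre-crisis" scenario (no planted
  income gradients, no mobility shock) is derived automatically when not
  given, sharing the same geography, so year-over-year destination
  analytics have a baseline to compare against.
* **inputs mode**: paths to externally produced CSVs (antennas, comunas,
  regions, xdr, optionally quarantine and a baseline-year xdr).

Outputs are plain CSV/JSON under ``out_dir``; the manifest records row
counts and content hashes for every file, which makes end-to-end
determinism checkable by re-running with the same seed.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, model_validator

from . import destinations as dst
from . import geography as gio
from . import homes as hm
from . import migration as mig
from . import mobility as mob
from . import strata
from . import synth
from .errors import PipelineError

logger = logging.getLogger(__name__)

__all__ = ["InputPaths", "AnalysisParams", "RunConfig", "load_run_config",
           "run_pipeline", "default_baseline"]


class InputPaths(BaseModel):
    antennas: str
    comunas: str
    regions: str
    xdr: str
    quarantine: str | None = None
    xdr_baseline: str | None = None


class AnalysisParams(BaseModel):
    wasserstein_coordinate: str = "income_decile"
    zscore_mode: str = "global"
    zscore_threshold: float = 1.96
    rich_fraction: float = 0.2
    per: float = 1000.0
    night_window: tuple[int, int] = (22, 6)
    weekdays: tuple[int, ...] = (0, 1, 2, 3, 4)
    baseline_week_override: int | None = None


class RunConfig(BaseModel):
    out_dir: str
    scenario: synth.ScenarioConfig | None = None
    baseline_scenario: synth.ScenarioConfig | None = None
    inputs: InputPaths | None = None
    analysis: AnalysisParams = AnalysisParams()
    study_start: dt.date | None = None  # required in inputs mode
    study_end: dt.date | None = None
    rng_seed: int | None = None  # overrides scenario seeds when set

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if (self.scenario is None) == (self.inputs is None):
            raise ValueError("exactly one of 'scenario' or 'inputs' must be set")
        if self.inputs is not None and (self.study_start is None
                                        or self.study_end is None):
            raise ValueError("inputs mode requires study_start and study_end")
        return self


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig.model_validate(raw)


def default_baseline(scenario: synth.ScenarioConfig) -> synth.ScenarioConfig:
    """A pre-crisis comparison year: no income gradients, no mobility shock."""
    return scenario.model_copy(update={
        "migration_income_slope": 0.0,
        "mobility_reduction_by_decile": {d: 0.0 for d in range(1, 11)},
        "rng_seed": scenario.rng_seed + 1,
    })


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _record(manifest: dict, stage: str, path: Path, rows: int | None) -> None:
    manifest.setdefault(stage, []).append({
        "path": path.name, "rows": rows, "sha256": _sha256(path)})


def _write_csv(frame: pd.DataFrame, path: Path, manifest: dict, stage: str,
               **kwargs) -> None:
    frame.to_csv(path, index=kwargs.pop("index", False), **kwargs)
    _record(manifest, stage, path, len(frame))


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns {"manifest": ..., "summary": ...}.

    Any stage failure raises :class:`PipelineError` carrying the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {}
    summary: dict = {}
    ap = config.analysis

    # ----- stage 1: simulate (or load) ------------------------------------
    stage = "simulate"
    try:
        if config.scenario is not None:
            scenario = config.scenario
            baseline_sc = config.baseline_scenario or default_baseline(scenario)
            if config.rng_seed is not None:
                scenario = scenario.model_copy(update={"rng_seed": config.rng_seed})
                baseline_sc = baseline_sc.model_copy(
                    update={"rng_seed": config.rng_seed + 1})
            study_start, study_end = scenario.study_start, scenario.study_end
            rng = np.random.default_rng(scenario.rng_seed)
            geo = synth.generate_geography(scenario, rng)
            events, truth = synth.generate_xdr(scenario, geo, rng)
            calendar = synth.generate_quarantine(scenario, geo, rng)
            rng_b = np.random.default_rng(baseline_sc.rng_seed)
            events_base, _ = synth.generate_xdr(baseline_sc, geo, rng_b)
            antennas, comunas, regions = geo.antennas, geo.comunas, geo.regions
            focal = geo.focal_region_id
            gio.write_antennas(antennas, out / "antennas.csv")
            gio.write_comunas(comunas, out / "comunas.csv")
            gio.write_regions(regions, out / "regions.csv")
            gio.write_quarantine(calendar, out / "quarantine.csv")
            gio.write_xdr(events, out / "xdr.csv")
            gio.write_xdr(events_base, out / "xdr_baseline.csv")
            for name, rows in (("antennas.csv", len(antennas)),
                               ("comunas.csv", len(comunas)),
                               ("regions.csv", len(regions)),
                               ("quarantine.csv", len(calendar.intervals)),
                               ("xdr.csv", len(events)),
                               ("xdr_baseline.csv", len(events_base))):
                _record(manifest, stage, out / name, rows)
        else:
            paths = config.inputs
            study_start, study_end = config.study_start, config.study_end
            antennas = gio.read_antennas(paths.antennas)
            regions = gio.read_regions(paths.regions)
            comunas = gio.read_comunas(paths.comunas, regions)
            gio.check_referential_integrity(antennas, comunas, regions)
            focal = gio.focal_region_id(regions)
            events = gio.read_xdr(paths.xdr)
            events_base = (gio.read_xdr(paths.xdr_baseline)
                           if paths.xdr_baseline else None)
            calendar = (gio.read_quarantine(paths.quarantine)
                        if paths.quarantine else gio.QuarantineCalendar())
            truth = None
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    n_weeks = hm.weeks.n_study_weeks(study_start, study_end)
    baseline_week = (ap.baseline_week_override
                     if ap.baseline_week_override is not None
                     else hm.weeks.baseline_week_index(study_start))
    november = hm.weeks.november_week_indices(study_start)

    # ----- stage 2: homes --------------------------------------------------
    stage = "homes"
    try:
        homes = hm.weekly_homes(events, antennas, study_start, study_end,
                                ap.night_window, ap.weekdays)
        _write_csv(homes, out / "homes.csv", manifest, stage)
        homes_base = None
        if events_base is not None:
            homes_base = hm.weekly_homes(events_base, antennas, study_start,
                                         study_end, ap.night_window, ap.weekdays)
            _write_csv(homes_base, out / "homes_baseline.csv", manifest, stage)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ----- stage 3: migrate ------------------------------------------------
    stage = "migrate"
    try:
        calls = mig.call_migrations(homes, baseline_week, november, comunas)
        od = mig.build_od_matrix(calls, year="study")
        rates = mig.net_migration_rates(calls, comunas, per=ap.per)
        emi_pct = mig.emigration_percentage(od, mig.observed_devices(calls))
        _write_csv(calls, out / "calls.csv", manifest, stage)
        od_long = od.counts.stack().reset_index(name="count")
        _write_csv(od_long, out / "od_matrix.csv", manifest, stage)
        _write_csv(rates, out / "rates.csv", manifest, stage)
        _write_csv(emi_pct.rename("emigration_pct").reset_index(),
                   out / "emigration.csv", manifest, stage)
        od_base = None
        if homes_base is not None:
            calls_base = mig.call_migrations(homes_base, baseline_week,
                                             november, comunas)
            od_base = mig.build_od_matrix(calls_base, year="baseline")
            _write_csv(calls_base, out / "calls_baseline.csv", manifest, stage)
            _write_csv(od_base.counts.stack().reset_index(name="count"),
                       out / "od_matrix_baseline.csv", manifest, stage)
        summary["total_migrants"] = int(calls["migrated"].sum())
        summary["net_flow_balance"] = mig.net_flow_balance(calls)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ----- stage 4: destinations ------------------------------------------
    stage = "destinations"
    try:
        if od_base is not None:
            emi_b = dst.emigration_submatrix(od, comunas, focal)
            emi_a = dst.emigration_submatrix(od_base, comunas, focal)
            diff = dst.od_difference(emi_a, emi_b)
            retained = dst.zscore_filter_destinations(
                diff, ap.zscore_threshold, ap.zscore_mode)
            div = dst.divergences_by_origin(emi_a, emi_b, comunas,
                                            ap.wasserstein_coordinate)
            drur = [dst.delta_rurality(emi_b, emi_a, comunas, x)
                    for x in emi_b.counts.index]
            wdens = {x: dst.weighted_destination_attribute(
                emi_b, comunas, x, "density") for x in emi_b.counts.index}
            gravity = dst.gravity_rank(regions)
            impact = dst.host_region_impact(od_base, od, comunas, regions, focal)
            binned = dst.decile_binned_od(emi_b, comunas)
            _write_csv(diff, out / "od_difference.csv", manifest, stage, index=True)
            _write_csv(pd.DataFrame({"destination": retained}),
                       out / "retained_destinations.csv", manifest, stage)
            _write_csv(div.reset_index().rename(columns={"index": "origin"}),
                       out / "divergences.csv", manifest, stage)
            _write_csv(pd.DataFrame(
                [(r.origin, r.r_year, r.r_baseline, r.delta) for r in drur],
                columns=["origin", "r_year", "r_baseline", "delta"]),
                out / "delta_rurality.csv", manifest, stage)
            _write_csv(pd.DataFrame(
                [(x, w.value, w.coverage) for x, w in wdens.items()],
                columns=["origin", "weighted_density", "coverage"]),
                out / "weighted_attributes.csv", manifest, stage)
            _write_csv(gravity, out / "gravity.csv", manifest, stage)
            _write_csv(impact, out / "host_impact.csv", manifest, stage)
            _write_csv(binned, out / "decile_od.csv", manifest, stage, index=True)
            summary["mean_wasserstein"] = float(np.nanmean(div.to_numpy()))
            summary["retained_destinations"] = len(retained)
        else:
            manifest.setdefault(stage, [])
            logger.info("no baseline year: destinations stage skipped")
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ----- stage 5: mobility -----------------------------------------------
    stage = "mobility"
    try:
        base_homes = hm.baseline_homes(homes, baseline_week, comunas, n_weeks)
        series = mob.compute_mobility(events, antennas, base_homes,
                                      study_start, study_end, baseline_week,
                                      calendar)
        out_series = series.copy()
        out_series["date"] = pd.to_datetime(out_series["date"]).dt.date
        _write_csv(out_series, out / "mobility.csv", manifest, stage)
        qsum = mob.quarantine_summary(series)
        _write_csv(qsum, out / "quarantine_summary.csv", manifest, stage)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    # ----- stage 6: stratify -----------------------------------------------
    stage = "stratify"
    try:
        shock = (config.scenario.mobility_shock_date
                 if config.scenario is not None else study_start)
        post = series[series["date"] >= pd.Timestamp(shock)]
        per_comuna = post.groupby("comuna_id", observed=True)[
            "reduction_total_pp"].mean().rename("mean_reduction_pp")
        records = comunas.set_index("comuna_id")[["income_decile"]].join(
            per_comuna, how="inner").dropna()
        reg = strata.decile_outcome_regression(records, "mean_reduction_pp")
        tt = strata.rich_poor_ttest(records, "mean_reduction_pp",
                                    ap.rich_fraction)
        emi_records = comunas.set_index("comuna_id")[["income_decile"]].join(
            emi_pct.rename("emigration_pct"), how="inner").dropna()
        reg_emi = strata.decile_outcome_regression(emi_records, "emigration_pct")
        strat = {
            "mobility_reduction": {"regression": reg.__dict__,
                                   "rich_poor_ttest": tt.__dict__},
            "emigration_pct": {"regression": reg_emi.__dict__},
        }
        with open(out / "strata_summary.json", "w") as fh:
            json.dump(strat, fh, indent=2, sort_keys=True)
        _record(manifest, stage, out / "strata_summary.json", None)
        summary["reduction_vs_decile_r"] = reg.r
        summary["reduction_rich_poor_p"] = tt.p_value
        summary["emigration_vs_decile_r"] = reg_emi.r
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    if truth is not None:
        rec = truth.emigration.set_index("comuna_id")["realized_fraction"]
        est = (mig.emigration_percentage(od, mig.observed_devices(calls)) / 100.0)
        both = pd.concat([rec, est.rename("est")], axis=1).dropna()
        if len(both) >= 3:
            summary["emigration_recovery_r"] = float(
                np.corrcoef(both["realized_fraction"], both["est"])[0, 1])

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return {"manifest": manifest, "summary": summary}
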