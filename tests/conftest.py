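import datetime as dt

import numpy as np
import pandas as pd
import pytest

import migflow as mf


@pytest.fixture(scope="session")
def tiny_geo():
    """Hand-built two-region geography with controlled covariates.

    Region RA (focal, distance 0) holds comunas X and Y; region RB holds
    comunas Z and W. Each comuna has two antennas named <comuna>a/<comuna>b.
    """
    regions = pd.DataFrame({
        "region_id": ["RA", "RB"],
        "name": ["Focal", "Host"],
        "population": [20000, 8000],
        "distance_to_origin_km": [0.0, 400.0],
    })
    comunas = pd.DataFrame({
        "comuna_id": ["X", "Y", "Z", "W"],
        "region_id": ["RA", "RA", "RB", "RB"],
        "name": ["X", "Y", "Z", "W"],
        "population": [12000, 8000, 6000, 2000],
        "area_km2": [24.0, 40.0, 12.0, 100.0],
        "income_decile": [9.0, 3.0, 6.0, 2.0],
        "poverty_rate": [0.05, 0.25, 0.15, 0.35],
        "rural_fraction": [0.0, 0.1, 0.2, 0.6],
        "icvu": [80.0, 55.0, 70.0, np.nan],
        "centroid_lat": [-33.4, -33.5, -36.0, -36.1],
        "centroid_lon": [-70.6, -70.7, -72.0, -72.1],
    })
    comunas["density"] = comunas["population"] / comunas["area_km2"]
    antennas = pd.DataFrame({
        "antenna_id": ["Xa", "Xb", "Ya", "Yb", "Za", "Zb", "Wa", "Wb"],
        "lat": [-33.4] * 4 + [-36.0] * 4,
        "lon": [-70.6] * 4 + [-72.0] * 4,
        "comuna_id": ["X", "X", "Y", "Y", "Z", "Z", "W", "W"],
    })
    return mf.Geography(antennas=antennas, comunas=comunas, regions=regions,
                        focal_region_id="RA")


@pytest.fixture(scope="session")
def small_scenario():
    """A modest full-window scenario shared by cross-module tests."""
    cfg = mf.ScenarioConfig(n_devices=1500, rng_seed=11, noise_fraction=0.1)
    return mf.simulate_scenario(cfg)


@pytest.fixture(scope="session")
def small_homes(small_scenario):
    cfg = small_scenario.ground_truth.config
    return mf.weekly_homes(small_scenario.events,
                           small_scenario.geography.antennas,
                           cfg.study_start, cfg.study_end)


@pytest.fixture(scope="session")
def small_calls(small_scenario, small_homes):
    cfg = small_scenario.ground_truth.config
    return mf.call_migrations(small_homes, cfg.baseline_week,
                              cfg.november_weeks,
                              small_scenario.geography.comunas)


def events_frame(rows):
    """Build an XDR event frame from (device, iso-timestamp, antenna) rows."""
    return pd.DataFrame({
        "device_id": [r[0] for r in rows],
        "timestamp": pd.to_datetime([r[1] for r in rows]),
        "antenna_id": [r[2] for r in rows],
    })
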