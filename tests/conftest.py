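import numpy as np
import pandas as pd
import pytest

from pmexpo.config import CitySpec, GeneratorConfig
from pmexpo.trace_io import MINUTE_COLUMNS


def make_minutes(
    n,
    start="2021-09-06 00:00",
    pm25=10.0,
    pm10=20.0,
    lat=-15.8,
    lon=35.0,
    pm_valid=True,
    gps_valid=True,
    child_id=None,
):
    """Build a minute-record frame; scalar args broadcast, arrays pass through."""

    def col(v, dtype=float):
        arr = np.asarray(v)
        return np.full(n, v, dtype=dtype) if arr.ndim == 0 else arr

    pm_ok = col(pm_valid, bool)
    gps_ok = col(gps_valid, bool)
    df = pd.DataFrame({
        "minute_start": pd.date_range(start, periods=n, freq="min"),
        "pm25_mean": np.where(pm_ok, col(pm25), np.nan),
        "pm10_mean": np.where(pm_ok, col(pm10), np.nan),
        "lat": np.where(gps_ok, col(lat), np.nan),
        "lon": np.where(gps_ok, col(lon), np.nan),
        "n_samples_valid": np.where(pm_ok, 60, 0),
        "pm_valid": pm_ok,
        "gps_valid": gps_ok,
    })[MINUTE_COLUMNS]
    if child_id is not None:
        df.insert(0, "child_id", child_id)
    return df


@pytest.fixture
def minutes_factory():
    return make_minutes


def small_generator_config(**overrides) -> GeneratorConfig:
    base = dict(
        cities=[
            CitySpec(city_id="A", gm=30.0, gsd=1.6, n_children=2,
                     lat0=-15.8, lon0=35.0),
            CitySpec(city_id="B", gm=20.0, gsd=1.5, n_children=2,
                     lat0=-17.8, lon0=31.0),
        ],
        seed=0,
        gps_jitter_m=0.0,
        dropout_rate=0.0,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


@pytest.fixture
def gen_config_factory():
    return small_generator_config
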