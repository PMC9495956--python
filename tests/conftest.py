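import numpy as np
import pandas as pd
import pytest

import rotaclim.synthetic_climate as sc
from rotaclim.crop_model import load_default_params
from rotaclim.weather_core import DailySeries, StationMeta


@pytest.fixture(scope="session")
def hefei():
    """(StationMeta, ClimatologyModel) for the shipped Hefei-like station."""
    return sc.default_climatologies()["hefei"]


@pytest.fixture(scope="session")
def obs10(hefei):
    """Ten years of generated daily pseudo-observations (fixed seed)."""
    meta, clim = hefei
    return sc.generate_station_baseline(clim, meta, 10, seed=123, start_year=1981)


@pytest.fixture(scope="session")
def default_params():
    """(wheat, rice, soil, management) shipped defaults."""
    return load_default_params()


def make_series(station_id="t", latitude=32.0, start="2001-01-01", n=365, tmax=20.0,
                tmin=10.0, prec=0.0, rad=15.0):
    """Small constant (or array-valued) daily series for direct unit tests."""
    dates = pd.date_range(start, periods=n, freq="D")
    frame = pd.DataFrame(
        {
            "date": dates,
            "tmax": np.broadcast_to(np.asarray(tmax, dtype=float), n).copy(),
            "tmin": np.broadcast_to(np.asarray(tmin, dtype=float), n).copy(),
            "prec": np.broadcast_to(np.asarray(prec, dtype=float), n).copy(),
            "rad": np.broadcast_to(np.asarray(rad, dtype=float), n).copy(),
        }
    )
    meta = StationMeta(station_id=station_id, latitude=latitude)
    return DailySeries(station=meta, frame=frame)
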