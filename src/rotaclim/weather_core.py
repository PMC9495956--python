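"""Core station weather data model and radiation utilities.

Daily station weather (tmax, tmin, prec and either sunshine hours or global
radiation) is the common currency of the pipeline: the stochastic generator
produces it, the downscaler reconstructs it from monthly GCM output, and the
crop model consumes it.  This module holds the container types, the
Angstrom-Prescott conversion from sunshine hours to global radiation (with
coefficient calibration against observed radiation), standard solar geometry
(extraterrestrial radiation and astronomical day length, FAO-56 convention),
monthly aggregation, and growth-period summaries.

Units: temperatures degC, precipitation mm d-1, radiation MJ m-2 d-1,
sunshine hours h.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StationMeta",
    "AngstromCoefficients",
    "DailySeries",
    "MonthlySeries",
    "GrowthPeriodSummary",
    "SOLAR_CONSTANT_MJ_MIN",
    "extraterrestrial_radiation",
    "day_length",
    "angstrom_prescott",
    "calibrate_angstrom",
    "aggregate_monthly",
    "growth_period_summary",
    "read_daily_csv",
    "write_daily_csv",
    "read_met",
    "write_met",
    "WHEAT_WINDOW",
    "RICE_WINDOW",
]

#: Solar constant, MJ m-2 min-1 (FAO-56).
SOLAR_CONSTANT_MJ_MIN = 0.0820

#: Default growth-period windows ((start month, day), (end month, day)).
#: The wheat window spans the year boundary (sown mid-October, harvested
#: late May); seasons are labelled by harvest year.
WHEAT_WINDOW = ((10, 15), (5, 31))
RICE_WINDOW = ((6, 15), (10, 5))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StationMeta:
    """Identity and location of a weather station."""

    station_id: str
    name: str = ""
    latitude: float = 0.0
    longitude: float = 0.0
    elevation: float = 0.0

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if not math.isfinite(self.elevation):
            raise ValueError("elevation must be finite")


@dataclass(frozen=True)
class AngstromCoefficients:
    """Coefficients of the sunshine-to-radiation regression.

    ``rad = (a + b * n/N) * Ra`` where ``n`` is observed and ``N``
    astronomical sunshine duration and ``Ra`` extraterrestrial radiation.
    ``a`` is the overcast transmissivity, ``a + b`` the clear-sky one.
    """

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError("Angstrom coefficients must be positive")
        if self.a + self.b > 1.0 + 1e-12:
            raise ValueError("a + b must not exceed 1 (clear-sky transmissivity)")


_DAILY_COLUMNS = ["date", "tmax", "tmin", "prec", "sh", "rad"]


@dataclass
class DailySeries:
    """Contiguous daily weather record for one station.

    ``frame`` has columns date (datetime64), tmax, tmin, prec, sh, rad;
    sh/rad may be NaN when unavailable.  Dates must increase strictly by
    one day with no gaps.
    """

    station: StationMeta
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        missing = [c for c in ("date", "tmax", "tmin", "prec") if c not in f.columns]
        if missing:
            raise ValueError(f"DailySeries frame missing columns {missing}")
        f = f.copy()
        f["date"] = pd.to_datetime(f["date"])
        for c in ("sh", "rad"):
            if c not in f.columns:
                f[c] = np.nan
        self.frame = f[_DAILY_COLUMNS].reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        f = self.frame
        if len(f) == 0:
            raise ValueError("empty DailySeries")
        deltas = f["date"].diff().dropna()
        if len(deltas) and not (deltas == pd.Timedelta(days=1)).all():
            raise ValueError("dates must increase by exactly one day with no gaps")
        if (f["tmax"] < f["tmin"]).any():
            bad = f.loc[f["tmax"] < f["tmin"], "date"].iloc[0]
            raise ValueError(f"tmax < tmin on {bad.date()}")
        if (f["prec"] < 0).any():
            raise ValueError("negative precipitation")
        rad = f["rad"].dropna()
        if (rad < 0).any():
            raise ValueError("negative radiation")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def tmean(self) -> pd.Series:
        """Daily mean temperature, (tmax + tmin) / 2 by convention."""
        return (self.frame["tmax"] + self.frame["tmin"]) / 2.0

    def slice_dates(self, start: dt.date, end: dt.date) -> pd.DataFrame:
        f = self.frame
        m = (f["date"] >= pd.Timestamp(start)) & (f["date"] <= pd.Timestamp(end))
        return f.loc[m]

    def ensure_radiation(self, coeffs: AngstromCoefficients) -> "DailySeries":
        """Fill missing rad from sunshine hours via the Angstrom-Prescott law."""
        f = self.frame
        need = f["rad"].isna() & f["sh"].notna()
        if need.any():
            doy = f.loc[need, "date"].dt.dayofyear.to_numpy()
            ra = np.array([extraterrestrial_radiation(self.station.latitude, int(d)) for d in doy])
            nn = np.array([day_length(self.station.latitude, int(d)) for d in doy])
            sh = np.minimum(f.loc[need, "sh"].to_numpy(), nn)
            rad = np.where(nn > 0, (coeffs.a + coeffs.b * np.divide(sh, nn, out=np.zeros_like(sh), where=nn > 0)) * ra, coeffs.a * ra)
            self.frame.loc[need, "rad"] = rad
        return self


@dataclass
class MonthlySeries:
    """Per (year, month) summaries: tmax/tmin/rad means and prec totals."""

    station: StationMeta
    frame: pd.DataFrame  # columns: year, month, tmax, tmin, prec, rad

    def __post_init__(self) -> None:
        need = ["year", "month", "tmax", "tmin", "prec", "rad"]
        missing = [c for c in need if c not in self.frame.columns]
        if missing:
            raise ValueError(f"MonthlySeries frame missing columns {missing}")
        self.frame = self.frame[need].reset_index(drop=True)
        if (self.frame["prec"] < 0).any():
            raise ValueError("negative monthly precipitation total")
        if (self.frame["tmax"] < self.frame["tmin"]).any():
            raise ValueError("monthly tmax mean below tmin mean")


@dataclass(frozen=True)
class GrowthPeriodSummary:
    """Mean growth-window climate over the seasons present in a series."""

    crop: str
    tmax_mean: float
    tmin_mean: float
    prec_total: float
    rad_mean: float
    n_seasons: int

    def __post_init__(self) -> None:
        if self.prec_total < 0:
            raise ValueError("negative precipitation total")
        if self.tmax_mean < self.tmin_mean:
            raise ValueError("tmax_mean below tmin_mean")


# ---------------------------------------------------------------------------
# solar geometry (FAO-56 convention)
# ---------------------------------------------------------------------------


def _solar_angles(latitude: float, day_of_year: int) -> tuple[float, float, float]:
    if not -90.0 <= latitude <= 90.0:
        raise ValueError(f"latitude {latitude} outside [-90, 90]")
    if not 1 <= int(day_of_year) <= 366:
        raise ValueError(f"day_of_year {day_of_year} outside [1, 366]")
    j = int(day_of_year)
    phi = math.radians(latitude)
    decl = 0.409 * math.sin(2.0 * math.pi * j / 365.0 - 1.39)
    x = -math.tan(phi) * math.tan(decl)
    ws = math.acos(min(1.0, max(-1.0, x)))  # sunset hour angle; clipped for polar day/night
    return phi, decl, ws


def extraterrestrial_radiation(latitude: float, day_of_year: int) -> float:
    """Daily extraterrestrial radiation Ra (MJ m-2 d-1).

    Standard declination / sunset-hour-angle geometry with the FAO-56
    solar constant and eccentricity correction.  Returns 0 in polar night.
    """
    phi, decl, ws = _solar_angles(latitude, day_of_year)
    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi * int(day_of_year) / 365.0)
    ra = (24.0 * 60.0 / math.pi) * SOLAR_CONSTANT_MJ_MIN * dr * (
        ws * math.sin(phi) * math.sin(decl) + math.cos(phi) * math.cos(decl) * math.sin(ws)
    )
    return max(ra, 0.0)


def day_length(latitude: float, day_of_year: int) -> float:
    """Astronomical day length N (hours), in [0, 24]."""
    _, _, ws = _solar_angles(latitude, day_of_year)
    return 24.0 / math.pi * ws


def angstrom_prescott(n: float, N: float, coeffs: AngstromCoefficients, Ra: float) -> float:
    """Global radiation from sunshine fraction: ``(a + b * n/N) * Ra``.

    Polar night (N == 0) falls back to the overcast term ``a * Ra``.
    """
    if Ra < 0:
        raise ValueError("Ra must be nonnegative")
    if N == 0:
        return coeffs.a * Ra
    if n < 0 or n > N + 1e-9:
        raise ValueError(f"sunshine hours n={n} outside [0, N={N}]")
    return (coeffs.a + coeffs.b * min(n, N) / N) * Ra


def calibrate_angstrom(observed: Iterable[tuple[float, float, float, float]]) -> AngstromCoefficients:
    """Least-squares calibration of (a, b) from (n, N, Ra, rad_obs) tuples.

    Regresses the atmospheric transmissivity rad_obs/Ra on the sunshine
    fraction n/N; the intercept is ``a`` and the slope ``b``.
    """
    rows = list(observed)
    if len(rows) < 2:
        raise ValueError("need at least two observations")
    arr = np.asarray(rows, dtype=float)
    n, N, ra, rad = arr.T
    if (ra <= 0).any() or (N <= 0).any():
        raise ValueError("Ra and N must be positive for calibration")
    x = n / N
    y = rad / ra
    if np.ptp(x) < 1e-12:
        raise ValueError("all sunshine fractions identical: singular fit")
    b, a = np.polyfit(x, y, 1)
    return AngstromCoefficients(a=float(a), b=float(b))


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def aggregate_monthly(series: DailySeries, include_partial: bool = False) -> MonthlySeries:
    """Monthly tmax/tmin/rad means and prec totals.

    Partial months at the ends of the record are dropped unless
    ``include_partial`` is set.
    """
    f = series.frame
    g = f.groupby([f["date"].dt.year, f["date"].dt.month])
    out = g.agg(
        tmax=("tmax", "mean"),
        tmin=("tmin", "mean"),
        prec=("prec", "sum"),
        rad=("rad", "mean"),
        n=("date", "size"),
    )
    out.index.names = ["year", "month"]
    out = out.reset_index()
    if not include_partial:
        full = [
            pd.Period(year=int(y), month=int(m), freq="M").days_in_month == int(n)
            for y, m, n in zip(out["year"], out["month"], out["n"])
        ]
        out = out.loc[full]
    return MonthlySeries(station=series.station, frame=out.drop(columns="n"))


def _season_dates(year: int, start: tuple[int, int], end: tuple[int, int]) -> tuple[dt.date, dt.date]:
    """Window dates for the season *ending* in ``year`` (harvest-year label)."""
    sm, sd = start
    em, ed = end
    end_date = dt.date(year, em, ed)
    start_year = year if (sm, sd) <= (em, ed) else year - 1
    return dt.date(start_year, sm, sd), end_date


def growth_period_summary(
    series: DailySeries,
    start: tuple[int, int],
    end: tuple[int, int],
    crop: str,
) -> GrowthPeriodSummary:
    """Mean climate over a fixed calendar growth window, averaged over seasons.

    ``start``/``end`` are (month, day) pairs; the window may span the year
    boundary (a wheat season sown in October is labelled by harvest year).
    Seasons only partially covered by the record are skipped.
    """
    if start == end:
        raise ValueError("degenerate growth window: start == end")
    f = series.frame
    first, last = f["date"].iloc[0].date(), f["date"].iloc[-1].date()
    per_season = []
    for year in range(first.year, last.year + 2):
        s, e = _season_dates(year, start, end)
        if s < first or e > last:
            continue
        win = series.slice_dates(s, e)
        per_season.append(
            (
                win["tmax"].mean(),
                win["tmin"].mean(),
                win["prec"].sum(),
                win["rad"].mean(),
            )
        )
    if not per_season:
        raise ValueError("no complete growth-window season inside the series")
    arr = np.asarray(per_season, dtype=float)
    return GrowthPeriodSummary(
        crop=crop,
        tmax_mean=float(arr[:, 0].mean()),
        tmin_mean=float(arr[:, 1].mean()),
        prec_total=float(arr[:, 2].mean()),
        rad_mean=float(np.nanmean(arr[:, 3])),
        n_seasons=len(per_season),
    )


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------


def write_daily_csv(series: DailySeries, path) -> None:
    f = series.frame.copy()
    f.insert(0, "station_id", series.station.station_id)
    f["date"] = f["date"].dt.strftime("%Y-%m-%d")
    f.to_csv(path, index=False)


def read_daily_csv(path, station: StationMeta | None = None, coeffs: AngstromCoefficients | None = None) -> DailySeries:
    """Load a daily CSV (station_id, date, tmax, tmin, prec, sh, rad).

    When ``coeffs`` is given, missing radiation is reconstructed from
    sunshine hours on load.
    """
    f = pd.read_csv(path)
    if station is None:
        station = StationMeta(station_id=str(f["station_id"].iloc[0]))
    series = DailySeries(station=station, frame=f.drop(columns=["station_id"], errors="ignore"))
    if coeffs is not None:
        series.ensure_radiation(coeffs)
    return series


def write_met(series: DailySeries, path) -> None:
    """Write an APSIM-met-style whitespace table (year day radn maxt mint rain)."""
    f = series.frame
    with open(path, "w") as fh:
        fh.write(f"!station = {series.station.station_id}\n")
        fh.write(f"latitude = {series.station.latitude:.4f} (DECIMAL DEGREES)\n")
        fh.write("year day radn maxt mint rain\n")
        fh.write("() () (MJ/m^2) (oC) (oC) (mm)\n")
        for d, tmax, tmin, prec, rad in zip(
            f["date"], f["tmax"], f["tmin"], f["prec"], f["rad"]
        ):
            r = 0.0 if pd.isna(rad) else float(rad)
            fh.write(f"{d.year} {d.dayofyear} {r:.2f} {tmax:.2f} {tmin:.2f} {prec:.2f}\n")


def read_met(path, station: StationMeta | None = None) -> DailySeries:
    lat = 0.0
    rows = []
    with open(path) as fh:
        lines = fh.readlines()
    station_id = "met"
    data_started = False
    for line in lines:
        line = line.strip()
        if not line:
            continue
        if line.startswith("!station"):
            station_id = line.split("=", 1)[1].strip()
            continue
        if line.startswith("latitude"):
            lat = float(line.split("=", 1)[1].split()[0])
            continue
        parts = line.split()
        if parts[0] == "year" or parts[0] == "()":
            data_started = True if parts[0] == "()" else data_started
            continue
        rows.append([float(p) for p in parts])
    arr = np.asarray(rows)
    dates = [dt.date(int(y), 1, 1) + dt.timedelta(days=int(d) - 1) for y, d in arr[:, :2]]
    frame = pd.DataFrame(
        {
            "date": pd.to_datetime(dates),
            "tmax": arr[:, 3],
            "tmin": arr[:, 4],
            "prec": arr[:, 5],
            "rad": arr[:, 2],
        }
    )
    if station is None:
        station = StationMeta(station_id=station_id, latitude=lat)
    return DailySeries(station=station, frame=frame)
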