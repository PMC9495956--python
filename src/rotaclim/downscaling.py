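"""Two-step statistical downscaling: grid-to-station, then monthly-to-daily.

Spatial step: inverse-distance-weighted (IDW) interpolation of monthly GCM
grid values to the station location, followed by empirical quantile-quantile
bias correction fitted per variable and calendar month against the station's
observed monthly record over the baseline window (the correction is then
applied to both the baseline and the future windows, with constant-offset
extrapolation beyond the fitted tails).

Temporal step: a monthly-conditioned stochastic weather generator.  Daily
weather is sampled from the generator fitted to the station observations,
then adjusted so every month reproduces the bias-corrected monthly targets:
wet-day amounts are rescaled multiplicatively to the monthly total (exact to
rounding), temperatures are shifted additively, radiation is rescaled
multiplicatively, and tmax >= tmin is restored by capping tmin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .synthetic_climate import (
    ClimatologyModel,
    GCMGrid,
    fit_climatology,
    generate_months,
    substream,
)
from .weather_core import DailySeries, MonthlySeries, StationMeta, aggregate_monthly

__all__ = [
    "QQMap",
    "WGENParams",
    "DownscaledScenario",
    "idw_interpolate",
    "fit_qq_map",
    "apply_qq_map",
    "fit_wgen",
    "generate_daily_conditioned",
    "downscale_model",
]

_EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# spatial step
# ---------------------------------------------------------------------------


def great_circle_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Haversine distance in km."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlmb = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlmb / 2) ** 2
    return 2 * _EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def idw_interpolate(
    node_values: Sequence[tuple[float, float, float]],
    target: tuple[float, float],
    power: float = 2.0,
    k_neighbors: int = 4,
    eps_km: float = 1e-6,
) -> float:
    """Inverse-distance-weighted mean of the k nearest (lat, lon, value) nodes.

    Weights are proportional to distance**(-power) and sum to one; a node
    coinciding with the target (distance < ``eps_km``) is returned exactly.
    Equidistant nodes receive equal weights by construction.
    """
    nodes = list(node_values)
    if not nodes:
        raise ValueError("empty node list")
    if power <= 0:
        raise ValueError("power must be positive")
    tlat, tlon = target
    dists = np.array([great_circle_km(la, lo, tlat, tlon) for la, lo, _ in nodes])
    vals = np.array([v for _, _, v in nodes], dtype=float)
    hit = np.where(dists < eps_km)[0]
    if len(hit):
        return float(vals[hit[0]])
    k = min(int(k_neighbors), len(nodes))
    idx = np.argsort(dists, kind="stable")[:k]
    w = dists[idx] ** (-power)
    w = w / w.sum()
    return float(np.dot(w, vals[idx]))


@dataclass(frozen=True)
class QQMap:
    """Empirical quantile map for one variable and calendar month.

    ``model_q`` and ``obs_q`` are rank-paired sorted quantile vectors of the
    baseline-window model and observed monthly values.
    """

    variable: str
    month: int
    model_q: np.ndarray
    obs_q: np.ndarray

    def __post_init__(self) -> None:
        mq = np.asarray(self.model_q, dtype=float)
        oq = np.asarray(self.obs_q, dtype=float)
        if len(mq) != len(oq) or len(mq) < 2:
            raise ValueError("quantile vectors must share length K >= 2")
        if np.any(np.diff(mq) < -1e-12) or np.any(np.diff(oq) < -1e-12):
            raise ValueError("quantile vectors must be nondecreasing")
        object.__setattr__(self, "model_q", mq)
        object.__setattr__(self, "obs_q", oq)

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "month": int(self.month),
            "model_q": [float(x) for x in self.model_q],
            "obs_q": [float(x) for x in self.obs_q],
        }


def fit_qq_map(
    obs_values: Sequence[float],
    model_values: Sequence[float],
    variable: str,
    month: int,
    K: int = 30,
) -> QQMap:
    """Pair the K empirical quantiles of the two samples in rank order."""
    obs = np.asarray(obs_values, dtype=float)
    mod = np.asarray(model_values, dtype=float)
    k = min(int(K), len(obs), len(mod))
    if k < 2:
        raise ValueError("need at least 2 values per sample")
    probs = np.linspace(0.0, 1.0, k)
    return QQMap(
        variable=variable,
        month=int(month),
        model_q=np.quantile(mod, probs),
        obs_q=np.quantile(obs, probs),
    )


def apply_qq_map(qmap: QQMap, value):
    """Piecewise-linear corrected value(s); constant-offset tail extrapolation."""
    v = np.asarray(value, dtype=float)
    out = np.interp(v, qmap.model_q, qmap.obs_q)
    lo_off = qmap.obs_q[0] - qmap.model_q[0]
    hi_off = qmap.obs_q[-1] - qmap.model_q[-1]
    out = np.where(v < qmap.model_q[0], v + lo_off, out)
    out = np.where(v > qmap.model_q[-1], v + hi_off, out)
    return float(out) if np.isscalar(value) else out


# ---------------------------------------------------------------------------
# temporal step
# ---------------------------------------------------------------------------


class WGENParams(ClimatologyModel):
    """Weather-generator parameters (climatology plus correlation structure).

    The conditional wet/dry monthly moments, gamma amount parameters,
    Markov transition probabilities and lag-1 auto/cross-correlations all
    live in the shared :class:`ClimatologyModel` layout; the subclass marks
    the fitted-for-generation role and adds YAML round-tripping.
    """

    def to_yaml(self, path) -> None:
        payload = {
            "monthly": {c: [float(x) for x in self.monthly[c]] for c in self.monthly.columns},
            "autocorr": {k: float(v) for k, v in self.autocorr.items()},
            "cross_corr": np.asarray(self.cross_corr, dtype=float).tolist(),
            "trace": float(self.trace),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "WGENParams":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        monthly = pd.DataFrame(payload["monthly"])
        monthly.index = pd.RangeIndex(1, 13, name="month")
        return cls(
            monthly=monthly,
            autocorr=payload["autocorr"],
            cross_corr=np.asarray(payload["cross_corr"], dtype=float),
            trace=payload["trace"],
        )


def fit_wgen(series: DailySeries, trace: float = 0.1) -> WGENParams:
    """Fit generator parameters to a daily record."""
    clim = fit_climatology(series, trace=trace)
    return WGENParams(
        monthly=clim.monthly,
        autocorr=clim.autocorr,
        cross_corr=clim.cross_corr,
        trace=clim.trace,
    )


def generate_daily_conditioned(
    params: ClimatologyModel,
    target: MonthlySeries,
    seed,
    station: StationMeta | None = None,
) -> DailySeries:
    """Generate daily weather whose monthly aggregates match ``target``.

    Monthly precipitation totals match to rounding (multiplicative rescale
    of wet-day amounts; if the chain produces no wet day for a wet target
    month, one uniformly chosen day carries the full total).  Temperatures
    are shifted additively and radiation rescaled multiplicatively; tmin is
    then capped at tmax - 0.1 degC.
    """
    station = station or target.station
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tf = target.frame
    months = [(int(r.year), int(r.month)) for r in tf.itertuples()]
    raw, _ = generate_months(params, station, months, rng)
    ym = raw["date"].dt.year.to_numpy() * 100 + raw["date"].dt.month.to_numpy()

    pieces = []
    for r in tf.itertuples():
        seg = raw.loc[ym == int(r.year) * 100 + int(r.month)].copy()
        nd = len(seg)
        # precipitation: exact monthly total
        if r.prec <= 0:
            seg["prec"] = 0.0
        else:
            tot = seg["prec"].sum()
            if tot > 0:
                seg["prec"] *= r.prec / tot
            else:
                pos = int(rng.integers(nd))
                seg.iloc[pos, seg.columns.get_loc("prec")] = float(r.prec)
        # temperatures: additive shift to the target monthly means
        seg["tmax"] += r.tmax - seg["tmax"].mean()
        seg["tmin"] += r.tmin - seg["tmin"].mean()
        seg["tmin"] = np.minimum(seg["tmin"], seg["tmax"] - 0.1)
        # radiation: multiplicative rescale, floored at a small positive
        # value; the floored deficit is redistributed so the monthly mean
        # matches the target exactly
        floor = 0.05
        mu = seg["rad"].mean()
        vals = seg["rad"].to_numpy() * (r.rad / mu) if mu > 0 else np.full(nd, r.rad)
        for _ in range(8):
            low = vals < floor
            if not low.any() or low.all():
                break
            deficit = r.rad * nd - floor * low.sum()
            vals = np.where(low, floor, vals * deficit / vals[~low].sum())
        seg["rad"] = np.maximum(vals, floor)
        pieces.append(seg)
    frame = pd.concat(pieces, ignore_index=True).drop(columns="wet")
    frame["sh"] = np.nan
    return DailySeries(station=station, frame=frame)


# ---------------------------------------------------------------------------
# composed pipeline for one pseudo-model
# ---------------------------------------------------------------------------


@dataclass
class DownscaledScenario:
    """Daily baseline/future station weather downscaled from one model."""

    station: StationMeta
    model: str
    scenario: str
    baseline: DailySeries
    future: DailySeries
    provenance: dict = field(default_factory=dict)


def _idw_station_monthly(
    grid: GCMGrid, station: StationMeta, window: str, power: float, k_neighbors: int
) -> pd.DataFrame:
    """IDW per (year, month, variable) from grid nodes to the station point."""
    f = grid.node_monthly(window)
    lats = np.sort(f["node_lat"].unique())
    lons = np.sort(f["node_lon"].unique())
    # weights are identical for every month: precompute on the node layout
    nodes = [(la, lo) for la in lats for lo in lons]
    dists = np.array([great_circle_km(la, lo, station.latitude, station.longitude) for la, lo in nodes])
    hit = np.where(dists < 1e-6)[0]
    w = np.zeros(len(nodes))
    if len(hit):
        w[hit[0]] = 1.0
    else:
        k = min(k_neighbors, len(nodes))
        idx = np.argsort(dists, kind="stable")[:k]
        ww = dists[idx] ** (-power)
        w[idx] = ww / ww.sum()
    key = pd.MultiIndex.from_tuples(nodes, names=["node_lat", "node_lon"])
    out = []
    for (year, month), g in f.groupby(["year", "month"]):
        g = g.set_index(["node_lat", "node_lon"]).reindex(key)
        row = {"year": int(year), "month": int(month)}
        for v in ("tmax", "tmin", "prec", "rad"):
            row[v] = float(np.dot(w, g[v].to_numpy()))
        out.append(row)
    return pd.DataFrame(out).sort_values(["year", "month"]).reset_index(drop=True)


def downscale_model(
    grid: GCMGrid,
    station: StationMeta,
    obs: DailySeries,
    seed,
    power: float = 2.0,
    k_neighbors: int = 4,
    K: int = 30,
    wgen: WGENParams | None = None,
) -> DownscaledScenario:
    """Full chain for one pseudo-model: IDW -> qq correction -> daily generation.

    Quantile maps are fitted between the model's baseline-window station
    monthlies and the observed monthlies, then applied to both windows.  The
    same generator substream is used for both windows so identical monthly
    targets yield identical daily series (paired windows).
    """
    obs_monthly = aggregate_monthly(obs)
    wgen = wgen or fit_wgen(obs)

    station_m = {
        w: _idw_station_monthly(grid, station, w, power, k_neighbors)
        for w in ("baseline", "future")
    }
    qmaps = {}
    for v in ("tmax", "tmin", "prec", "rad"):
        for m in range(1, 13):
            obs_vals = obs_monthly.frame.loc[obs_monthly.frame["month"] == m, v]
            mod_vals = station_m["baseline"].loc[station_m["baseline"]["month"] == m, v]
            qmaps[(v, m)] = fit_qq_map(obs_vals, mod_vals, v, m, K=K)

    corrected = {}
    for w, f in station_m.items():
        f = f.copy()
        for v in ("tmax", "tmin", "prec", "rad"):
            for m in range(1, 13):
                sel = f["month"] == m
                f.loc[sel, v] = apply_qq_map(qmaps[(v, m)], f.loc[sel, v].to_numpy())
        f["prec"] = f["prec"].clip(lower=0.0)
        f["rad"] = f["rad"].clip(lower=0.1)
        f["tmin"] = np.minimum(f["tmin"], f["tmax"] - 0.2)
        corrected[w] = MonthlySeries(station=station, frame=f)

    series = {}
    for w in ("baseline", "future"):
        rng = substream(seed, "wgen", station.station_id, grid.scenario, grid.model)
        series[w] = generate_daily_conditioned(wgen, corrected[w], rng, station=station)

    return DownscaledScenario(
        station=station,
        model=grid.model,
        scenario=grid.scenario,
        baseline=series["baseline"],
        future=series["future"],
        provenance={
            "seed": int(seed) if np.isscalar(seed) else None,
            "idw": {"power": power, "k_neighbors": k_neighbors},
            "qq_knots": K,
            "model_bias": grid.bias,
            "model_deltas": grid.deltas,
        },
    )
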