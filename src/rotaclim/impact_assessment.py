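"""Ensemble experiment, change statistics and attribution regressions.

Runs the baseline/future rotation experiment for every downscaled
station x scenario x pseudo-model combination, tabulates future-minus-
baseline changes of the climate drivers and crop outcomes
(:class:`EnsembleChange` rows), summarizes them across the ensemble with
box-plot statistics (10th/25th/median/75th/90th percentiles, mean), and
fits the no-intercept multiple regressions

    dY = a*dTmean + b*dRad + c*dPre + d*dCO2

for dYield, dET and dWUE per crop, with per-coefficient two-sided t-tests
and the uncentered R2 appropriate for a model without an intercept.  A sign
report compares the significant fitted signs against the expected
qualitative pattern (yield: -Tmean +Rad +Pre +CO2; ET: +Rad -CO2;
WUE: -Tmean +CO2).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .co2_scenarios import CO2Trajectory
from .crop_model import (
    CropParams,
    ManagementParams,
    SoilParams,
    simulate_rotation,
)
from .downscaling import DownscaledScenario
from .weather_core import DailySeries, growth_period_summary

__all__ = [
    "EnsembleChange",
    "BoxStats",
    "RegressionResult",
    "run_experiment",
    "ensemble_box_stats",
    "delta_regression",
    "sign_pattern_report",
    "EXPECTED_SIGNS",
]

CHANGE_COLUMNS = [
    "station", "scenario", "model", "crop",
    "d_tmean", "d_rad", "d_prec", "d_co2",
    "d_fd", "d_md", "d_rgp",
    "d_yield", "d_yield_pct", "d_et", "d_wue",
    "baseline_yield", "baseline_et", "baseline_wue",
    "excluded",
]

#: Qualitative sign pattern the attribution regressions are compared with
#: (only cells with an expectation are scored; +1 positive, -1 negative).
EXPECTED_SIGNS: dict[str, dict[str, int]] = {
    "yield": {"d_tmean": -1, "d_rad": +1, "d_prec": +1, "d_co2": +1},
    "et": {"d_rad": +1, "d_co2": -1},
    "wue": {"d_tmean": -1, "d_co2": +1},
}

_PREDICTORS = ["d_tmean", "d_rad", "d_prec", "d_co2"]


@dataclass(frozen=True)
class EnsembleChange:
    """One station x scenario x model x crop row of future-baseline deltas."""

    station: str
    scenario: str
    model: str
    crop: str
    d_tmean: float
    d_rad: float
    d_prec: float
    d_co2: float
    d_fd: float
    d_md: float
    d_rgp: float
    d_yield: float
    d_yield_pct: float
    d_et: float
    d_wue: float
    baseline_yield: float
    baseline_et: float
    baseline_wue: float
    excluded: bool = False


@dataclass(frozen=True)
class BoxStats:
    """Box-plot summary across the model ensemble."""

    mean: float
    median: float
    p10: float
    p25: float
    p75: float
    p90: float

    def __post_init__(self) -> None:
        order = (self.p10, self.p25, self.median, self.p75, self.p90)
        if any(a > b + 1e-12 for a, b in zip(order, order[1:])):
            raise ValueError("percentiles must be nondecreasing")


@dataclass
class RegressionResult:
    """No-intercept OLS attribution fit for one response and crop."""

    response: str
    crop: str
    coefficients: dict
    pvalues: dict
    stars: dict
    r_squared: float
    n: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("R2 outside [0, 1]")
        for k, p in self.pvalues.items():
            want = "**" if p < 0.01 else ("*" if p < 0.05 else "")
            if self.stars[k] != want:
                raise ValueError("significance flags inconsistent with p-values")


# ---------------------------------------------------------------------------
# experiment
# ---------------------------------------------------------------------------


def _season_stats(results, crop: str) -> dict | None:
    ok = [r for r in results if r.crop == crop and not r.failed]
    total = [r for r in results if r.crop == crop]
    if not total:
        return None
    frac_failed = 1.0 - len(ok) / len(total)
    if not ok:
        return {"failed_frac": 1.0}
    return {
        "failed_frac": frac_failed,
        "fd": float(np.mean([r.flowering_date.timetuple().tm_yday for r in ok])),
        "md": float(np.mean([r.maturity_date.timetuple().tm_yday for r in ok])),
        "rgp": float(np.mean([r.rgp_days for r in ok])),
        "yield": float(np.mean([r.yield_kg_ha for r in ok])),
        "et": float(np.mean([r.et_mm for r in ok])),
        "wue": float(np.mean([r.wue for r in ok])),
    }


def _climate_deltas(
    baseline: DailySeries, future: DailySeries, window: tuple | None
) -> tuple[float, float, float]:
    """(dTmean, dRad, dPre) over a growth window or the whole record."""

    def stats(series: DailySeries):
        if window is None:
            f = series.frame
            years = max(1, round(len(f) / 365.25))
            return (
                float(((f["tmax"] + f["tmin"]) / 2).mean()),
                float(f["rad"].mean()),
                float(f["prec"].sum() / years),
            )
        s = growth_period_summary(series, window[0], window[1], crop="win")
        return ((s.tmax_mean + s.tmin_mean) / 2, s.rad_mean, s.prec_total)

    b = stats(baseline)
    fu = stats(future)
    return fu[0] - b[0], fu[1] - b[1], fu[2] - b[2]


def run_experiment(
    downscaled: Sequence[DownscaledScenario],
    co2_trajectories: Mapping[str, CO2Trajectory],
    wheat: CropParams,
    rice: CropParams,
    soil: SoilParams,
    mgmt: ManagementParams | None = None,
    max_failed_frac: float = 0.2,
) -> pd.DataFrame:
    """Simulate both windows for every downscaled scenario and tabulate deltas.

    Returns one row per station x scenario x model x crop (wheat, rice and
    their total).  Baseline runs read the historical portion of the CO2
    trajectory, future runs the projection portion; climate deltas use each
    crop's growth window (annual values for the total rows).  Cells whose
    failed-season fraction exceeds ``max_failed_frac`` are flagged
    ``excluded`` (they stay in the table but drop out of the regressions).
    """
    mgmt = mgmt or ManagementParams()
    windows = {
        "wheat": ((mgmt.wheat_sow), (5, 31)),
        "rice": ((mgmt.rice_sow), (10, 5)),
        "total": None,
    }
    rows = []
    for ds in downscaled:
        traj = co2_trajectories[ds.scenario]
        co2 = {int(y): float(p) for y, p in zip(traj.years, traj.ppm)}

        per_window = {}
        for wname, series in (("baseline", ds.baseline), ("future", ds.future)):
            results, annual = simulate_rotation(series, co2, wheat, rice, soil, mgmt)
            per_window[wname] = {
                "wheat": _season_stats(results, "wheat"),
                "rice": _season_stats(results, "rice"),
                "annual": annual,
            }

        def years_of(series: DailySeries) -> tuple[int, int]:
            y = series.frame["date"].dt.year
            return int(y.iloc[0]), int(y.iloc[-1])

        b0, b1 = years_of(ds.baseline)
        f0, f1 = years_of(ds.future)
        d_co2 = traj.mean(f0, f1) - traj.mean(b0, b1)

        for crop in ("wheat", "rice", "total"):
            d_t, d_r, d_p = _climate_deltas(ds.baseline, ds.future, windows[crop])
            if crop == "total":
                ab = per_window["baseline"]["annual"]
                af = per_window["future"]["annual"]
                if len(ab) == 0 or len(af) == 0:
                    continue
                by, be, bw = ab["yield_kg_ha"].mean(), ab["et_mm"].mean(), ab["wue"].mean()
                fy, fe, fw = af["yield_kg_ha"].mean(), af["et_mm"].mean(), af["wue"].mean()
                excluded = False
                row = dict(
                    d_fd=np.nan, d_md=np.nan, d_rgp=np.nan,
                    d_yield=fy - by, d_yield_pct=100.0 * (fy - by) / by,
                    d_et=fe - be, d_wue=fw - bw,
                    baseline_yield=by, baseline_et=be, baseline_wue=bw,
                )
            else:
                sb = per_window["baseline"][crop]
                sf = per_window["future"][crop]
                if sb is None or sf is None:
                    continue
                excluded = (
                    sb.get("failed_frac", 1.0) > max_failed_frac
                    or sf.get("failed_frac", 1.0) > max_failed_frac
                    or "yield" not in sb
                    or "yield" not in sf
                )
                if excluded:
                    row = dict(
                        d_fd=np.nan, d_md=np.nan, d_rgp=np.nan, d_yield=np.nan,
                        d_yield_pct=np.nan, d_et=np.nan, d_wue=np.nan,
                        baseline_yield=np.nan, baseline_et=np.nan, baseline_wue=np.nan,
                    )
                else:
                    row = dict(
                        d_fd=sf["fd"] - sb["fd"], d_md=sf["md"] - sb["md"],
                        d_rgp=sf["rgp"] - sb["rgp"],
                        d_yield=sf["yield"] - sb["yield"],
                        d_yield_pct=100.0 * (sf["yield"] - sb["yield"]) / sb["yield"],
                        d_et=sf["et"] - sb["et"], d_wue=sf["wue"] - sb["wue"],
                        baseline_yield=sb["yield"], baseline_et=sb["et"],
                        baseline_wue=sb["wue"],
                    )
            rows.append(
                dict(
                    station=ds.station.station_id, scenario=ds.scenario,
                    model=ds.model, crop=crop,
                    d_tmean=d_t, d_rad=d_r, d_prec=d_p, d_co2=d_co2,
                    excluded=excluded, **row,
                )
            )
    return pd.DataFrame(rows, columns=CHANGE_COLUMNS)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def ensemble_box_stats(
    changes: pd.DataFrame,
    value: str,
    grouping: Sequence[str] = ("station", "scenario", "crop"),
) -> pd.DataFrame:
    """Box-plot statistics of one delta column across the model dimension.

    Percentiles use the linear-interpolation convention.
    """
    out = []
    for key, g in changes.groupby(list(grouping)):
        v = g[value].dropna().to_numpy(dtype=float)
        if len(v) == 0:
            continue
        p10, p25, p50, p75, p90 = np.percentile(v, [10, 25, 50, 75, 90])
        bs = BoxStats(mean=float(v.mean()), median=float(p50), p10=float(p10),
                      p25=float(p25), p75=float(p75), p90=float(p90))
        key = key if isinstance(key, tuple) else (key,)
        out.append({**dict(zip(grouping, key)), "n": len(v), **bs.__dict__})
    return pd.DataFrame(out)


def delta_regression(
    changes: pd.DataFrame,
    response: str,
    crop: str,
    intercept: bool = False,
    min_rows: int = 10,
) -> RegressionResult:
    """No-intercept OLS of a change column on the four climate deltas.

    Pools stations x scenarios x models for the given crop.  R2 is the
    uncentered (about-zero) coefficient of determination matching the
    no-intercept model; ``intercept=True`` is available for sensitivity.
    """
    col = {"yield": "d_yield", "et": "d_et", "wue": "d_wue"}.get(response, response)
    sub = changes.loc[(changes["crop"] == crop) & (~changes["excluded"])].dropna(subset=[col] + _PREDICTORS)
    if len(sub) < min_rows:
        raise ValueError(f"only {len(sub)} usable rows for {response}/{crop}; need >= {min_rows}")
    X = sub[_PREDICTORS].to_numpy(dtype=float)
    names = list(_PREDICTORS)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        bad = [
            names[j]
            for j in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == np.linalg.matrix_rank(X)
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {bad or names}")
    exog = sm.add_constant(X) if intercept else X
    fit = sm.OLS(sub[col].to_numpy(dtype=float), exog).fit()
    offset = 1 if intercept else 0
    coefs = {n: float(fit.params[offset + j]) for j, n in enumerate(names)}
    pvals = {n: float(fit.pvalues[offset + j]) for j, n in enumerate(names)}
    stars = {n: "**" if p < 0.01 else ("*" if p < 0.05 else "") for n, p in pvals.items()}
    return RegressionResult(
        response=response, crop=crop, coefficients=coefs, pvalues=pvals,
        stars=stars, r_squared=float(fit.rsquared), n=int(len(sub)),
    )


def sign_pattern_report(results: Sequence[RegressionResult], alpha: float = 0.05) -> pd.DataFrame:
    """Compare significant fitted coefficient signs against the expected pattern.

    Returns one row per (response, crop, predictor) with status ``match``,
    ``mismatch`` or ``not-significant``; cells without an expectation are
    skipped.
    """
    rows = []
    for res in results:
        expected = EXPECTED_SIGNS.get(res.response, {})
        for pred, sign in expected.items():
            p = res.pvalues[pred]
            coef = res.coefficients[pred]
            if p >= alpha:
                status = "not-significant"
            else:
                status = "match" if np.sign(coef) == sign else "mismatch"
            rows.append(
                dict(response=res.response, crop=res.crop, predictor=pred,
                     coefficient=coef, pvalue=p, expected_sign=sign, status=status)
            )
    return pd.DataFrame(rows)
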