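"""Synthetic inputs with the statistical structure the analysis assumes.

The published study region (Guizhou) prints only two survey years of
land-use areas and the ranges of its socioeconomic drivers; the annual
panels behind the forecasts are unpublished.  This module generates
substitutes with the right structure so every pipeline stage is testable:

* closure-constrained annual land-use series interpolating geometrically
  between the two printed survey years (geometric, because the grey
  forecast's response is exponential — generator and model share a family,
  which makes recovery tests meaningful), with optional multiplicative
  lognormal noise applied before each year is rescaled proportionally to
  the territory total;
* exact GM(1,1) response sequences, generated by the model's own
  recursion so that fitting recovers the generating (a, u) to machine
  precision;
* monotone driver trajectories inside the published ranges (the
  afforestation programme, a policy series, may instead fluctuate
  uniformly within its range).

All randomness flows from the explicit integer seed in the scenario spec;
the same spec always yields the same data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from . import guizhou
from .grey_forecast import ago  # noqa: F401  (re-exported convenience)
from .grey_relational import DriverSeries
from .valuation import LandUseSeries, ValueCoefficientMatrix

__all__ = [
    "DriverSpec",
    "ScenarioSpec",
    "StudyFixture",
    "default_scenario",
    "gm11_exact_series",
    "generate_land_use_series",
    "generate_driver_series",
    "make_study_fixture",
]


def gm11_exact_series(
    a: float, u: float, x1: float, n: int, a_epsilon: float = 1e-12
) -> np.ndarray:
    """A series on which GM(1,1) fitting is exact.

    Generated by the model's own background-value recursion
    ``x0(k) = (u - a * X(k-1)) / (1 + a/2)`` (X the accumulated series,
    X(1) = x1), so the least-squares fit recovers (a, u) to machine
    precision and the restored series reproduces the data with zero
    residual.  For |a| < ``a_epsilon`` the limiting form gives the
    constant continuation x0(k) = u.
    """
    if n < 4:
        raise ValueError(f"need n >= 4, got {n}")
    if abs(a) >= 2.0:
        raise ValueError(f"development coefficient must satisfy |a| < 2, got {a}")
    x0 = np.empty(n, dtype=float)
    x0[0] = x1
    acc = float(x1)
    for k in range(1, n):
        if abs(a) < a_epsilon:
            value = u
        else:
            value = (u - a * acc) / (1.0 + a / 2.0)
        x0[k] = value
        acc += value
    if np.any(x0 <= 0):
        raise ValueError(
            f"parameters (a={a}, u={u}, x1={x1}, n={n}) produce non-positive values"
        )
    return x0


@dataclass(frozen=True)
class DriverSpec:
    """Trajectory recipe for one driving factor."""

    start: float
    end: float
    noise_cv: float = 0.0
    #: "geometric" | "linear" monotone trends, or "uniform" (fluctuating
    #: anywhere inside ``bounds``; used for policy series)
    shape: str = "geometric"
    #: admissible (low, high) range; start/end must fall inside
    bounds: tuple[float, float] | None = None

    def validate(self, name: str) -> None:
        if self.shape not in ("geometric", "linear", "uniform"):
            raise ValueError(f"driver {name}: unknown shape {self.shape!r}")
        if self.noise_cv < 0:
            raise ValueError(f"driver {name}: noise_cv must be >= 0")
        if self.bounds is not None:
            lo, hi = self.bounds
            for label, v in (("start", self.start), ("end", self.end)):
                if not lo <= v <= hi:
                    raise ValueError(
                        f"driver {name}: {label}={v} outside declared range [{lo}, {hi}]"
                    )
        if self.shape == "geometric" and (self.start <= 0 or self.end <= 0):
            raise ValueError(f"driver {name}: geometric shape needs positive endpoints")


@dataclass(frozen=True)
class ScenarioSpec:
    """Full recipe for one synthetic study: land-use endpoints + drivers."""

    first_year: int
    n_years: int
    territory_total: float
    start_areas: Mapping[str, float]
    end_areas: Mapping[str, float]
    noise_cv: float = 0.0
    driver_specs: Mapping[str, DriverSpec] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_years < 4:
            raise ValueError("n_years must be >= 4 (grey models need 4 points)")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        for label, areas in (("start", self.start_areas), ("end", self.end_areas)):
            if set(areas) != set(self.start_areas):
                raise ValueError("start and end areas must cover the same categories")
            if any(v < 0 for v in areas.values()):
                raise ValueError(f"{label} areas must be non-negative")
            total = sum(areas.values())
            if abs(total - self.territory_total) > 1e-6 * self.territory_total:
                raise ValueError(
                    f"{label} areas sum to {total}, not the territory total "
                    f"{self.territory_total}"
                )
        for name, spec in self.driver_specs.items():
            spec.validate(name)

    @property
    def years(self) -> list[int]:
        return list(range(self.first_year, self.first_year + self.n_years))


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log(1.0 + cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def _interpolate(start: float, end: float, n: int, shape: str) -> np.ndarray:
    t = np.linspace(0.0, 1.0, n)
    if shape == "geometric" and start > 0 and end > 0:
        return start * (end / start) ** t
    return start + (end - start) * t


def generate_land_use_series(spec: ScenarioSpec) -> LandUseSeries:
    """Annual land-use areas between the scenario endpoints, closed exactly.

    Each category follows a constant-annual-rate (geometric) path between
    its endpoints; categories with a zero endpoint fall back to linear.
    Multiplicative lognormal noise (``spec.noise_cv``) is applied before
    each year's column is rescaled proportionally so the total equals the
    territory total exactly.  With ``noise_cv = 0`` the first and last
    columns equal the endpoints exactly.
    """
    rng = np.random.default_rng([int(spec.seed) % 2**31, 101])
    categories = list(spec.start_areas)
    grid = np.vstack(
        [
            _interpolate(
                float(spec.start_areas[c]), float(spec.end_areas[c]), spec.n_years,
                "geometric",
            )
            for c in categories
        ]
    )
    grid = grid * _lognormal_factors(rng, spec.noise_cv, grid.shape)
    sums = grid.sum(axis=0)
    grid = grid * (spec.territory_total / sums)
    df = pd.DataFrame(grid, index=categories, columns=spec.years)
    return LandUseSeries(areas=df, territory_total=spec.territory_total)


def generate_driver_series(spec: ScenarioSpec) -> DriverSeries:
    """Driver trajectories per the scenario's :class:`DriverSpec` recipes."""
    rng = np.random.default_rng([int(spec.seed) % 2**31, 202])
    rows: dict[str, np.ndarray] = {}
    for name, d in spec.driver_specs.items():
        if d.shape == "uniform":
            lo, hi = d.bounds if d.bounds else (min(d.start, d.end), max(d.start, d.end))
            values = rng.uniform(lo, hi, spec.n_years)
        else:
            values = _interpolate(d.start, d.end, spec.n_years, d.shape)
            values = values * _lognormal_factors(rng, d.noise_cv, spec.n_years)
        rows[name] = values
    df = pd.DataFrame(rows).T
    df.columns = spec.years
    return DriverSeries(values=df)


def default_scenario(seed: int = 0, noise_cv: float = 0.01) -> ScenarioSpec:
    """The packaged study scenario: ten annual surveys (2009-2018) between
    the published Guizhou endpoints, 1% multiplicative noise, and driver
    trajectories spanning the published ranges (afforestation fluctuates
    uniformly, as policy series do)."""
    r = guizhou.DRIVER_RANGES
    drivers = {
        "TP": DriverSpec(r["TP"]["low"], r["TP"]["high"], noise_cv,
                         "geometric", (r["TP"]["low"], r["TP"]["high"])),
        "UL": DriverSpec(r["UL"]["low"], r["UL"]["high"], noise_cv,
                         "linear", (r["UL"]["low"], r["UL"]["high"])),
        "GDP": DriverSpec(r["GDP"]["low"], r["GDP"]["high"], noise_cv,
                          "geometric", (r["GDP"]["low"], r["GDP"]["high"])),
        "SIP": DriverSpec(r["SIP"]["high"], r["SIP"]["low"], noise_cv,
                          "linear", (r["SIP"]["low"], r["SIP"]["high"])),
        "TIP": DriverSpec(r["TIP"]["low"], r["TIP"]["high"], noise_cv,
                          "linear", (r["TIP"]["low"], r["TIP"]["high"])),
        "TIFA": DriverSpec(r["TIFA"]["low"], r["TIFA"]["high"], noise_cv,
                           "geometric", (r["TIFA"]["low"], r["TIFA"]["high"])),
        "AP": DriverSpec(r["AP"]["low"], r["AP"]["high"], 0.0,
                         "uniform", (r["AP"]["low"], r["AP"]["high"])),
    }
    return ScenarioSpec(
        first_year=guizhou.STUDY_YEARS[0],
        n_years=guizhou.STUDY_YEARS[1] - guizhou.STUDY_YEARS[0] + 1,
        territory_total=guizhou.TERRITORY_HM2,
        start_areas=dict(guizhou.AREAS_2009),
        end_areas=dict(guizhou.AREAS_2018),
        noise_cv=noise_cv,
        driver_specs=drivers,
        seed=int(seed),
    )


@dataclass(frozen=True)
class StudyFixture:
    """The published study tables, packaged and consistency-checked."""

    vc: ValueCoefficientMatrix
    #: the two published survey years only (2009, 2018)
    areas: LandUseSeries
    scenario: ScenarioSpec
    driver_ranges: dict[str, dict[str, float]]


def make_study_fixture(seed: int = 0, noise_cv: float = 0.01) -> StudyFixture:
    """Package the published Guizhou tables as verified fixtures.

    The coefficient matrix is cross-checked against the published column
    totals (to 0.01 CNY) and the survey areas against the territory total
    before being returned; a transcription error raises immediately.
    """
    vc = ValueCoefficientMatrix.from_records(guizhou.VALUE_COEFFICIENTS)
    totals = vc.column_totals()
    for cat, stated in guizhou.PUBLISHED_COLUMN_TOTALS.items():
        if abs(totals[cat] - stated) > 0.01:
            raise AssertionError(
                f"transcribed coefficients for {cat} sum to {totals[cat]}, "
                f"published total is {stated}"
            )
    areas = LandUseSeries(
        areas=pd.DataFrame(
            {
                guizhou.STUDY_YEARS[0]: guizhou.AREAS_2009,
                guizhou.STUDY_YEARS[1]: guizhou.AREAS_2018,
            }
        ),
        territory_total=guizhou.TERRITORY_HM2,
    )
    sums = areas.areas.sum(axis=0)
    # the published 2018 column sums to one hm2 under the territory total
    # (rounding in the printed survey figures); tolerate exactly that
    if (sums - guizhou.TERRITORY_HM2).abs().max() > 1.0:
        raise AssertionError("transcribed survey areas do not close on the territory")
    return StudyFixture(
        vc=vc,
        areas=areas,
        scenario=default_scenario(seed=seed, noise_cv=noise_cv),
        driver_ranges={k: dict(v) for k, v in guizhou.DRIVER_RANGES.items()},
    )
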