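"""GM(1,1) grey forecasting of short positive time series.

Grey models forecast from very few observations (here, ten annual land-use
surveys) by smoothing the original series x0 with the accumulated
generating operation (AGO, a running cumulative sum) and fitting the grey
differential equation

    dx1/dt + a * x1 = u

where ``a`` is the development coefficient (per step) and ``u`` the grey
action quantity.  The equation is discretized at the background values
z1(k) = (x1(k) + x1(k-1)) / 2 and (a, u) are estimated by least squares on
the n-1 stacked equations x0(k) = -a z1(k) + u.

Restoration and forecasting evaluate a time response for x1 and difference
it back (inverse AGO).  Two response forms are provided:

* ``"discrete"`` (default): x1(k) = (x0(1) - u/a) * beta^(k-1) + u/a with
  beta = (1 - a/2)/(1 + a/2) — the exact solution of the fitted difference
  system.  With this form the model reproduces, without bias, any series
  generated by its own recursion (in particular geometric series), which
  makes parameter-recovery tests exact.
* ``"continuous"``: the classical whitenization response
  x1(k) = (x0(1) - u/a) * exp(-a (k-1)) + u/a.

The two agree to O(a^2) per step; land-use development coefficients are
small (|a| well below 0.1) so the practical difference is negligible.
When |a| falls below ``a_epsilon`` the limiting linear response
x1(k) = x0(1) + u (k-1) is used (constant-series case).

Model adequacy is graded by the posterior-difference test: C = S2/S1
(residual vs data spread) and P, the share of residuals within 0.6745 S1
of the mean residual; C < 0.35 and P >= 0.95 is grade 1 (good).

For a multi-category land-use table under a fixed territory total, every
category but one is forecast by its own GM(1,1) and the remaining
"closure" category absorbs the residual area, so forecast years close
exactly on the territory total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .valuation import (
    ESVAccount,
    LandUseSeries,
    ValueCoefficientMatrix,
    canonical_category,
    compute_esv,
)

__all__ = [
    "AccuracyReport",
    "GM11Model",
    "ForecastResult",
    "ago",
    "fit_gm11",
    "forecast",
    "predict_at_steps",
    "posterior_error_test",
    "forecast_land_use",
    "forecast_structure",
    "forecast_esv",
]


def ago(x0: Sequence[float]) -> np.ndarray:
    """Accumulated generating operation: running cumulative sum of x0."""
    x0 = np.asarray(x0, dtype=float)
    if x0.size == 0:
        raise ValueError("cannot accumulate an empty series")
    if not np.all(np.isfinite(x0)):
        raise ValueError("series contains non-finite entries")
    return np.cumsum(x0)


@dataclass(frozen=True)
class GM11Model:
    """A fitted GM(1,1) model.

    ``fitted`` is the restored in-sample series (fitted[0] = x0[0] by
    construction, hence residuals[0] = 0).
    """

    x0: np.ndarray
    x1: np.ndarray
    z1: np.ndarray
    a: float
    u: float
    fitted: np.ndarray
    residuals: np.ndarray
    response: str = "discrete"
    a_epsilon: float = 1e-12

    @property
    def n(self) -> int:
        return int(self.x0.size)


def _x1_response(
    a: float, u: float, x0_first: float, k: np.ndarray, response: str, a_epsilon: float
) -> np.ndarray:
    """Evaluate the accumulated-series time response at 1-based steps k."""
    k = np.asarray(k, dtype=float)
    if abs(a) < a_epsilon:
        return x0_first + u * (k - 1.0)
    if response == "discrete":
        beta = (1.0 - a / 2.0) / (1.0 + a / 2.0)
        return (x0_first - u / a) * beta ** (k - 1.0) + u / a
    return (x0_first - u / a) * np.exp(-a * (k - 1.0)) + u / a


def fit_gm11(
    x0: Sequence[float], response: str = "discrete", a_epsilon: float = 1e-12
) -> GM11Model:
    """Fit GM(1,1) to a positive series of length >= 4.

    Least squares on the background-value equations is solved with a
    stable factorization (``numpy.linalg.lstsq``), never an explicit
    inverse.  The discrete response requires |a| < 2; should a fit land
    outside that region (wildly non-grey data) the continuous response is
    used instead, with a warning.
    """
    x0 = np.asarray(x0, dtype=float)
    if x0.size < 4:
        raise ValueError(f"GM(1,1) needs at least 4 observations, got {x0.size}")
    nonpos = np.where(x0 <= 0)[0]
    if nonpos.size:
        raise ValueError(
            f"GM(1,1) requires strictly positive data; offending indices: {nonpos.tolist()}"
        )
    if response not in ("discrete", "continuous"):
        raise ValueError(f"unknown response form {response!r}")

    x1 = ago(x0)
    z1 = 0.5 * (x1[1:] + x1[:-1])
    design = np.column_stack([-z1, np.ones_like(z1)])
    coeffs, *_ = np.linalg.lstsq(design, x0[1:], rcond=None)
    a, u = float(coeffs[0]), float(coeffs[1])

    if response == "discrete" and abs(a) >= 2.0 - 1e-9:
        warnings.warn(
            f"development coefficient a={a:.4g} outside the discrete-response "
            "region |a| < 2; falling back to the continuous response",
            RuntimeWarning,
            stacklevel=2,
        )
        response = "continuous"

    k = np.arange(1, x0.size + 1)
    x1_hat = _x1_response(a, u, x0[0], k, response, a_epsilon)
    fitted = np.empty_like(x0)
    fitted[0] = x0[0]
    fitted[1:] = np.diff(x1_hat)
    return GM11Model(
        x0=x0,
        x1=x1,
        z1=z1,
        a=a,
        u=u,
        fitted=fitted,
        residuals=x0 - fitted,
        response=response,
        a_epsilon=a_epsilon,
    )


def predict_at_steps(model: GM11Model, steps: Sequence[int]) -> np.ndarray:
    """Restored series values at arbitrary 1-based observation steps.

    Step 1 returns x0(1); any step k >= 2 returns the difference of the
    accumulated response at k and k-1.
    """
    steps = np.asarray(steps, dtype=int)
    if np.any(steps < 1):
        raise ValueError("steps are 1-based and must be >= 1")
    hi = _x1_response(model.a, model.u, model.x0[0], steps, model.response, model.a_epsilon)
    lo = _x1_response(
        model.a, model.u, model.x0[0], steps - 1, model.response, model.a_epsilon
    )
    out = hi - lo
    out[steps == 1] = model.x0[0]
    return out


def forecast(model: GM11Model, horizon: int) -> np.ndarray:
    """Restored out-of-sample values for steps n+1 .. n+horizon."""
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    return predict_at_steps(model, np.arange(model.n + 1, model.n + horizon + 1))


@dataclass(frozen=True)
class AccuracyReport:
    """Posterior-difference accuracy test of a fitted grey model."""

    c: float
    p: float
    s1: float
    s2: float
    grade: int


def posterior_error_test(model: GM11Model) -> AccuracyReport:
    """Grade a fitted model by the posterior error ratio C and the
    small-error probability P.

    S1 and S2 are population standard deviations of the data and the
    residuals; C = S2/S1 and P is the fraction of residuals within
    0.6745 S1 of the mean residual.  Grades: 1 (C<0.35, P>=0.95),
    2 (C<0.50, P>=0.80), 3 (C<0.65, P>=0.70), else 4.  A constant series
    (S1 = 0) is a perfect fit by convention: C = 0, P = 1, grade 1.
    """
    s1 = float(np.std(model.x0))
    if s1 == 0.0:
        return AccuracyReport(c=0.0, p=1.0, s1=0.0, s2=0.0, grade=1)
    eps = model.residuals
    s2 = float(np.std(eps))
    c = s2 / s1
    p = float(np.mean(np.abs(eps - eps.mean()) < 0.6745 * s1))
    if c < 0.35 and p >= 0.95:
        grade = 1
    elif c < 0.50 and p >= 0.80:
        grade = 2
    elif c < 0.65 and p >= 0.70:
        grade = 3
    else:
        grade = 4
    return AccuracyReport(c=c, p=p, s1=s1, s2=s2, grade=grade)


@dataclass(frozen=True)
class ForecastResult:
    """Land-use forecast bundle: areas plus per-category diagnostics."""

    areas: LandUseSeries
    models: dict[str, GM11Model]
    accuracy: dict[str, AccuracyReport]
    closure_category: str
    #: forecast years whose closure residual went negative and was clamped
    clamped_years: list[int] = field(default_factory=list)

    def accuracy_frame(self) -> pd.DataFrame:
        rows = {
            cat: {
                "a": m.a,
                "u": m.u,
                "C": self.accuracy[cat].c,
                "P": self.accuracy[cat].p,
                "grade": self.accuracy[cat].grade,
            }
            for cat, m in self.models.items()
        }
        return pd.DataFrame(rows).T


def _steps_for_years(years: Sequence[int], targets: Sequence[int]) -> np.ndarray:
    years = np.asarray(years, dtype=int)
    diffs = np.diff(years)
    if years.size < 2 or np.any(diffs != diffs[0]):
        raise ValueError("year axis must be uniformly spaced")
    step = int(diffs[0])
    targets = np.asarray(targets, dtype=int)
    offsets = targets - years[0]
    if np.any(offsets % step != 0):
        raise ValueError(f"target years {list(targets)} do not fall on the year grid")
    return offsets // step + 1


def forecast_structure(
    areas: LandUseSeries,
    horizon_years: Sequence[int],
    closure_category: str = "unused land",
    response: str = "discrete",
) -> ForecastResult:
    """Forecast every category's area and close on the territory total.

    Each non-closure category is forecast by its own GM(1,1); the closure
    category is set to territory_total minus the others, so every forecast
    year sums to the territory total exactly.  If that residual goes
    negative it is clamped to zero and the other categories are rescaled
    proportionally (warned and flagged in ``clamped_years``).
    """
    closure = canonical_category(closure_category)
    if closure not in areas.categories:
        raise KeyError(f"closure category {closure_category!r} not in the area table")
    if len(areas.years) < 4:
        raise ValueError(
            f"need at least 4 annual observations, got {len(areas.years)}"
        )
    horizon_years = [int(y) for y in horizon_years]
    steps = _steps_for_years(areas.years, horizon_years)

    models: dict[str, GM11Model] = {}
    accuracy: dict[str, AccuracyReport] = {}
    pred = pd.DataFrame(index=areas.categories, columns=horizon_years, dtype=float)
    for cat in areas.categories:
        if cat == closure:
            continue
        model = fit_gm11(areas.areas.loc[cat].to_numpy(), response=response)
        models[cat] = model
        accuracy[cat] = posterior_error_test(model)
        pred.loc[cat] = predict_at_steps(model, steps)

    clamped: list[int] = []
    for y in horizon_years:
        others = pred.loc[pred.index != closure, y].clip(lower=0.0)
        residual = areas.territory_total - others.sum()
        if residual < 0:
            clamped.append(y)
            warnings.warn(
                f"closure residual for {y} is negative ({residual:.1f} hm2); "
                f"clamping {closure} to 0 and rescaling the other categories",
                RuntimeWarning,
                stacklevel=2,
            )
            others = others * (areas.territory_total / others.sum())
            residual = 0.0
        pred.loc[others.index, y] = others
        pred.loc[closure, y] = residual

    future = LandUseSeries(areas=pred, territory_total=areas.territory_total)
    return ForecastResult(
        areas=future,
        models=models,
        accuracy=accuracy,
        closure_category=closure,
        clamped_years=clamped,
    )


def forecast_land_use(
    areas: LandUseSeries,
    horizon_years: Sequence[int],
    closure_category: str = "unused land",
    response: str = "discrete",
) -> LandUseSeries:
    """Forecast the land-use table for the given years (see
    :func:`forecast_structure` for diagnostics)."""
    return forecast_structure(areas, horizon_years, closure_category, response).areas


def forecast_esv(
    future_areas: LandUseSeries, vc: ValueCoefficientMatrix
) -> ESVAccount:
    """Value a forecast land-use table (delegates to the valuation model)."""
    return compute_esv(future_areas, vc)
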