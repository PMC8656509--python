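"""Grey relational analysis: ranking drivers by similarity of trend.

Grey relational analysis (GRA) scores how closely each comparative series
(a candidate driving factor) tracks a reference series (here, annual total
ecosystem-services value) without any distributional assumptions — useful
when only a decade of annual observations exists.

After normalizing all series to dimensionless form (dividing by the
initial value or by the mean), the pointwise deviations
Delta_i(k) = |x0(k) - xi(k)| are combined with the global minimum and
maximum deviation over all factors and times in the analysis window:

    xi_i(k) = (Dmin + rho * Dmax) / (Delta_i(k) + rho * Dmax)

with distinguished coefficient rho in (0, 1] (conventionally 0.5).  The
relational grade r_i is the time average of xi_i(k); factors are ranked by
descending grade.  Every coefficient and grade lies in (0, 1], a series
identical to the reference grades 1, and with rho = 0.5 and Dmin = 0 the
smallest attainable coefficient is 1/3.
"""

from __future__ import annotations

import pathlib
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DriverSeries",
    "RelationalResult",
    "normalize_series",
    "relational_coefficients",
    "relational_grade",
    "rank_drivers",
]


@dataclass(frozen=True)
class DriverSeries:
    """Factor x year grid of candidate driving variables, native units."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values.copy()
        df.columns = [int(y) for y in df.columns]
        df = df.astype(float)
        if not np.isfinite(df.to_numpy()).all():
            raise ValueError("driver series contain non-finite values")
        object.__setattr__(self, "values", df)

    @property
    def names(self) -> list[str]:
        return list(self.values.index)

    @property
    def years(self) -> list[int]:
        return list(self.values.columns)

    @classmethod
    def from_csv(cls, path: str | pathlib.Path) -> "DriverSeries":
        return cls(pd.read_csv(path, index_col=0))

    def to_csv(self, path: str | pathlib.Path) -> None:
        self.values.to_csv(path, index_label="factor")


def normalize_series(values: Sequence[float], method: str = "mean") -> np.ndarray:
    """Make a series dimensionless by its initial value or its mean."""
    values = np.asarray(values, dtype=float)
    if method == "initial":
        divisor = values[0] if values.size else 0.0
    elif method == "mean":
        divisor = values.mean() if values.size else 0.0
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    if divisor == 0:
        raise ValueError(f"cannot normalize: {method} value is zero")
    return values / divisor


def relational_coefficients(
    reference: Sequence[float],
    comparatives: pd.DataFrame | np.ndarray,
    rho: float = 0.5,
) -> pd.DataFrame:
    """Grey relational coefficients xi_i(k) of each comparative series.

    ``comparatives`` is a factor x time grid already normalized to the
    same scale as ``reference``.  The global min and max deviation are
    taken over all factors and all times.  If every series coincides with
    the reference (Dmax = 0) all coefficients are 1 by convention.
    """
    if not 0 < rho <= 1:
        raise ValueError(f"rho must lie in (0, 1], got {rho}")
    comp = pd.DataFrame(comparatives).astype(float)
    reference = np.asarray(reference, dtype=float)
    if reference.size != comp.shape[1]:
        raise ValueError(
            f"reference length {reference.size} != comparative length {comp.shape[1]}"
        )
    delta = (comp - reference).abs()
    dmax = float(delta.to_numpy().max())
    if dmax == 0.0:
        warnings.warn(
            "all comparative series coincide with the reference; "
            "coefficients set to 1",
            RuntimeWarning,
            stacklevel=2,
        )
        return pd.DataFrame(1.0, index=comp.index, columns=comp.columns)
    dmin = float(delta.to_numpy().min())
    return (dmin + rho * dmax) / (delta + rho * dmax)


def relational_grade(coefficients: pd.DataFrame) -> pd.Series:
    """Unweighted time-mean of the coefficients, per factor."""
    coefficients = pd.DataFrame(coefficients)
    if coefficients.empty:
        raise ValueError("empty coefficient grid")
    return coefficients.mean(axis=1)


@dataclass(frozen=True)
class RelationalResult:
    """GRA outcome for one analysis window."""

    window: tuple[int, int]
    normalization: str
    rho: float
    coefficients: pd.DataFrame
    grades: pd.Series
    #: factor names ordered by descending grade (ties keep input order)
    ranking: list[str]


def rank_drivers(
    esv_totals: pd.Series,
    drivers: DriverSeries,
    windows: Sequence[tuple[int, int]] | None = None,
    rho: float = 0.5,
    normalization: str = "mean",
) -> list[RelationalResult]:
    """Rank the driving factors of ESV change per analysis window.

    ``esv_totals`` is the year-indexed reference series (total ESV, CNY).
    Each window (start_year, end_year), inclusive, is analyzed on its own:
    normalization and the global min/max deviations are re-evaluated on
    the window's data only, so sub-period grades are self-contained.
    """
    esv_totals = pd.Series(esv_totals).astype(float)
    esv_totals.index = [int(y) for y in esv_totals.index]
    years = drivers.years
    if windows is None:
        windows = [(years[0], years[-1])]

    results: list[RelationalResult] = []
    for start, end in windows:
        start, end = int(start), int(end)
        span = [y for y in years if start <= y <= end]
        if not span or start not in years or end not in years:
            raise ValueError(
                f"window {(start, end)} outside the driver year range {years[0]}-{years[-1]}"
            )
        missing = [y for y in span if y not in esv_totals.index]
        if missing:
            raise ValueError(f"ESV series missing years {missing} for window {(start, end)}")

        ref = normalize_series(esv_totals.loc[span].to_numpy(), normalization)
        comp = pd.DataFrame(
            {
                name: normalize_series(drivers.values.loc[name, span].to_numpy(), normalization)
                for name in drivers.names
            }
        ).T
        comp.columns = span
        xi = relational_coefficients(ref, comp, rho)
        grades = relational_grade(xi)
        order = grades.to_numpy()
        # stable sort on the negated grades keeps input order for ties
        ranking = [drivers.names[i] for i in np.argsort(-order, kind="stable")]
        if len(set(np.round(order, 12))) < len(order):
            warnings.warn(
                f"tied relational grades in window {(start, end)}; "
                "ties broken by input factor order",
                RuntimeWarning,
                stacklevel=2,
            )
        results.append(
            RelationalResult(
                window=(start, end),
                normalization=normalization,
                rho=float(rho),
                coefficients=xi,
                grades=grades,
                ranking=ranking,
            )
        )
    return results
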