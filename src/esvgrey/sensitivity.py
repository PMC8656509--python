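"""Coefficient-perturbation sensitivity of the total ecosystem-services value.

The valuation rests on transferred per-hectare coefficients, so a standard
robustness check perturbs one category's coefficient column by a fraction
``delta`` (conventionally +-50%) and measures the elasticity of the total:

    CS = (|ESV_adjusted - ESV_base| / ESV_base) / |delta|

evaluated per calendar year.  Because the valuation is linear in the
coefficients, CS equals the perturbed category's share of that year's
total ESV: it is independent of the magnitude and sign of ``delta`` and is
strictly below 1 whenever at least two categories contribute value.  A
CS well below 1 means the total is inelastic to that coefficient, i.e.
the transferred value is safe to use.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .valuation import (
    ESVAccount,
    LandUseSeries,
    ValueCoefficientMatrix,
    canonical_category,
    change_rate,
    compute_esv,
)

__all__ = [
    "SensitivityRecord",
    "adjust_vc",
    "coefficient_of_sensitivity",
    "sensitivity_table",
    "records_to_frame",
]


@dataclass(frozen=True)
class SensitivityRecord:
    """Outcome of one (category, delta) coefficient perturbation."""

    category: str
    delta_fraction: float
    #: year -> adjusted total ESV (CNY)
    esv_adjusted: dict[int, float]
    #: percent change of the adjusted total between the two study years
    rate_of_change_adjusted: float
    #: year -> coefficient of sensitivity (dimensionless)
    cs: dict[int, float]


def adjust_vc(
    vc: ValueCoefficientMatrix, category: str, delta_fraction: float
) -> ValueCoefficientMatrix:
    """Scale one category's coefficient column by ``1 + delta_fraction``."""
    if delta_fraction < -1:
        raise ValueError(
            f"delta_fraction={delta_fraction} would make coefficients negative"
        )
    cat = canonical_category(category)
    if cat not in vc.values.columns:
        raise KeyError(f"unknown category {category!r}")
    values = vc.values.copy()
    values[cat] = values[cat] * (1.0 + delta_fraction)
    return ValueCoefficientMatrix(values)


def coefficient_of_sensitivity(
    esv_base_year: float, esv_adjusted_year: float, delta_fraction: float
) -> float:
    """Elasticity of total ESV to a fractional coefficient change, one year."""
    if delta_fraction == 0:
        raise ValueError("coefficient of sensitivity is undefined for delta = 0")
    if not esv_base_year > 0:
        raise ValueError("base-year ESV must be positive")
    return abs(esv_adjusted_year - esv_base_year) / esv_base_year / abs(delta_fraction)


def sensitivity_table(
    areas: LandUseSeries,
    vc: ValueCoefficientMatrix,
    categories: Sequence[str] | None = None,
    delta_fractions: Sequence[float] = (0.5, -0.5),
    years: Sequence[int] | None = None,
) -> list[SensitivityRecord]:
    """One record per (category, delta): adjusted totals, adjusted
    between-year rate of change, and per-year CS.

    ``categories`` defaults to every category with a nonzero coefficient
    (perturbing a zero column, e.g. construction land, cannot move the
    total).  ``years`` defaults to the first and last year of ``areas``.
    """
    if categories is None:
        totals = vc.column_totals()
        categories = [c for c in areas.categories if totals.get(c, 0.0) != 0.0]
    if years is None:
        years = [areas.years[0], areas.years[-1]]
    years = [int(y) for y in years]
    missing = [y for y in years if y not in areas.years]
    if missing:
        raise ValueError(f"study years {missing} not present in the area series")

    base = compute_esv(areas, vc).totals
    records: list[SensitivityRecord] = []
    for category in categories:
        for delta in delta_fractions:
            adjusted: ESVAccount = compute_esv(areas, adjust_vc(vc, category, delta))
            totals_adj = {y: float(adjusted.totals[y]) for y in years}
            rate = change_rate(totals_adj[years[0]], totals_adj[years[-1]])
            cs = {
                y: coefficient_of_sensitivity(float(base[y]), totals_adj[y], delta)
                for y in years
            }
            records.append(
                SensitivityRecord(
                    category=canonical_category(category),
                    delta_fraction=float(delta),
                    esv_adjusted=totals_adj,
                    rate_of_change_adjusted=rate,
                    cs=cs,
                )
            )
    return records


def records_to_frame(records: Sequence[SensitivityRecord]) -> pd.DataFrame:
    """Tabulate records: one row per (category, delta), adjusted totals in
    billion CNY (2 dp), adjusted rate and CS per year (3 dp)."""
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "category": rec.category,
            "delta_pct": round(rec.delta_fraction * 100.0, 6),
        }
        for y, v in rec.esv_adjusted.items():
            row[f"esv_{y}_billion"] = round(v / 1e9, 2)
        row["rate_of_change_pct"] = round(rec.rate_of_change_adjusted, 3)
        for y, v in rec.cs.items():
            row[f"cs_{y}"] = round(v, 3)
        rows.append(row)
    return pd.DataFrame(rows)
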