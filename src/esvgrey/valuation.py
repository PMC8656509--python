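"""Area-based ecosystem-services valuation (benefit transfer).

The core model prices the services supplied by a territory as

    ESV = sum_i  A_i * VC_i

where ``A_i`` is the area (hm2) occupied by land-use category *i* and
``VC_i`` is its per-hectare, per-year value coefficient (CNY/hm2/yr),
itself the sum of nine service-function coefficients (gas regulation,
climate regulation, hydrological regulation, waste treatment, soil
formation and retention, biodiversity protection, food production, raw
material, recreation and culture).  Construction land carries a zero
coefficient: built-up land is treated as supplying no priced services.

The module provides the two tabular containers (coefficient matrix and
land-use area series), the valuation itself, change-rate accounting
between survey years, and a closure check that every year's category
areas sum to the fixed territory total.
"""

from __future__ import annotations

import io
import pathlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .guizhou import SERVICES

__all__ = [
    "CATEGORIES",
    "CategoryMismatchError",
    "ESVAccount",
    "LandUseSeries",
    "UndefinedRateError",
    "ValueCoefficientMatrix",
    "canonical_category",
    "change_rate",
    "closure_check",
    "column_totals",
    "compute_esv",
]

#: The seven first-class land-use categories of the Chinese land-use
#: classification system, in conventional reporting order.
CATEGORIES: tuple[str, ...] = (
    "cultivated land",
    "garden land",
    "forest land",
    "grass land",
    "construction land",
    "water area",
    "unused land",
)

_ALIASES: dict[str, str] = {
    "water": "water area",
    "water body": "water area",
    "waterbody": "water area",
    "waters": "water area",
    "construction": "construction land",
    "built-up land": "construction land",
    "built up land": "construction land",
    "cropland": "cultivated land",
    "farmland": "cultivated land",
    "arable land": "cultivated land",
    "forest": "forest land",
    "woodland": "forest land",
    "grassland": "grass land",
    "grass": "grass land",
    "garden": "garden land",
    "orchard": "garden land",
    "unused": "unused land",
    "bare land": "unused land",
}


class CategoryMismatchError(ValueError):
    """Category sets of two inputs do not agree after canonicalization."""


class UndefinedRateError(ValueError):
    """Rate of change requested against a zero base area."""


def canonical_category(name: str) -> str:
    """Canonicalize a land-use category name.

    Matching is case- and whitespace-insensitive with a small alias map
    (e.g. ``"Water"`` -> ``"water area"``).  Unknown names pass through
    normalized, so user-defined categories remain usable.
    """
    key = " ".join(str(name).strip().lower().split())
    return _ALIASES.get(key, key)


def _canonical_index(index: Iterable[str]) -> list[str]:
    return [canonical_category(c) for c in index]


@dataclass(frozen=True)
class ValueCoefficientMatrix:
    """Per-service, per-category value coefficients (CNY/hm2/yr).

    ``values`` is a service x category DataFrame.  Column sums are the
    working per-category coefficients of the valuation formula.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values.copy()
        df.index = [str(s).strip().lower() for s in df.index]
        df.columns = _canonical_index(df.columns)
        df = df.astype(float)
        missing = [s for s in SERVICES if s not in df.index]
        if missing:
            raise ValueError(f"coefficient matrix is missing service rows: {missing}")
        extra = [s for s in df.index if s not in SERVICES]
        if extra:
            raise ValueError(f"coefficient matrix has unknown service rows: {extra}")
        df = df.loc[list(SERVICES)]
        if (df.values < 0).any():
            raise ValueError("value coefficients must be non-negative")
        if "construction land" in df.columns and (df["construction land"] != 0).any():
            raise ValueError("construction land must carry a zero coefficient column")
        object.__setattr__(self, "values", df)

    @property
    def categories(self) -> list[str]:
        return list(self.values.columns)

    @property
    def services(self) -> list[str]:
        return list(self.values.index)

    def column_totals(self) -> pd.Series:
        """Per-category coefficient totals, in column order (CNY/hm2/yr)."""
        return self.values.sum(axis=0)

    @classmethod
    def from_records(cls, records: Mapping[str, Mapping[str, float]]) -> "ValueCoefficientMatrix":
        """Build from a ``service -> {category: coefficient}`` mapping."""
        return cls(pd.DataFrame(records).T)

    @classmethod
    def from_csv(cls, path: str | pathlib.Path) -> "ValueCoefficientMatrix":
        """Read a coefficient CSV (rows = services, columns = categories).

        An optional ``total`` row is cross-checked against the recomputed
        column sums (absolute tolerance 0.01 CNY) and then dropped.
        """
        df = pd.read_csv(path, index_col=0)
        df.index = [str(s).strip().lower() for s in df.index]
        if "total" in df.index:
            stated = df.loc["total"].astype(float)
            df = df.drop(index="total")
            recomputed = df.astype(float).sum(axis=0)
            bad = (stated - recomputed).abs() > 0.01
            if bad.any():
                raise ValueError(
                    "stated total row disagrees with column sums for: "
                    f"{list(stated.index[bad])}"
                )
        return cls(df)

    def to_csv(self, path: str | pathlib.Path, include_total: bool = True) -> None:
        df = self.values.copy()
        if include_total:
            df.loc["total"] = self.column_totals()
        df.to_csv(path, index_label="service")


def column_totals(vc: ValueCoefficientMatrix) -> pd.Series:
    """Per-category sums of the nine service coefficients (CNY/hm2/yr)."""
    return vc.column_totals()


@dataclass(frozen=True)
class LandUseSeries:
    """Category x year grid of areas (hm2) under a fixed territory total."""

    areas: pd.DataFrame
    territory_total: float

    def __post_init__(self) -> None:
        df = self.areas.copy()
        df.index = _canonical_index(df.index)
        df.columns = [int(y) for y in df.columns]
        df = df.astype(float)
        if (df.values < 0).any():
            raise ValueError("areas must be non-negative")
        if not float(self.territory_total) > 0:
            raise ValueError("territory_total must be positive")
        object.__setattr__(self, "areas", df)
        object.__setattr__(self, "territory_total", float(self.territory_total))

    @property
    def categories(self) -> list[str]:
        return list(self.areas.index)

    @property
    def years(self) -> list[int]:
        return list(self.areas.columns)

    @classmethod
    def from_csv(
        cls, path: str | pathlib.Path, territory_total: float | None = None
    ) -> "LandUseSeries":
        """Read an area CSV (first column = category, year columns, hm2).

        The territory total comes either from the ``territory_total``
        argument or from a leading metadata comment line of the form
        ``# territory_total=17609858``.
        """
        text = pathlib.Path(path).read_text(encoding="utf-8")
        lines = text.splitlines()
        body_start = 0
        for line in lines:
            if not line.startswith("#"):
                break
            body_start += 1
            if "territory_total" in line and territory_total is None:
                territory_total = float(line.split("=", 1)[1])
        if territory_total is None:
            raise ValueError(
                "territory_total not given and no '# territory_total=' metadata line found"
            )
        df = pd.read_csv(io.StringIO("\n".join(lines[body_start:])), index_col=0)
        return cls(df, territory_total)

    def to_csv(self, path: str | pathlib.Path) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(f"# territory_total={self.territory_total:.6f}\n")
            self.areas.to_csv(fh, index_label="category")


@dataclass(frozen=True)
class ESVAccount:
    """Per-category and total ecosystem-services value per year (CNY).

    ``esv`` is carried at full precision; display rounding (billions to
    two decimals, percentages to three) happens only in reports.
    """

    esv: pd.DataFrame

    @property
    def totals(self) -> pd.Series:
        """Per-year total ESV (CNY)."""
        return self.esv.sum(axis=0)

    @property
    def proportions(self) -> pd.DataFrame:
        """Per-category share of each year's total, in percent."""
        return self.esv.div(self.totals, axis=1) * 100.0

    def variation(self, year0: int, year1: int) -> pd.Series:
        """Plain per-category ESV difference ``year1 - year0`` (CNY)."""
        return self.esv[year1] - self.esv[year0]

    def rate_of_change(self, year0: int, year1: int) -> pd.Series:
        """Per-category percent ESV change between two years.

        Categories with zero ESV in ``year0`` (e.g. construction land)
        report 0 when unchanged and NaN otherwise.
        """
        base = self.esv[year0]
        delta = self.esv[year1] - base
        with np.errstate(divide="ignore", invalid="ignore"):
            rate = np.where(
                base != 0, delta / base * 100.0, np.where(delta == 0, 0.0, np.nan)
            )
        return pd.Series(rate, index=self.esv.index)

    def report(self, year0: int | None = None, year1: int | None = None) -> pd.DataFrame:
        """Rounded account table: value (billion CNY, 2 dp) and share (%)
        per year, plus variation and rate between two reference years."""
        years = self.esv.columns
        if year0 is None:
            year0 = int(years[0])
        if year1 is None:
            year1 = int(years[-1])
        out = pd.DataFrame(index=self.esv.index)
        for y in years:
            out[f"value_{y}_billion"] = (self.esv[y] / 1e9).round(2)
            out[f"proportion_{y}_pct"] = self.proportions[y].round(3)
        out["variation_billion"] = (self.variation(year0, year1) / 1e9).round(2)
        out["rate_of_change_pct"] = self.rate_of_change(year0, year1).round(3)
        total = out.sum(axis=0)
        total["rate_of_change_pct"] = round(
            change_rate(float(self.totals[year0]), float(self.totals[year1])), 3
        )
        out.loc["total"] = total
        # re-round: summing rounded cells reintroduces float dust
        return out.round(
            {c: 2 if "billion" in c else 3 for c in out.columns}
        )

    def to_csv(self, path: str | pathlib.Path, **kwargs) -> None:
        self.report(**kwargs).to_csv(path, index_label="category")


def compute_esv(areas: LandUseSeries, vc: ValueCoefficientMatrix) -> ESVAccount:
    """Value every category-year cell as area x per-category coefficient.

    Categories are matched by canonical name; order may differ between
    the two inputs.  Raises :class:`CategoryMismatchError` if any area
    category lacks a coefficient column.
    """
    totals = vc.column_totals()
    missing = [c for c in areas.categories if c not in totals.index]
    if missing:
        raise CategoryMismatchError(
            f"no value coefficient for categories: {missing}; "
            f"coefficient matrix has {list(totals.index)}"
        )
    esv = areas.areas.mul(totals.reindex(areas.categories), axis=0)
    return ESVAccount(esv=esv)


def change_rate(area_t0: float, area_t1: float) -> float:
    """Signed percent change ``(t1 - t0)/t0 * 100`` between two areas."""
    if area_t0 == 0:
        raise UndefinedRateError("rate of change is undefined for a zero base area")
    return (area_t1 - area_t0) / area_t0 * 100.0


def closure_check(areas: LandUseSeries, tol: float = 1.0) -> pd.DataFrame:
    """Report each year's deviation of the category sum from the territory total.

    Returns a year-indexed frame with columns ``sum`` (hm2), ``deviation``
    (hm2, signed) and ``ok`` (|deviation| <= tol).  Purely reporting: it
    never raises.
    """
    sums = areas.areas.sum(axis=0)
    dev = sums - areas.territory_total
    return pd.DataFrame(
        {"sum": sums, "deviation": dev, "ok": dev.abs() <= tol},
        index=areas.years,
    )
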