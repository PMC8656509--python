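"""Stage orchestration: wire the analysis modules behind one config.

Each ``run_*`` function reads CSV inputs, executes one analysis stage and
writes CSV outputs into the configured directory; :func:`run_all` chains
valuation -> sensitivity -> forecast -> relational (optionally generating
synthetic inputs first) and writes a JSON manifest of inputs, parameters,
seed and package versions so a run can be reproduced exactly.  All outputs
are plain UTF-8 CSV with explicit headers; identical config + seed yields
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .grey_forecast import forecast_esv, forecast_structure
from .grey_relational import DriverSeries, rank_drivers
from .sensitivity import records_to_frame, sensitivity_table
from .synthetic_data import default_scenario, generate_driver_series, generate_land_use_series, make_study_fixture
from .valuation import LandUseSeries, ValueCoefficientMatrix, closure_check, compute_esv

logger = logging.getLogger("esvgrey")

__all__ = [
    "RunConfig",
    "StageError",
    "run_valuation",
    "run_sensitivity",
    "run_forecast",
    "run_drivers",
    "run_simulate",
    "run_all",
]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything a pipeline run needs; CLI flags override config files."""

    areas: str | None = None
    vc: str | None = None
    drivers: str | None = None
    out: str = "esvgrey_out"
    seed: int = 0
    territory_total: float | None = None
    delta_fractions: tuple[float, ...] = (0.5, -0.5)
    rho: float = 0.5
    normalization: str = "mean"
    horizon_years: tuple[int, ...] = (2025, 2030)
    closure_category: str = "unused land"
    windows: tuple[tuple[int, int], ...] | None = None
    noise_cv: float = 0.01
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | pathlib.Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(pathlib.Path(path).read_text(encoding="utf-8")) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def validate(self, require: Sequence[str] = ()) -> None:
        for name in require:
            path = getattr(self, name)
            if path is None:
                raise FileNotFoundError(f"required input '--{name}' not given")
            if not pathlib.Path(path).exists():
                raise FileNotFoundError(f"input file for '--{name}' not found: {path}")
        if not 0 < self.rho <= 1:
            raise ValueError(f"rho must be in (0, 1], got {self.rho}")
        if self.normalization not in ("mean", "initial"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if any(d <= -1 for d in self.delta_fractions):
            raise ValueError("delta fractions must be > -1")

    @property
    def out_dir(self) -> pathlib.Path:
        path = pathlib.Path(self.out)
        path.mkdir(parents=True, exist_ok=True)
        return path


def _load_inputs(config: RunConfig) -> tuple[LandUseSeries, ValueCoefficientMatrix]:
    areas = LandUseSeries.from_csv(config.areas, territory_total=config.territory_total)
    vc = ValueCoefficientMatrix.from_csv(config.vc)
    report = closure_check(areas, tol=1.0)
    if not report["ok"].all():
        bad = report.index[~report["ok"]].tolist()
        logger.warning("area table does not close on the territory total in %s", bad)
    return areas, vc


def run_valuation(config: RunConfig) -> dict[str, str]:
    """Value the area table and write the account report + yearly totals."""
    config.validate(require=("areas", "vc"))
    areas, vc = _load_inputs(config)
    account = compute_esv(areas, vc)
    out = config.out_dir
    report_path = out / "esv_account.csv"
    account.to_csv(report_path)
    totals_path = out / "esv_totals.csv"
    account.totals.rename("esv_cny").to_csv(totals_path, index_label="year")
    logger.info(
        "total ESV: %s",
        ", ".join(f"{y}: {v / 1e9:.2f}e9 CNY" for y, v in account.totals.items()),
    )
    return {"esv_account": str(report_path), "esv_totals": str(totals_path)}


def run_sensitivity(config: RunConfig) -> dict[str, str]:
    """Coefficient-perturbation sensitivity table for the study years."""
    config.validate(require=("areas", "vc"))
    areas, vc = _load_inputs(config)
    records = sensitivity_table(areas, vc, delta_fractions=config.delta_fractions)
    path = config.out_dir / "sensitivity.csv"
    records_to_frame(records).to_csv(path, index=False)
    return {"sensitivity": str(path)}


def run_forecast(config: RunConfig) -> dict[str, str]:
    """Grey-forecast the land-use structure and its ESV."""
    config.validate(require=("areas", "vc"))
    areas, vc = _load_inputs(config)
    result = forecast_structure(
        areas, config.horizon_years, closure_category=config.closure_category
    )
    out = config.out_dir
    areas_path = out / "forecast_areas.csv"
    result.areas.to_csv(areas_path)
    esv_path = out / "forecast_esv.csv"
    forecast_esv(result.areas, vc).to_csv(esv_path)
    acc_path = out / "forecast_accuracy.csv"
    result.accuracy_frame().to_csv(acc_path, index_label="category")
    return {
        "forecast_areas": str(areas_path),
        "forecast_esv": str(esv_path),
        "forecast_accuracy": str(acc_path),
    }


def run_drivers(config: RunConfig) -> dict[str, str]:
    """Grey relational ranking of the driving factors of ESV change."""
    config.validate(require=("areas", "vc", "drivers"))
    areas, vc = _load_inputs(config)
    drivers = DriverSeries.from_csv(config.drivers)
    totals = compute_esv(areas, vc).totals
    results = rank_drivers(
        totals,
        drivers,
        windows=config.windows,
        rho=config.rho,
        normalization=config.normalization,
    )
    grades = pd.DataFrame(
        {f"{r.window[0]}-{r.window[1]}": r.grades.round(4) for r in results}
    )
    out = config.out_dir
    grades_path = out / "driver_grades.csv"
    grades.to_csv(grades_path, index_label="factor")
    ranking_path = out / "driver_ranking.csv"
    pd.DataFrame(
        {f"{r.window[0]}-{r.window[1]}": r.ranking for r in results}
    ).to_csv(ranking_path, index_label="rank")
    return {"driver_grades": str(grades_path), "driver_ranking": str(ranking_path)}


def run_simulate(config: RunConfig) -> dict[str, str]:
    """Generate a synthetic study (areas, coefficients, drivers) to disk."""
    scenario = default_scenario(seed=config.seed, noise_cv=config.noise_cv)
    fixture = make_study_fixture(seed=config.seed, noise_cv=config.noise_cv)
    out = config.out_dir / "inputs"
    out.mkdir(parents=True, exist_ok=True)
    areas_path = out / "areas.csv"
    generate_land_use_series(scenario).to_csv(areas_path)
    drivers_path = out / "drivers.csv"
    generate_driver_series(scenario).to_csv(drivers_path)
    vc_path = out / "vc.csv"
    fixture.vc.to_csv(vc_path)
    return {"areas": str(areas_path), "vc": str(vc_path), "drivers": str(drivers_path)}


_STAGES = (
    ("valuation", run_valuation),
    ("sensitivity", run_sensitivity),
    ("forecast", run_forecast),
    ("relational", run_drivers),
)


def run_all(config: RunConfig, simulate: bool = False) -> dict[str, object]:
    """Run every stage in order and write a reproducibility manifest.

    With ``simulate=True`` (or when no area table is given) a synthetic
    study is generated first and used as the input set.  Any stage failure
    raises :class:`StageError` naming the stage.
    """
    stages_done: dict[str, dict[str, str]] = {}
    if simulate or config.areas is None:
        try:
            inputs = run_simulate(config)
        except Exception as exc:  # pragma: no cover - generation is deterministic
            raise StageError("simulate", exc) from exc
        stages_done["simulate"] = inputs
        config = dataclasses.replace(
            config, areas=inputs["areas"], vc=inputs["vc"], drivers=inputs["drivers"]
        )
    for name, stage in _STAGES:
        try:
            stages_done[name] = stage(config)
        except Exception as exc:
            raise StageError(name, exc) from exc
    manifest = {
        "package": {"name": "esvgrey", "version": __version__},
        "versions": {"pandas": pd.__version__},
        "seed": config.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "stages": stages_done,
    }
    manifest_path = config.out_dir / "manifest.json"
    manifest_path.write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str), encoding="utf-8"
    )
    manifest["manifest_path"] = str(manifest_path)
    return manifest
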