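"""Configured end-to-end pipeline: scene → areas → supply → demand → balance
→ classification → regression, with validation, structured logging and a
reproducible report bundle.

Two entry modes:

* **synthetic** — generate a scene from a landscape configuration and run
  every stage;
* **tables** — start from an area table CSV (and optional coefficient CSV)
  and run the supply-side stages only, which reproduces published
  valuation tables with zero geodata.

Every output table is written as CSV with fixed ordering and float format,
and a ``metadata.json`` sidecar records the full configuration and seed, so
identical config + seed gives byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import accounting, balance, demand, quantreg, supply, synthetic
from .accounting import ALL_ZONES

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class DemandOptions:
    log_base: float = 10.0
    nlci_scale: float = 100.0
    pop_floor: float = 1.0
    nlci_floor: float = 1.0


@dataclass
class RegressionOptions:
    run: bool = True
    thetas: tuple = quantreg.DEFAULT_THETAS
    n_boot: int = 200
    pool_years: bool = True


@dataclass
class PipelineConfig:
    """Everything a run needs; see the demo YAML for the synthetic mode."""

    mode: str = "synthetic"  # "synthetic" | "tables"
    landscape: synthetic.LandscapeConfig = field(
        default_factory=synthetic.LandscapeConfig
    )
    areas_csv: str | None = None  # tables mode input
    coefficients_csv: str | None = None  # optional replacement for Table-1 set
    demand_options: DemandOptions = field(default_factory=DemandOptions)
    balance_mode: str = "normalized"
    k_levels: int = 5
    k_balance: int = 7
    per_year_breaks: bool = True
    regression: RegressionOptions = field(default_factory=RegressionOptions)
    outdir: str = "esbalance_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        land = raw.pop("landscape", {})
        if isinstance(land, dict):
            land = dict(land)
            if "transition_rates" in land:
                land["transition_rates"] = {
                    tuple(s.strip() for s in key.split("->")): rate
                    for key, rate in land["transition_rates"].items()
                }
            if "grid_shape" in land:
                land["grid_shape"] = tuple(land["grid_shape"])
            if "years" in land:
                land["years"] = tuple(land["years"])
            if "pop_params" in land:
                land["pop_params"] = synthetic.PopulationParams(**land["pop_params"])
            if "light_params" in land:
                land["light_params"] = synthetic.LightParams(**land["light_params"])
            land = synthetic.LandscapeConfig(**land)
        dem = raw.pop("demand_options", {})
        if isinstance(dem, dict):
            dem = DemandOptions(**dem)
        reg = raw.pop("regression", {})
        if isinstance(reg, dict):
            reg = dict(reg)
            if "thetas" in reg:
                reg["thetas"] = tuple(reg["thetas"])
            reg = RegressionOptions(**reg)
        return cls(landscape=land, demand_options=dem, regression=reg, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["landscape"]["transition_rates"] = {
            f"{src} -> {dst}": r
            for (src, dst), r in self.landscape.transition_rates.items()
        }
        return d


@dataclass
class ValidationReport:
    """Input problems found before running: fatal errors vs warnings."""

    fatal: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.fatal

    @property
    def empty(self) -> bool:
        return not self.fatal and not self.warnings


def validate_inputs(config: PipelineConfig) -> ValidationReport:
    """Check a configuration without running it; never raises."""
    report = ValidationReport()
    if config.mode not in ("synthetic", "tables"):
        report.fatal.append(f"unknown mode {config.mode!r}")
        return report
    if config.mode == "tables":
        if config.areas_csv is None:
            report.fatal.append("tables mode requires areas_csv")
        elif not Path(config.areas_csv).exists():
            report.fatal.append(f"areas_csv not found: {config.areas_csv}")
        else:
            df = pd.read_csv(config.areas_csv)
            need = {"zone", "year", "land_class", "area_km2"}
            if not need <= set(df.columns):
                report.fatal.append(
                    f"areas_csv missing columns: {sorted(need - set(df.columns))}"
                )
            elif (df["area_km2"] < 0).any():
                report.fatal.append("areas_csv contains negative areas")
    else:
        try:
            config.landscape.validate()
        except synthetic.ConfigurationError as exc:
            report.fatal.append(f"landscape config invalid: {exc}")
    if config.coefficients_csv is not None and not Path(config.coefficients_csv).exists():
        report.fatal.append(f"coefficients_csv not found: {config.coefficients_csv}")
    if config.balance_mode not in ("normalized", "raw"):
        report.fatal.append(f"unknown balance_mode {config.balance_mode!r}")
    if config.mode == "synthetic":
        rows, cols = config.landscape.grid_shape
        if config.landscape.n_zones < config.k_balance:
            report.warnings.append(
                "fewer zones than balance classes; the typology will collapse "
                f"({config.landscape.n_zones} < k_balance={config.k_balance})"
            )
    return report


def validate_raster_inputs(
    landuse: np.ndarray, nightlight: np.ndarray, zones: np.ndarray
) -> ValidationReport:
    """Shape and DN-range checks for externally supplied rasters."""
    report = ValidationReport()
    if nightlight.shape[-2:] != zones.shape:
        report.fatal.append(
            f"nightlight shape {nightlight.shape[-2:]} != zones shape {zones.shape}"
        )
    if landuse.shape[-2:] != zones.shape:
        report.fatal.append(
            f"landuse shape {landuse.shape[-2:]} != zones shape {zones.shape}"
        )
    if nightlight.min() < 0 or nightlight.max() > demand.DN_MAX:
        report.fatal.append(
            f"DN range [{nightlight.min()}, {nightlight.max()}] outside [0, 63]"
        )
    return report


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def run_pipeline(config: PipelineConfig, outdir=None) -> dict:
    """Run every applicable stage; return the bundle as a dict of frames.

    Writes tidy CSVs plus ``metadata.json`` into ``outdir`` (default from the
    config). On a stage failure, partial outputs are kept, a ``FAILED``
    marker names the stage, and :class:`PipelineError` is raised.
    """
    report = validate_inputs(config)
    if not report.ok:
        raise PipelineError("validate", ValueError("; ".join(report.fatal)))
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, pd.DataFrame] = {}
    stage = "setup"
    t0 = time.perf_counter()
    try:
        coeffs = supply.load_value_coefficients(config.coefficients_csv)

        if config.mode == "tables":
            stage = "areas"
            areas = pd.read_csv(config.areas_csv)
            scene = None
        else:
            stage = "simulate"
            scene = synthetic.generate_scene(config.landscape)
            logger.info("simulate: %s grid, %d zones", config.landscape.grid_shape,
                        config.landscape.n_zones)
            stage = "areas"
            areas = accounting.tabulate_stack(scene.landuse_grids(), zones=scene.zones)
        bundle["areas"] = areas
        _write_csv(areas, out / "areas.csv")

        stage = "area_change"
        years = sorted(set(areas["year"]))
        periods = list(zip(years[:-1], years[1:]))
        if len(years) > 1:
            periods.append((years[0], years[-1]))
        changes = []
        for y0, y1 in periods:
            ch = accounting.area_change(areas, (y0, y1))
            ch.insert(0, "period", f"{y0}-{y1}")
            changes.append(ch)
        if changes:
            bundle["area_change"] = pd.concat(changes, ignore_index=True)
            _write_csv(bundle["area_change"], out / "area_change.csv")

        stage = "supply"
        esv = supply.esv_compute(areas, coeffs)
        bundle["esv"] = esv
        _write_csv(esv, out / "esv.csv")
        by_class = supply.esv_by_class(esv).reset_index()
        by_service = supply.esv_by_service(esv).reset_index()
        _write_csv(by_class, out / "esv_by_class.csv")
        _write_csv(by_service, out / "esv_by_service.csv")
        bundle["esv_by_class"] = by_class
        bundle["esv_by_service"] = by_service
        esv_changes = []
        for y0, y1 in periods:
            ch = supply.esv_change(esv, (y0, y1))
            ch.insert(0, "period", f"{y0}-{y1}")
            esv_changes.append(ch)
        if esv_changes:
            bundle["esv_change"] = pd.concat(esv_changes, ignore_index=True)
            _write_csv(bundle["esv_change"], out / "esv_change.csv")

        if scene is not None:
            stage = "demand"
            opts = config.demand_options
            dem = demand.demand_table(
                areas,
                scene.population,
                scene.nightlight,
                scene.zones,
                log_base=opts.log_base,
                nlci_scale=opts.nlci_scale,
                pop_floor=opts.pop_floor,
                nlci_floor=opts.nlci_floor,
            )
            bundle["demand"] = dem
            _write_csv(dem, out / "demand.csv")

            stage = "balance"
            zone_esv = supply.esv_zone_totals(esv)
            bi = balance.balance_index(zone_esv, dem, mode=config.balance_mode)
            bundle["balance"] = bi
            _write_csv(bi, out / "balance.csv")

            stage = "classify"
            classified = balance.classify_balance_table(
                bi,
                k_balance=config.k_balance,
                k_levels=config.k_levels,
                per_year=config.per_year_breaks,
            )
            bundle["classification"] = classified
            _write_csv(classified, out / "classification.csv")
            breaks_meta = {}
            for year, grp in classified.groupby("year"):
                sch = balance.balance_scheme(grp["BI"], config.k_balance)
                breaks_meta[str(year)] = {
                    "bounds": [float(b) for b in sch.bounds],
                    "labels": list(sch.labels),
                }
            with open(out / "breaks.json", "w") as fh:
                json.dump(breaks_meta, fh, indent=1, sort_keys=True)

            if config.regression.run:
                stage = "regress"
                reg_df = _zone_composition(areas, bi)
                covs = [c for c in reg_df.columns if c not in ("zone", "year", "balance_index")]
                design = quantreg.RegressionDesign.from_frame(
                    reg_df, response="balance_index", covariates=tuple(covs)
                )
                path = quantreg.quantile_path(
                    design,
                    thetas=config.regression.thetas,
                    n_boot=config.regression.n_boot,
                    seed=config.seed,
                )
                table = path.to_frame().reset_index(names="term")
                bundle["regression"] = table
                _write_csv(table, out / "regression.csv")

        stage = "metadata"
        meta = {
            "config": config.to_dict(),
            "seed": config.seed,
            "stages": sorted(bundle),
        }
        with open(out / "metadata.json", "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True, default=str)
        logger.info("pipeline finished in %.2fs", time.perf_counter() - t0)
    except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc
    return bundle


def _zone_composition(areas: pd.DataFrame, bi: pd.DataFrame) -> pd.DataFrame:
    """Per-zone covariates for the regression stage: primary-class
    proportions with the largest-share class dropped as the compositional
    reference category (keeps the design full rank and well conditioned
    alongside an intercept), joined to BI."""
    sub = areas[areas["zone"] != ALL_ZONES]
    wide = sub.pivot_table(
        index=["zone", "year"], columns="land_class", values="area_km2", aggfunc="sum"
    ).fillna(0.0)
    props = wide.div(wide.sum(axis=1), axis=0)
    reference = props.mean(axis=0).idxmax()
    keep = [c for c in props.columns if c != reference]
    props = props[keep].reset_index()
    merged = props.merge(bi[["zone", "year", "BI"]], on=["zone", "year"])
    return merged.rename(columns={"BI": "balance_index"})
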