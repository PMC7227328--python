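"""CSV schemas, run configuration and the end-to-end pipeline.

Every writer stamps its output with comment-prefixed header lines (tool
version, seed, SHA-256 checksums of the inputs) so a run is auditable and a
rerun with the same inputs is byte-identical.  Readers skip ``#`` comment
lines; the dialect is UTF-8, comma-separated, ``.`` decimal, header row
mandatory.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import pandas as pd

from . import __version__
from .accounting import compute_tree_stocks, estimate_class_stocks, landscape_summary, plot_stocks
from .allometry import ModelRegistry, default_registry
from .inventory import CENSUS_COLUMNS, PLOT_COLUMNS, importance_value_index, validate_census, validate_plots
from .rasters import render_stock_map, write_ascii_grid
from .synthetic import generate_class_map
from .tier import tier_report
from .traits import TraitsTable

__all__ = [
    "RunConfig",
    "run_pipeline",
    "read_census",
    "read_plots",
    "read_areas",
    "read_traits",
    "write_table",
    "read_table",
]

log = logging.getLogger("agstocks")


class SchemaError(ValueError):
    """An input file violates its schema (reported with file context)."""


def _checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_table(path, df: pd.DataFrame, meta: Mapping[str, object] | None = None) -> None:
    lines = [f"# agstocks {__version__}"]
    for k, v in (meta or {}).items():
        lines.append(f"# {k}={v}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _read_checked(path, required: list[str], what: str) -> pd.DataFrame:
    try:
        df = read_table(path)
    except FileNotFoundError:
        raise SchemaError(f"{what} file not found: {path}") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: {what} is missing columns {missing}")
    return df


def read_census(path) -> pd.DataFrame:
    return _read_checked(path, CENSUS_COLUMNS, "census")


def read_plots(path) -> pd.DataFrame:
    return _read_checked(path, PLOT_COLUMNS, "plot register")


def read_areas(path) -> pd.DataFrame:
    return _read_checked(path, ["lulc", "area_ha"], "area table")


def read_traits(path, weighting: str = "species") -> TraitsTable:
    """Traits from either a raw-sample CSV or a percent-scale summary CSV.

    Raw samples: ``species, carbon_pct, nitrogen_pct[, dbh_cm]``; summary
    files are recognised by their ``c_mean`` column.
    """
    df = read_table(path)
    if "c_mean" in df.columns:
        return TraitsTable.from_summary_frame(df, weighting=weighting)
    needed = {"species", "carbon_pct", "nitrogen_pct"}
    if not needed <= set(df.columns):
        raise SchemaError(f"{path}: traits file needs {sorted(needed)} or summary columns")
    from .traits import WoodSample
    samples = [
        WoodSample(r.species, r.carbon_pct / 100, r.nitrogen_pct / 100,
                   getattr(r, "dbh_cm", None))
        for r in df.itertuples(index=False)
    ]
    return TraitsTable.from_samples(samples, weighting=weighting)


@dataclass
class RunConfig:
    """Paths and switches for one accounting run."""

    traits: Path
    census: Path
    plots: Path
    areas: Path
    out_dir: Path
    registry: Path | None = None
    element: Literal["C", "N", "both"] = "both"
    weighting: Literal["species", "samples"] = "species"
    seed: int = 0
    map_resolution: float | None = None  # m; None disables the stock map

    def elements(self) -> tuple[str, ...]:
        if self.element == "both":
            return ("C", "N")
        if self.element in ("C", "N"):
            return (self.element,)
        raise SchemaError(f"element must be C, N or both, got {self.element!r}")


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run census → stocks → class estimates → summary (+ maps, reports).

    Deterministic given inputs and seed; every CSV artifact embeds the tool
    version, the seed and input checksums in comment headers.  Returns the
    artifact paths keyed by artifact name.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    elements = config.elements()

    traits = read_traits(config.traits, weighting=config.weighting)
    census = validate_census(read_census(config.census))
    plots = validate_plots(read_plots(config.plots))
    areas = read_areas(config.areas)
    registry = (ModelRegistry.from_yaml(config.registry) if config.registry
                else default_registry())
    unknown = set(plots["lulc"]) - set(areas["lulc"])
    if unknown:
        raise SchemaError(f"plot register has LULC classes absent from the area table: "
                          f"{sorted(unknown)}")

    meta = {
        "seed": config.seed,
        "element": config.element,
        "weighting": config.weighting,
        "traits_sha256": _checksum(config.traits),
        "census_sha256": _checksum(config.census),
        "plots_sha256": _checksum(config.plots),
        "areas_sha256": _checksum(config.areas),
    }
    artifacts: dict[str, Path] = {}

    stocks = compute_tree_stocks(census, plots, registry, traits)
    lulc_of = plots.set_index("plot_id")["lulc"]
    per_plot = plot_stocks(stocks, plots)

    if len(census):
        ivi = importance_value_index(census, plots)
        artifacts["ivi"] = out_dir / "ivi.csv"
        write_table(artifacts["ivi"], ivi, meta)

        tier = tier_report(stocks.assign(lulc=stocks["plot_id"].map(lulc_of)))
        artifacts["tier"] = out_dir / "tier_report.csv"
        write_table(artifacts["tier"], tier, meta)

    summaries = {}
    for element in elements:
        est = estimate_class_stocks(per_plot, areas, element)
        disp = est.copy()
        for col in ("min_density", "max_density", "mean_density", "se_density",
                    "total_stock", "se_total"):
            disp[f"{col}_full"] = est[col]
            disp[col] = est[col].round(2)
        name = {"C": "carbon", "N": "nitrogen"}[element]
        artifacts[f"estimates_{name}"] = out_dir / f"estimates_{name}.csv"
        write_table(artifacts[f"estimates_{name}"], disp, meta)
        summaries[element] = landscape_summary(est)

    rows = []
    for element, summ in summaries.items():
        for r in summ.categories.itertuples(index=False):
            rows.append({"element": element, "scope": "category", "name": r.category,
                         "total_stock": r.total_stock, "se_total": r.se_total})
        rows.append({"element": element, "scope": "landscape", "name": "watershed",
                     "total_stock": summ.grand_total, "se_total": summ.grand_se})
    artifacts["summary"] = out_dir / "landscape_summary.csv"
    write_table(artifacts["summary"], pd.DataFrame(rows), meta)

    if config.map_resolution:
        cmap = generate_class_map(areas, resolution_m=config.map_resolution,
                                  seed=config.seed)
        for element, summ in summaries.items():
            densities = dict(zip(summ.classes["lulc"], summ.classes["mean_density"]))
            # map classes never sampled (no plots) carry no estimate → drop
            present = [c for c in cmap.classes if c in densities]
            missing = set(cmap.classes) - set(densities)
            if missing:
                log.warning("classes without estimates rendered as nodata: %s",
                            sorted(missing))
                densities = {**{c: -9999.0 for c in missing}, **densities}
            name = {"C": "carbon", "N": "nitrogen"}[element]
            artifacts[f"map_{name}"] = out_dir / f"stock_map_{name}.asc"
            write_ascii_grid(artifacts[f"map_{name}"], render_stock_map(cmap, densities))

    log.info("pipeline complete: %d artifacts in %s", len(artifacts), out_dir)
    return artifacts
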