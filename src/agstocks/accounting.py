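"""Stock accounting: tree → plot → LULC class → landscape.

The chain is multiplicative then additive.  A tree's element stock is its
oven-dry aboveground biomass times the species' dry-matter fraction of that
element (the overall mean across sampled species substitutes for unsampled
species).  Plot stocks are sums over stems, expressed per hectare of plot
area; a class's density is the mean of its per-plot densities with standard
error SD/√n_plots; the class total is density times the mapped class area,
and landscape totals add classes (SEs combine in quadrature across classes,
which are independent strata).

Units: kg per tree, Mg (= 10³ kg) at plot level and above, Mg/ha densities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .allometry import ModelRegistry
from .inventory import validate_census, validate_plots
from .traits import Element, TraitsTable

__all__ = [
    "TreeStock",
    "StockEstimate",
    "LandscapeSummary",
    "tree_stock",
    "compute_tree_stocks",
    "plot_stocks",
    "lulc_density",
    "lulc_total",
    "estimate_class_stocks",
    "landscape_summary",
]

KG_PER_MG = 1000.0


@dataclass(frozen=True)
class TreeStock:
    """Element stocks of one stem (kg)."""

    species: str
    biomass: float   # kg dry matter
    carbon: float    # kg
    nitrogen: float  # kg
    carbon_provenance: str    # species-specific | fallback
    nitrogen_provenance: str


def tree_stock(biomass_kg: float, traits: TraitsTable, species: str) -> TreeStock:
    """C and N stock of one tree from its dry biomass and species traits."""
    if biomass_kg < 0:
        raise ValueError("biomass must be non-negative")
    cf, cp = traits.fraction_for_species(species, "C")
    nf, np_ = traits.fraction_for_species(species, "N")
    return TreeStock(
        species=species,
        biomass=float(biomass_kg),
        carbon=cf * biomass_kg,
        nitrogen=nf * biomass_kg,
        carbon_provenance=cp,
        nitrogen_provenance=np_,
    )


def compute_tree_stocks(
    census: pd.DataFrame,
    plots: pd.DataFrame,
    registry: ModelRegistry,
    traits: TraitsTable,
) -> pd.DataFrame:
    """Census with per-stem biomass and element stocks appended (kg).

    Adds ``biomass_kg, carbon_kg, nitrogen_kg, carbon_fallback,
    nitrogen_fallback`` columns; biomass comes from the registry's routed
    allometric model per stem.
    """
    plots = validate_plots(plots)
    census = validate_census(census, plots)
    out = census.copy()
    biomass = registry.predict(census, plots) if len(census) else np.array([])
    cf, c_fb = traits.fractions_for(census["species"], "C")
    nf, n_fb = traits.fractions_for(census["species"], "N")
    out["biomass_kg"] = biomass
    out["carbon_kg"] = cf * biomass
    out["nitrogen_kg"] = nf * biomass
    out["carbon_fallback"] = c_fb
    out["nitrogen_fallback"] = n_fb
    return out


def plot_stocks(tree_stocks: pd.DataFrame, plots: pd.DataFrame) -> pd.DataFrame:
    """Per-plot stocks (Mg) and densities (Mg/ha), one row per plot.

    Every registered plot appears; plots without stems are genuine zero
    observations (grassland and cropland plots are often treeless) and enter
    with zero stocks.
    """
    plots = validate_plots(plots)
    if len(tree_stocks):
        unknown = set(tree_stocks["plot_id"]) - set(plots["plot_id"])
        if unknown:
            raise ValueError(f"tree stocks reference unknown plots: {sorted(unknown)[:5]}")
        sums = tree_stocks.groupby("plot_id")[["biomass_kg", "carbon_kg", "nitrogen_kg"]].sum()
    else:
        sums = pd.DataFrame(columns=["biomass_kg", "carbon_kg", "nitrogen_kg"])
    out = plots[["plot_id", "lulc", "area_ha"]].copy()
    for col in ("biomass_kg", "carbon_kg", "nitrogen_kg"):
        mg = col.replace("_kg", "_mg")
        out[mg] = out["plot_id"].map(sums[col] if col in sums else {}).fillna(0.0) / KG_PER_MG
    out["carbon_density"] = out["carbon_mg"] / out["area_ha"]
    out["nitrogen_density"] = out["nitrogen_mg"] / out["area_ha"]
    out["biomass_density"] = out["biomass_mg"] / out["area_ha"]
    return out


@dataclass
class StockEstimate:
    """Per-class density estimate, optionally scaled to the class area."""

    lulc: str
    element: Literal["C", "N"]
    n_plots: int
    mean_density: float            # Mg/ha
    se_density: float              # Mg/ha (SD of plot densities / √n_plots)
    min_density: float
    max_density: float
    area: float | None = None      # ha mapped to the class
    total_stock: float | None = None   # Mg
    se_total: float | None = None      # Mg


def lulc_density(plot_stocks_df: pd.DataFrame, element: Element) -> StockEstimate:
    """Mean ± SE of per-plot densities for one LULC class.

    The standard error is the sample SD of plot densities over √n_plots;
    with a single plot it is reported as 0 with a warning.
    """
    if plot_stocks_df.empty:
        raise ValueError("no plots given")
    classes = plot_stocks_df["lulc"].unique()
    if len(classes) > 1:
        raise ValueError(f"plots mix LULC classes: {sorted(classes)}")
    col = {"C": "carbon_density", "N": "nitrogen_density"}[element]
    d = plot_stocks_df[col].to_numpy(dtype=float)
    n = d.size
    if n >= 2:
        se = float(np.std(d, ddof=1) / math.sqrt(n))
    else:
        warnings.warn(f"single plot in {classes[0]!r}: SE reported as 0", stacklevel=2)
        se = 0.0
    return StockEstimate(
        lulc=str(classes[0]), element=element, n_plots=int(n),
        mean_density=float(d.mean()), se_density=se,
        min_density=float(d.min()), max_density=float(d.max()),
    )


def lulc_total(est: StockEstimate, area_ha: float) -> StockEstimate:
    """Scale a density estimate to its mapped class area (unrounded)."""
    if area_ha <= 0:
        raise ValueError("area must be positive")
    est.area = float(area_ha)
    est.total_stock = est.mean_density * area_ha
    est.se_total = est.se_density * area_ha
    return est


def estimate_class_stocks(
    plot_stocks_df: pd.DataFrame,
    areas: pd.DataFrame,
    element: Element,
) -> pd.DataFrame:
    """One row per LULC class: n_plots, density stats, area-scaled totals.

    ``areas`` needs ``lulc, area_ha`` (a ``category`` column is carried
    through when present).  Every sampled class must appear in the area
    table.
    """
    rows = []
    area_lut = areas.set_index("lulc")["area_ha"]
    cat_lut = areas.set_index("lulc")["category"] if "category" in areas.columns else None
    missing = set(plot_stocks_df["lulc"].unique()) - set(area_lut.index)
    if missing:
        raise ValueError(f"classes sampled but absent from the area table: {sorted(missing)}")
    for lulc, sub in plot_stocks_df.groupby("lulc", sort=False):
        est = lulc_total(lulc_density(sub, element), float(area_lut[lulc]))
        rows.append({
            "lulc": lulc,
            "category": cat_lut[lulc] if cat_lut is not None else lulc,
            "element": element,
            "n_plots": est.n_plots,
            "min_density": est.min_density,
            "max_density": est.max_density,
            "mean_density": est.mean_density,
            "se_density": est.se_density,
            "area_ha": est.area,
            "total_stock": est.total_stock,
            "se_total": est.se_total,
        })
    return pd.DataFrame(rows)


@dataclass
class LandscapeSummary:
    element: Literal["C", "N"]
    classes: pd.DataFrame      # per-class estimates
    categories: pd.DataFrame   # category subtotals (total, SE in quadrature)
    grand_total: float         # Mg
    grand_se: float            # Mg


def landscape_summary(
    class_estimates: pd.DataFrame,
    category_map: Mapping[str, str] | None = None,
) -> LandscapeSummary:
    """Category subtotals and the landscape grand total.

    ``category_map`` overrides the per-class ``category`` column; every class
    must map to exactly one category.  Totals add exactly; SEs combine by
    root-sum-of-squares since classes are disjoint strata sampled
    independently.
    """
    df = class_estimates.copy()
    if category_map is not None:
        unmapped = set(df["lulc"]) - set(category_map)
        if unmapped:
            raise ValueError(f"classes without a category: {sorted(unmapped)}")
        df["category"] = df["lulc"].map(category_map)
    elif "category" not in df.columns:
        raise ValueError("no category column and no category_map given")
    if df["category"].isna().any():
        raise ValueError("classes without a category")
    cats = (
        df.groupby("category", sort=False)
        .agg(total_stock=("total_stock", "sum"),
             se_total=("se_total", lambda s: math.sqrt(float((s**2).sum()))))
        .reset_index()
    )
    element = df["element"].iloc[0] if "element" in df.columns and len(df) else "C"
    return LandscapeSummary(
        element=element,
        classes=df,
        categories=cats,
        grand_total=float(df["total_stock"].sum()),
        grand_se=math.sqrt(float((df["se_total"] ** 2).sum())),
    )
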