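"""Plot register and tree census: densities, basal area, Importance Value Index.

The census is one row per stem with DBH ≥ 5 cm; the plot register carries the
stratification (one LULC class per plot) and the plot dimensions, which differ
by class (30 × 30 m in natural vegetation and cropland, 100 × 100 m in
settlements, 10 × 20 m in agroforestry and plantations).
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
import pandas as pd

from .traits import normalize_species

__all__ = [
    "PLOT_COLUMNS",
    "CENSUS_COLUMNS",
    "plot_area_ha",
    "basal_area",
    "validate_plots",
    "validate_census",
    "stem_density",
    "importance_value_index",
]

PLOT_COLUMNS = ["plot_id", "lulc", "width_m", "length_m"]
CENSUS_COLUMNS = ["plot_id", "species", "dbh_cm", "height_m", "wood_density_g_cm3"]


def plot_area_ha(width_m, length_m=None):
    """Plot area in hectares; accepts scalars or arrays.

    ``plot_area_ha(30, 30) == 0.09``; with one argument the plot is square.
    """
    if length_m is None:
        length_m = width_m
    w = np.asarray(width_m, dtype=float)
    l = np.asarray(length_m, dtype=float)
    if np.any(w <= 0) or np.any(l <= 0):
        raise ValueError("plot dimensions must be positive")
    out = w * l / 10_000.0
    return out if out.ndim else float(out)


def basal_area(dbh_cm):
    """Stem cross-sectional area at breast height in m²: π·(DBH/200)²."""
    d = np.asarray(dbh_cm, dtype=float)
    if np.any(d <= 0):
        raise ValueError("dbh must be positive")
    out = math.pi * (d / 200.0) ** 2
    return out if out.ndim else float(out)


def _require(df: pd.DataFrame, columns: Iterable[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing columns {missing}")


def validate_plots(plots: pd.DataFrame) -> pd.DataFrame:
    """Check the plot register and return it with an ``area_ha`` column."""
    _require(plots, PLOT_COLUMNS, "plot register")
    if plots["plot_id"].duplicated().any():
        dupes = plots.loc[plots["plot_id"].duplicated(), "plot_id"].tolist()
        raise ValueError(f"duplicate plot_id: {dupes[:5]}")
    out = plots.copy()
    out["area_ha"] = plot_area_ha(out["width_m"].to_numpy(), out["length_m"].to_numpy())
    return out


def validate_census(census: pd.DataFrame, plots: pd.DataFrame | None = None) -> pd.DataFrame:
    _require(census, CENSUS_COLUMNS, "census")
    if len(census) and census["dbh_cm"].min() < 5:
        raise ValueError("census contains stems below the 5 cm DBH threshold")
    if len(census) and census["height_m"].min() <= 0:
        raise ValueError("census contains non-positive heights")
    if plots is not None and len(census):
        unknown = set(census["plot_id"]) - set(plots["plot_id"])
        if unknown:
            raise ValueError(f"census references unknown plots: {sorted(unknown)[:5]}")
    return census


def stem_density(census: pd.DataFrame, plots: pd.DataFrame, lulc: str | None = None):
    """Stems per hectare, pooled over the sampled area.

    With ``lulc`` given, the ratio estimator for that class (total stems over
    total sampled area); otherwise a Series indexed by class.  Treeless plots
    count in the denominator.
    """
    plots = validate_plots(plots)
    if lulc is not None:
        sub = plots[plots["lulc"] == lulc]
        if sub.empty or sub["area_ha"].sum() <= 0:
            raise ValueError(f"no sampled area for LULC {lulc!r}")
        n = census["plot_id"].isin(set(sub["plot_id"])).sum() if len(census) else 0
        return float(n / sub["area_ha"].sum())
    return pd.Series(
        {cls: stem_density(census, plots, cls) for cls in plots["lulc"].unique()},
        name="stems_per_ha",
    )


def importance_value_index(census: pd.DataFrame, plots: pd.DataFrame) -> pd.DataFrame:
    """Importance Value Index per species (Curtis–McIntosh convention).

    IVI_i = relative density + relative frequency + relative dominance, where
    relative density is the species' share of stems, relative frequency its
    share of plot occurrences, and relative dominance its share of total basal
    area — each in percent, so components each sum to 100 and IVI sums to 300
    across species.  Sorted by IVI descending, ties broken alphabetically.
    """
    census = validate_census(census, plots)
    if census.empty:
        raise ValueError("empty census")
    df = census.assign(
        species=census["species"].map(normalize_species),
        ba=basal_area(census["dbh_cm"].to_numpy()),
    )
    grp = df.groupby("species")
    n_i = grp.size()
    f_i = grp["plot_id"].nunique()
    ba_i = grp["ba"].sum()
    out = pd.DataFrame({
        "species": n_i.index,
        "relative_density": 100.0 * n_i / n_i.sum(),
        "relative_frequency": 100.0 * f_i / f_i.sum(),
        "relative_dominance": 100.0 * ba_i / ba_i.sum(),
    }).reset_index(drop=True)
    out["ivi"] = out[["relative_density", "relative_frequency", "relative_dominance"]].sum(axis=1)
    return (
        out.sort_values(["ivi", "species"], ascending=[False, True])
        .reset_index(drop=True)
    )
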