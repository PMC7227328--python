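"""Seeded generators for trait samples, stands, area tables and class maps.

The generators emulate the statistical structure of a West-African Sudan
Savannah field campaign: per-species stem-wood C/N fractions drawn from
truncated normals matching published summary statistics; a plot design of
250 plots across eight LULC classes (30 × 30 m in natural vegetation and
cropland, 100 × 100 m in settlements, 10 × 20 m in agroforestry and
plantations); and stem lists per plot with negative-binomial counts,
truncated log-normal DBH, a power-law height curve and per-species wood
density.

Calibration.  Each class carries a target mean carbon density (Mg/ha).  The
generator hits it in expectation by scaling the class's allometric
coefficient so that  stems/ha × E[carbon per stem] / 1000  equals the target,
where the expectation over the tree-mark distribution is computed by a
fixed-seed Monte-Carlo independent of the user's seed.  The calibrated
registry is part of the generated study and must be the one used when the
pipeline is run on the synthetic census.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .allometry import AllometricModel, ModelRegistry, _DEFAULT_COEFFS
from .traits import TraitsTable, load_reference_traits, normalize_species

__all__ = [
    "TraitGenSpec",
    "LulcStandSpec",
    "StandGenSpec",
    "SyntheticStudy",
    "generate_trait_samples",
    "generate_inventory",
    "generate_area_table",
    "generate_class_map",
    "calibrate_registry",
    "default_stand_spec",
    "simulate_study",
    "ClassMap",
]

_CALIBRATION_SEED = 709127  # fixed: calibration is part of the spec, not of the draw
_POWER_B = _DEFAULT_COEFFS["b"]

#: plausible oven-dry wood densities (g/cm³) for the region's main species
WOOD_DENSITY_G_CM3: Mapping[str, float] = {
    "terminalia macroptera": 0.70, "terminalia avicennioides": 0.68,
    "acacia seyal": 0.65, "acacia gourmaensis": 0.72,
    "combretum glutinosum": 0.75, "pterocarpus erinaceus": 0.80,
    "anogeisus leiocarpus": 0.78, "mitragyna inermis": 0.60,
    "lannea microcrapa": 0.50, "lannea acida": 0.52,
    "ficus sp": 0.45, "crosopteryx febrifuga": 0.74,
    "entada africana": 0.58, "parkia biglobosa": 0.55,
    "vitelaria paradoxa": 0.70, "azadirachta indica": 0.66,
    "anacardium occidentale": 0.50, "eucalyptus grandis": 0.55,
}
_DEFAULT_RHO = 0.60
_RHO_SD = 0.05


# ----------------------------------------------------------------------
# trait samples
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class SpeciesTraitGen:
    """Truncated-normal generating parameters for one species (fractions)."""

    species: str
    n: int
    c_mean: float
    c_sd: float
    c_min: float
    c_max: float
    n_mean: float
    n_sd: float
    n_min: float
    n_max: float

    def __post_init__(self):
        for lo, mu, hi in ((self.c_min, self.c_mean, self.c_max),
                           (self.n_min, self.n_mean, self.n_max)):
            if not lo < hi:
                raise ValueError(f"{self.species}: infeasible truncation [{lo}, {hi}]")
            if not lo <= mu <= hi:
                raise ValueError(f"{self.species}: mean {mu} outside [{lo}, {hi}]")


@dataclass(frozen=True)
class TraitGenSpec:
    entries: tuple[SpeciesTraitGen, ...]

    @classmethod
    def from_traits(cls, traits: TraitsTable) -> "TraitGenSpec":
        """SD is recovered from the summary as SE·√n."""
        entries = []
        for e in traits.entries.values():
            rt_n = np.sqrt(e.n_samples)
            entries.append(SpeciesTraitGen(
                species=e.species, n=e.n_samples,
                c_mean=e.carbon.mean, c_sd=max(e.carbon.se * rt_n, 1e-12),
                c_min=e.carbon.min, c_max=e.carbon.max,
                n_mean=e.nitrogen.mean, n_sd=max(e.nitrogen.se * rt_n, 1e-12),
                n_min=e.nitrogen.min, n_max=e.nitrogen.max,
            ))
        return cls(entries=tuple(entries))


def default_trait_spec() -> TraitGenSpec:
    return TraitGenSpec.from_traits(load_reference_traits())


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_trait_samples(spec: TraitGenSpec | None = None, seed: int = 0) -> pd.DataFrame:
    """Per-sample C and N fractions: exactly n rows per species.

    Values are truncated-normal within each species' published [min, max];
    nitrogen < carbon holds by construction (nitrogen fractions are two
    orders of magnitude below carbon fractions).
    """
    spec = spec or default_trait_spec()
    rng = np.random.default_rng(seed)
    frames = []
    for e in spec.entries:
        c = _truncnorm(rng, e.c_mean, e.c_sd, e.c_min, e.c_max, e.n)
        n = _truncnorm(rng, e.n_mean, e.n_sd, e.n_min, e.n_max, e.n)
        frames.append(pd.DataFrame({
            "species": e.species,
            "carbon_fraction": c,
            "nitrogen_fraction": n,
        }))
    out = pd.concat(frames, ignore_index=True)
    assert (out["nitrogen_fraction"] < out["carbon_fraction"]).all()
    return out


# ----------------------------------------------------------------------
# stands
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class LulcStandSpec:
    """Generating parameters for one LULC class's stand structure."""

    lulc: str
    category: str
    n_plots: int
    plot_width_m: float
    plot_length_m: float
    stems_per_ha: float
    species_mix: Mapping[str, float]
    dbh_median_cm: float
    dbh_log_sd: float
    dbh_max_cm: float
    dbh_min_cm: float = 5.0
    height_coeff: float = 2.5       # H = coeff · D^exp · exp(noise)
    height_exp: float = 0.55
    height_log_sd: float = 0.25
    nb_dispersion: float = 5.0      # negative-binomial k; var = μ + μ²/k
    target_carbon_density: float | None = None  # Mg C/ha

    def __post_init__(self):
        total = sum(self.species_mix.values())
        if self.species_mix and abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.lulc}: species-mix probabilities sum to {total}")
        if self.stems_per_ha < 0:
            raise ValueError("stems_per_ha must be non-negative")

    @property
    def area_ha(self) -> float:
        return self.plot_width_m * self.plot_length_m / 10_000.0


@dataclass(frozen=True)
class StandGenSpec:
    classes: tuple[LulcStandSpec, ...]

    def __getitem__(self, lulc: str) -> LulcStandSpec:
        for c in self.classes:
            if c.lulc == lulc:
                return c
        raise KeyError(lulc)


def generate_area_table() -> pd.DataFrame:
    """The packaged watershed LULC area table (ha, % of basin, plot design)."""
    from importlib import resources
    with resources.files("agstocks.fixtures").joinpath("lulc_areas.csv").open() as fh:
        return pd.read_csv(fh)


def default_stand_spec() -> StandGenSpec:
    """The default study conditions: the eight-class watershed design.

    Plot counts and sizes follow the sampled design (250 plots, 27.26 ha);
    stem densities use the two published class figures (1397/ha riparian,
    300/ha cashew agroforestry) with realistic rates elsewhere; target
    carbon densities are the published class means (the plantation class is
    the area-weighted mean of its species-level figures).
    """
    mixes = {
        "Riparian forest and woodland": {
            "Pterocarpus erinaceus": 0.20, "Mitragyna inermis": 0.20,
            "Terminalia macroptera": 0.15, "Anogeisus leiocarpus": 0.15,
            "Ficus sp": 0.10, "Crosopteryx febrifuga": 0.10,
            "Combretum glutinosum": 0.10,
        },
        "Savannah Woodland": {
            "Vitelaria paradoxa": 0.20, "Terminalia macroptera": 0.15,
            "Combretum glutinosum": 0.15, "Acacia seyal": 0.10,
            "Crosopteryx febrifuga": 0.10, "Anogeisus leiocarpus": 0.10,
            "Lannea microcrapa": 0.10, "Parkia biglobosa": 0.10,
        },
        "Shrub Savannah": {
            "Combretum glutinosum": 0.30, "Acacia seyal": 0.20,
            "Terminalia avicennioides": 0.20, "Lannea acida": 0.15,
            "Crosopteryx febrifuga": 0.15,
        },
        "Savannah grassland": {
            "Vitelaria paradoxa": 0.40, "Parkia biglobosa": 0.30,
            "Lannea microcrapa": 0.30,
        },
        "Cropland and Fallow": {
            "Vitelaria paradoxa": 0.45, "Parkia biglobosa": 0.30,
            "Lannea microcrapa": 0.15, "Lannea acida": 0.10,
        },
        "Settlements": {
            "Azadirachta indica": 0.70, "Parkia biglobosa": 0.20, "Ficus sp": 0.10,
        },
        "Agroforestry": {"Anacardium occidentale": 1.0},
        "Plantation": {
            "Eucalyptus grandis": 0.50, "Azadirachta indica": 0.30,
            "Acacia gourmaensis": 0.20,
        },
    }
    stems = {
        "Riparian forest and woodland": 1397.0, "Savannah Woodland": 800.0,
        "Shrub Savannah": 600.0, "Savannah grassland": 30.0,
        "Cropland and Fallow": 25.0, "Settlements": 60.0,
        "Agroforestry": 300.0, "Plantation": 1100.0,
    }
    targets = {
        "Riparian forest and woodland": 44.81, "Savannah Woodland": 21.35,
        "Shrub Savannah": 6.57, "Savannah grassland": 1.67,
        "Cropland and Fallow": 1.52, "Settlements": 2.30,
        "Agroforestry": 21.39, "Plantation": 1504.36 / 16.74,
    }
    dbh = {  # (median cm, log-SD, max cm)
        "Riparian forest and woodland": (12.0, 0.50, 60.0),
        "Savannah Woodland": (12.0, 0.50, 60.0),
        "Shrub Savannah": (8.0, 0.45, 40.0),
        "Savannah grassland": (25.0, 0.40, 80.0),
        "Cropland and Fallow": (25.0, 0.40, 80.0),
        "Settlements": (20.0, 0.50, 70.0),
        "Agroforestry": (15.0, 0.35, 45.0),
        "Plantation": (12.0, 0.45, 50.0),
    }
    areas = generate_area_table()
    classes = []
    for row in areas.itertuples(index=False):
        med, lsd, dmax = dbh[row.lulc]
        classes.append(LulcStandSpec(
            lulc=row.lulc, category=row.category,
            n_plots=int(row.n_plots),
            plot_width_m=float(row.plot_width_m),
            plot_length_m=float(row.plot_length_m),
            stems_per_ha=stems[row.lulc],
            species_mix=mixes[row.lulc],
            dbh_median_cm=med, dbh_log_sd=lsd, dbh_max_cm=dmax,
            target_carbon_density=targets[row.lulc],
        ))
    return StandGenSpec(classes=tuple(classes))


def _draw_tree_marks(cls: LulcStandSpec, rng, size: int):
    """(species index array, species list, dbh, height, rho) for *size* stems."""
    species = list(cls.species_mix)
    probs = np.array([cls.species_mix[s] for s in species])
    idx = rng.choice(len(species), size=size, p=probs)
    mu = np.log(cls.dbh_median_cm)
    d = np.exp(_truncnorm(rng, mu, cls.dbh_log_sd,
                          np.log(cls.dbh_min_cm), np.log(cls.dbh_max_cm), size))
    h = cls.height_coeff * d**cls.height_exp * np.exp(
        rng.normal(0.0, cls.height_log_sd, size))
    rho_mean = np.array([WOOD_DENSITY_G_CM3.get(normalize_species(s), _DEFAULT_RHO)
                         for s in species])[idx]
    rho = np.clip(rng.normal(rho_mean, _RHO_SD), 0.1, 1.5)
    return idx, species, d, h, rho


def _mean_carbon_per_stem(cls: LulcStandSpec, traits: TraitsTable, n_mc: int) -> float:
    """E[carbon fraction · (ρD²H)^b] per stem, fixed-seed Monte-Carlo (kg/a)."""
    rng = np.random.default_rng(_CALIBRATION_SEED)
    idx, species, d, h, rho = _draw_tree_marks(cls, rng, n_mc)
    frac = np.array([traits.fraction_for_species(s, "C")[0] for s in species])[idx]
    return float(np.mean(frac * (rho * d**2 * h) ** _POWER_B))


def calibrate_registry(
    spec: StandGenSpec,
    traits: TraitsTable | None = None,
    n_mc: int = 500_000,
) -> ModelRegistry:
    """Per-class power-product models scaled to the target carbon densities.

    For class ℓ the coefficient is a_ℓ = 1000·target_ℓ / (stems/ha_ℓ · m_ℓ)
    with m_ℓ the Monte-Carlo mark expectation, so the expected pipeline
    density equals the target.  Classes without a target fall through to the
    generic default model.
    """
    traits = traits or load_reference_traits()
    models = [AllometricModel("pantropical-default", "power_product", _DEFAULT_COEFFS)]
    for cls in spec.classes:
        for s in cls.species_mix:
            if s not in traits:
                raise ValueError(f"{cls.lulc}: species {s!r} not in the traits table")
        if cls.target_carbon_density is None or cls.stems_per_ha <= 0:
            continue
        m = _mean_carbon_per_stem(cls, traits, n_mc)
        a = 1000.0 * cls.target_carbon_density / (cls.stems_per_ha * m)
        models.append(AllometricModel(
            f"calibrated-{cls.lulc}", "power_product",
            {"a": a, "b": _POWER_B}, applies_to_lulc=(cls.lulc,),
        ))
    return ModelRegistry(models)


def generate_inventory(
    spec: StandGenSpec | None = None,
    seed: int = 0,
    traits: TraitsTable | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(plot register, tree census) for the whole design.

    Stem counts per plot are negative-binomial with mean stems/ha × plot
    area; treeless plots stay in the register as genuine zero observations.
    """
    spec = spec or default_stand_spec()
    traits = traits or load_reference_traits()
    rng = np.random.default_rng(seed)
    plot_rows, census = [], []
    for ci, cls in enumerate(spec.classes):
        for s in cls.species_mix:
            if s not in traits:
                raise ValueError(f"{cls.lulc}: species {s!r} not in the traits table")
        mu = cls.stems_per_ha * cls.area_ha
        if mu > 0:
            k = cls.nb_dispersion
            counts = rng.negative_binomial(k, k / (k + mu), size=cls.n_plots)
        else:
            counts = np.zeros(cls.n_plots, dtype=int)
        ids = [f"L{ci:02d}-{i + 1:03d}" for i in range(cls.n_plots)]
        for pid in ids:
            plot_rows.append({"plot_id": pid, "lulc": cls.lulc,
                              "width_m": cls.plot_width_m, "length_m": cls.plot_length_m})
        total = int(counts.sum())
        if total == 0:
            continue
        idx, species, d, h, rho = _draw_tree_marks(cls, rng, total)
        census.append(pd.DataFrame({
            "plot_id": np.repeat(ids, counts),
            "species": np.array(species, dtype=object)[idx],
            "dbh_cm": d,
            "height_m": h,
            "wood_density_g_cm3": rho,
        }))
    plots = pd.DataFrame(plot_rows)
    trees = (pd.concat(census, ignore_index=True) if census
             else pd.DataFrame(columns=["plot_id", "species", "dbh_cm",
                                        "height_m", "wood_density_g_cm3"]))
    return plots, trees


@dataclass
class SyntheticStudy:
    """A complete generated study: everything the pipeline needs to run."""

    seed: int
    traits_samples: pd.DataFrame
    traits: TraitsTable
    plots: pd.DataFrame
    census: pd.DataFrame
    registry: ModelRegistry
    areas: pd.DataFrame
    spec: StandGenSpec


def simulate_study(
    spec: StandGenSpec | None = None,
    seed: int = 0,
    traits: TraitsTable | None = None,
    calibration_mc: int = 500_000,
) -> SyntheticStudy:
    """Generate trait samples, plots, census and the calibrated registry."""
    spec = spec or default_stand_spec()
    traits = traits or load_reference_traits()
    rng = np.random.default_rng(seed)
    trait_seed, stand_seed = rng.integers(0, 2**31 - 1, size=2)
    samples = generate_trait_samples(default_trait_spec(), seed=int(trait_seed))
    plots, census = generate_inventory(spec, seed=int(stand_seed), traits=traits)
    registry = calibrate_registry(spec, traits, n_mc=calibration_mc)
    return SyntheticStudy(
        seed=seed, traits_samples=samples, traits=traits, plots=plots,
        census=census, registry=registry, areas=generate_area_table(), spec=spec,
    )


# ----------------------------------------------------------------------
# class map
# ----------------------------------------------------------------------
@dataclass
class ClassMap:
    """Categorical raster: integer class codes over a regular grid."""

    values: np.ndarray          # 2-D int array; nodata where unassigned
    classes: tuple[str, ...]    # code i ↔ classes[i]
    cellsize_m: float
    nodata: int = -1

    @property
    def cell_area_ha(self) -> float:
        return self.cellsize_m**2 / 10_000.0

    def class_areas_ha(self) -> pd.Series:
        vals, counts = np.unique(self.values[self.values != self.nodata],
                                 return_counts=True)
        return pd.Series({self.classes[v]: c * self.cell_area_ha
                          for v, c in zip(vals, counts)})


def generate_class_map(
    areas: pd.DataFrame | None = None,
    resolution_m: float = 100.0,
    seed: int = 0,
) -> ClassMap:
    """A synthetic stand-in for a classified land-cover map.

    Each class gets round(area / cell area) cells — within half a cell of the
    table — laid out as one contiguous block per class along a boustrophedon
    scan (consecutive scan cells are 4-adjacent, so each block is connected);
    class order is a seeded permutation.  Cells beyond the classified area
    are nodata.
    """
    if resolution_m <= 0:
        raise ValueError("resolution must be positive")
    areas = areas if areas is not None else generate_area_table()
    cell_ha = resolution_m**2 / 10_000.0
    names = tuple(areas["lulc"])
    counts = {row.lulc: int(round(row.area_ha / cell_ha))
              for row in areas.itertuples(index=False)}
    too_coarse = [k for k, v in counts.items() if v == 0]
    if too_coarse:
        raise ValueError(
            f"grid too coarse ({resolution_m} m) for classes {too_coarse}")
    total = sum(counts.values())
    ncols = int(np.ceil(np.sqrt(total)))
    nrows = int(np.ceil(total / ncols))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(names))
    flat = np.full(nrows * ncols, -1, dtype=np.int32)
    pos = 0
    for idx in order:
        n = counts[names[idx]]
        flat[pos:pos + n] = idx
        pos += n
    grid = flat.reshape(nrows, ncols)
    grid[1::2] = grid[1::2, ::-1]  # boustrophedon: reverse every other row
    return ClassMap(values=grid, classes=names, cellsize_m=float(resolution_m))
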