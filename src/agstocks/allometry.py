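"""Allometric models mapping tree measurements to oven-dry aboveground biomass.

A registry of published equations is routed per (species, LULC): species
overrides (palms do not follow the D²H scaling of dicot trees and get a
dedicated linear-in-D form) take precedence over LULC-specific equations,
which take precedence over a generic default.  Coefficients are configuration,
not code: a YAML file declares every model.

Supported functional forms (B in kg dry matter, D in cm, H in m, ρ in g/cm³):

``power_product``       B = a · (ρ · D² · H)^b
``power_dbh``           B = a · D^b
``linear_combination``  B = a + b·D + c·D²
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .traits import normalize_species

__all__ = [
    "AllometricModel",
    "ModelRegistry",
    "estimate_biomass",
    "default_registry",
    "DEFAULT_PALM_SPECIES",
]

FORMS = ("power_product", "power_dbh", "linear_combination")

#: species routed to the palm-style model by default
DEFAULT_PALM_SPECIES = ("Phoenix reclinata", "Borassus flabellifer")

#: generic pantropical moist/dry-forest default, B = 0.0673·(ρD²H)^0.976
_DEFAULT_COEFFS = {"a": 0.0673, "b": 0.976}


@dataclass(frozen=True)
class AllometricModel:
    model_id: str
    form: str
    coefficients: Mapping[str, float]
    applies_to_species: tuple[str, ...] = ()
    applies_to_lulc: tuple[str, ...] = ()
    dbh_range: tuple[float, float] | None = None  # cm validity interval

    def __post_init__(self) -> None:
        if self.form not in FORMS:
            raise ValueError(f"unknown form {self.form!r}; expected one of {FORMS}")
        needed = {"power_product": "ab", "power_dbh": "ab", "linear_combination": "abc"}[self.form]
        missing = [k for k in needed if k not in self.coefficients]
        if missing:
            raise ValueError(f"model {self.model_id!r} missing coefficients {missing}")
        if not all(np.isfinite(list(self.coefficients.values()))):
            raise ValueError(f"model {self.model_id!r} has non-finite coefficients")

    def __call__(self, dbh, height=None, wood_density=None):
        """Evaluate biomass (kg); scalar or vectorised over numpy arrays."""
        c = self.coefficients
        dbh = np.asarray(dbh, dtype=float)
        if np.any(dbh <= 0):
            raise ValueError("dbh must be positive")
        if self.form == "power_product":
            if height is None or wood_density is None:
                raise ValueError(f"model {self.model_id!r} needs height and wood density")
            height = np.asarray(height, dtype=float)
            rho = np.asarray(wood_density, dtype=float)
            if np.any(height <= 0):
                raise ValueError("height must be positive")
            out = c["a"] * (rho * dbh**2 * height) ** c["b"]
        elif self.form == "power_dbh":
            out = c["a"] * dbh ** c["b"]
        else:  # linear_combination
            out = c["a"] + c["b"] * dbh + c["c"] * dbh**2
        return out if out.ndim else float(out)


def estimate_biomass(model: AllometricModel, dbh, height=None, wood_density=None):
    """Evaluate *model*, warning (not failing) on out-of-range DBH.

    Extrapolation outside the fitted DBH interval is common in censuses (the
    fitting samples rarely span the full stand); it is flagged but allowed.
    """
    if model.dbh_range is not None:
        lo, hi = model.dbh_range
        d = np.asarray(dbh, dtype=float)
        n_out = int(np.count_nonzero((d < lo) | (d > hi)))
        if n_out:
            warnings.warn(
                f"{n_out} DBH value(s) outside model {model.model_id!r} "
                f"validity range [{lo}, {hi}] cm; extrapolating",
                stacklevel=2,
            )
    out = model(dbh, height=height, wood_density=wood_density)
    if np.any(np.asarray(out) < 0):
        raise ValueError(f"model {model.model_id!r} produced negative biomass")
    return out


class ModelRegistry:
    """Routing order: species-specific > LULC-specific > default.

    Exactly one model resolves for every (species, LULC) pair; construction
    fails if no default exists or two models claim the same route.
    """

    def __init__(self, models: Iterable[AllometricModel]):
        self.models = list(models)
        if not self.models:
            raise ValueError("empty registry")
        self._by_species: dict[str, AllometricModel] = {}
        self._by_lulc: dict[str, AllometricModel] = {}
        self._default: AllometricModel | None = None
        for m in self.models:
            for sp in m.applies_to_species:
                key = normalize_species(sp)
                if key in self._by_species:
                    raise ValueError(f"two models claim species {sp!r}")
                self._by_species[key] = m
            for lulc in m.applies_to_lulc:
                if lulc in self._by_lulc:
                    raise ValueError(f"two models claim LULC {lulc!r}")
                self._by_lulc[lulc] = m
            if not m.applies_to_species and not m.applies_to_lulc:
                if self._default is not None:
                    raise ValueError("two default models (no applicability scope)")
                self._default = m
        if self._default is None:
            raise ValueError("registry needs a default model (one with no scope)")

    def select(self, species: str, lulc: str) -> AllometricModel:
        m = self._by_species.get(normalize_species(species))
        if m is not None:
            return m
        return self._by_lulc.get(lulc, self._default)

    def predict(self, census: pd.DataFrame, plots: pd.DataFrame) -> np.ndarray:
        """Vectorised biomass (kg) for a census joined to its plot register.

        Needs census columns ``plot_id, species, dbh_cm, height_m,
        wood_density_g_cm3`` and plot columns ``plot_id, lulc``.
        """
        lulc = census["plot_id"].map(plots.set_index("plot_id")["lulc"])
        if lulc.isna().any():
            bad = census.loc[lulc.isna(), "plot_id"].unique()
            raise ValueError(f"census references unknown plots: {list(bad)[:5]}")
        out = np.empty(len(census), dtype=float)
        groups = pd.DataFrame({
            "species": census["species"].map(normalize_species).to_numpy(),
            "lulc": lulc.to_numpy(),
        })
        for (sp, lc), idx in groups.groupby(["species", "lulc"], sort=False).groups.items():
            m = self.select(sp, lc)
            loc = census.index.get_indexer(idx)
            out[loc] = np.asarray(estimate_biomass(
                m,
                census["dbh_cm"].to_numpy()[loc],
                census["height_m"].to_numpy()[loc],
                census["wood_density_g_cm3"].to_numpy()[loc],
            ))
        return out

    # ------------------------------------------------------------------
    @classmethod
    def from_config(cls, cfg: Sequence[Mapping]) -> "ModelRegistry":
        models = []
        for i, entry in enumerate(cfg):
            try:
                applies = entry.get("applies_to", {}) or {}
                models.append(AllometricModel(
                    model_id=entry["model_id"],
                    form=entry["form"],
                    coefficients=dict(entry["coefficients"]),
                    applies_to_species=tuple(applies.get("species", []) or []),
                    applies_to_lulc=tuple(applies.get("lulc", []) or []),
                    dbh_range=tuple(entry["dbh_range"]) if entry.get("dbh_range") else None,
                ))
            except (KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"registry entry #{i + 1}: {exc}") from exc
        return cls(models)

    @classmethod
    def from_yaml(cls, path) -> "ModelRegistry":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        if not isinstance(cfg, list):
            raise ValueError("registry YAML must be a list of model entries")
        return cls.from_config(cfg)

    def to_config(self) -> list[dict]:
        out = []
        for m in self.models:
            out.append({
                "model_id": m.model_id,
                "form": m.form,
                "coefficients": dict(m.coefficients),
                "applies_to": {
                    "species": list(m.applies_to_species),
                    "lulc": list(m.applies_to_lulc),
                },
                "dbh_range": list(m.dbh_range) if m.dbh_range else None,
            })
        return out

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_config(), fh, sort_keys=False)


def default_registry(palm_species: Sequence[str] = DEFAULT_PALM_SPECIES) -> ModelRegistry:
    """Generic registry: pantropical power-product default + palm override.

    The palm coefficients follow a coconut-style aboveground dry-mass curve
    (linear in D with a small quadratic term); both entries are meant to be
    replaced with locally fitted equations via the YAML registry.
    """
    return ModelRegistry([
        AllometricModel("pantropical-default", "power_product", _DEFAULT_COEFFS),
        AllometricModel(
            "palm-coconut", "linear_combination",
            {"a": -6.0, "b": 8.0, "c": 0.1},
            applies_to_species=tuple(palm_species),
            dbh_range=(10.0, 60.0),
        ),
    ])
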