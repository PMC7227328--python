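"""Per-species stem-wood carbon and nitrogen fractions.

Elemental analysis of stem-wood cores gives, for each main tree species of a
region, the fraction of oven-dry matter that is carbon or nitrogen.  This
module houses those trait summaries and resolves the fraction to apply to any
censused tree: the species-specific mean when the species was sampled, the
overall mean across sampled species otherwise (the higher-tier replacement for
the IPCC Tier 1 default of 0.47).

Fractions are stored as proportions in (0, 1); percent appears only at I/O
boundaries (the summary CSV mirrors field tables printed in percent of dry
matter).
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "WoodSample",
    "StatSummary",
    "SpeciesTraits",
    "TraitsTable",
    "summarize_species",
    "normalize_species",
    "load_reference_traits",
]

Element = Literal["C", "N"]

#: columns of the percent-scale summary CSV (species rows, stats as printed)
SUMMARY_COLUMNS = [
    "species", "n", "c_min", "c_max", "c_mean", "c_se",
    "n_min", "n_max", "n_mean", "n_se", "cn_mean", "cn_se",
]


def normalize_species(name: str) -> str:
    """Canonical matching key: case-folded, whitespace-collapsed binomial.

    Open nomenclature like ``"Ficus sp"`` is matched literally (after the
    same normalisation), not expanded.
    """
    return re.sub(r"\s+", " ", str(name).strip()).casefold()


@dataclass(frozen=True)
class WoodSample:
    """One stem-wood sample taken at breast height (1.3 m)."""

    species: str
    carbon_fraction: float   # proportion of dry matter
    nitrogen_fraction: float  # proportion of dry matter
    dbh: float | None = None  # cm

    def __post_init__(self) -> None:
        if not 0.0 < self.carbon_fraction < 1.0:
            raise ValueError(f"carbon_fraction must be in (0, 1), got {self.carbon_fraction}")
        if not 0.0 < self.nitrogen_fraction < self.carbon_fraction:
            raise ValueError(
                "nitrogen_fraction must be in (0, carbon_fraction), got "
                f"{self.nitrogen_fraction}"
            )
        if self.dbh is not None and self.dbh < 5:
            raise ValueError(f"dbh below the 5 cm census threshold: {self.dbh}")

    @property
    def cn_ratio(self) -> float:
        return self.carbon_fraction / self.nitrogen_fraction


@dataclass(frozen=True)
class StatSummary:
    """mean / SE / min / max of one trait (SE of the mean, n−1 sample SD)."""

    mean: float
    se: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if not (self.min <= self.mean <= self.max):
            raise ValueError(f"mean {self.mean} outside [{self.min}, {self.max}]")
        if self.se < 0:
            raise ValueError("SE must be non-negative")


@dataclass(frozen=True)
class SpeciesTraits:
    species: str
    n_samples: int
    carbon: StatSummary    # proportions of dry matter
    nitrogen: StatSummary  # proportions of dry matter
    cn_ratio: StatSummary  # dimensionless


def _summary(values: np.ndarray) -> StatSummary:
    n = values.size
    if n >= 2:
        se = float(np.std(values, ddof=1) / math.sqrt(n))
    else:
        warnings.warn("single sample: SE reported as 0", stacklevel=3)
        se = 0.0
    return StatSummary(float(np.mean(values)), se, float(np.min(values)), float(np.max(values)))


def summarize_species(samples: Iterable[WoodSample]) -> SpeciesTraits:
    """Summarise C, N and per-sample C/N ratio for one species.

    SE is the standard error of the mean (sample SD with n−1 denominator over
    √n), reported as 0 with a warning for a single sample.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("no samples given")
    keys = {normalize_species(s.species) for s in samples}
    if len(keys) > 1:
        raise ValueError(f"samples mix species: {sorted(keys)}")
    c = np.array([s.carbon_fraction for s in samples])
    n = np.array([s.nitrogen_fraction for s in samples])
    return SpeciesTraits(
        species=samples[0].species,
        n_samples=len(samples),
        carbon=_summary(c),
        nitrogen=_summary(n),
        cn_ratio=_summary(c / n),
    )


@dataclass
class TraitsTable:
    """Trait summaries for the sampled ("main") species plus overall means.

    Parameters
    ----------
    entries
        One :class:`SpeciesTraits` per species.
    weighting
        ``"species"`` (default) averages the per-species means with equal
        weight; ``"samples"`` weights each species mean by its sample count.
        The unweighted mean is the convention used when a region's overall
        stem-wood carbon fraction is quoted against the Tier 1 default.
    """

    entries: dict[str, SpeciesTraits] = field(default_factory=dict)
    weighting: Literal["species", "samples"] = "species"

    @classmethod
    def from_entries(cls, entries: Iterable[SpeciesTraits], weighting="species") -> "TraitsTable":
        table = cls(weighting=weighting)
        for e in entries:
            key = normalize_species(e.species)
            if key in table.entries:
                raise ValueError(f"duplicate species: {e.species}")
            table.entries[key] = e
        return table

    @classmethod
    def from_samples(cls, samples: Iterable[WoodSample], weighting="species") -> "TraitsTable":
        by_species: dict[str, list[WoodSample]] = {}
        for s in samples:
            by_species.setdefault(normalize_species(s.species), []).append(s)
        return cls.from_entries(
            (summarize_species(group) for group in by_species.values()), weighting=weighting
        )

    @classmethod
    def from_summary_frame(cls, df: pd.DataFrame, weighting="species") -> "TraitsTable":
        """Build from a percent-scale summary table (as printed in the field).

        Expects at least ``species, n, c_min, c_max, c_mean, c_se, n_min,
        n_max, n_mean, n_se``; ``cn_*`` columns are optional and derived from
        the means when absent.
        """
        entries = []
        for row in df.itertuples(index=False):
            d = row._asdict()
            cn_mean = d.get("cn_mean", d["c_mean"] / d["n_mean"])
            cn_se = d.get("cn_se", 0.0)
            cn_min = d.get("cn_min", cn_mean)
            cn_max = d.get("cn_max", cn_mean)
            entries.append(
                SpeciesTraits(
                    species=d["species"],
                    n_samples=int(d["n"]),
                    carbon=StatSummary(d["c_mean"] / 100, d["c_se"] / 100,
                                       d["c_min"] / 100, d["c_max"] / 100),
                    nitrogen=StatSummary(d["n_mean"] / 100, d["n_se"] / 100,
                                         d["n_min"] / 100, d["n_max"] / 100),
                    cn_ratio=StatSummary(cn_mean, cn_se, cn_min, cn_max),
                )
            )
        return cls.from_entries(entries, weighting=weighting)

    @classmethod
    def from_summary_csv(cls, path, weighting="species") -> "TraitsTable":
        return cls.from_summary_frame(pd.read_csv(path, comment="#"), weighting=weighting)

    # ------------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, species: str) -> bool:
        return normalize_species(species) in self.entries

    def _stat(self, entry: SpeciesTraits, element: Element) -> StatSummary:
        if element == "C":
            return entry.carbon
        if element == "N":
            return entry.nitrogen
        raise ValueError(f"element must be 'C' or 'N', got {element!r}")

    def overall_mean_fraction(self, element: Element) -> float:
        """Overall mean fraction across the table (C_mc / N_mn analogue)."""
        if not self.entries:
            raise ValueError("empty traits table")
        means = np.array([self._stat(e, element).mean for e in self.entries.values()])
        if self.weighting == "samples":
            w = np.array([e.n_samples for e in self.entries.values()], dtype=float)
            return float(np.average(means, weights=w))
        return float(means.mean())

    def fraction_for_species(self, species: str, element: Element) -> tuple[float, str]:
        """Fraction applied to a tree of *species*, with provenance.

        Returns ``(fraction, provenance)`` where provenance is
        ``"species-specific"`` when the species was sampled and
        ``"fallback"`` when the overall mean is substituted.
        """
        if not self.entries:
            raise ValueError("empty traits table")
        entry = self.entries.get(normalize_species(species))
        if entry is not None:
            return self._stat(entry, element).mean, "species-specific"
        return self.overall_mean_fraction(element), "fallback"

    def fractions_for(self, species: Iterable[str], element: Element
                      ) -> tuple[np.ndarray, np.ndarray]:
        """Vectorised :meth:`fraction_for_species` over a census column.

        Returns ``(fractions, is_fallback)`` arrays aligned with the input.
        """
        fallback = self.overall_mean_fraction(element)
        lut = {k: self._stat(e, element).mean for k, e in self.entries.items()}
        keys = [normalize_species(s) for s in species]
        frac = np.array([lut.get(k, fallback) for k in keys])
        fb = np.array([k not in lut for k in keys])
        return frac, fb

    def to_summary_frame(self) -> pd.DataFrame:
        """Percent-scale summary rows, one per species."""
        rows = []
        for e in self.entries.values():
            rows.append({
                "species": e.species, "n": e.n_samples,
                "c_min": e.carbon.min * 100, "c_max": e.carbon.max * 100,
                "c_mean": e.carbon.mean * 100, "c_se": e.carbon.se * 100,
                "n_min": e.nitrogen.min * 100, "n_max": e.nitrogen.max * 100,
                "n_mean": e.nitrogen.mean * 100, "n_se": e.nitrogen.se * 100,
                "cn_mean": e.cn_ratio.mean, "cn_se": e.cn_ratio.se,
            })
        return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def load_reference_traits(weighting: Literal["species", "samples"] = "species") -> TraitsTable:
    """The packaged 18-species Sudan-Savannah stem-wood trait table.

    277 samples across 18 main species; the species-weighted overall carbon
    mean is 0.4701 and the nitrogen mean 0.00229 (proportions of dry matter).
    """
    with resources.files("agstocks.fixtures").joinpath("species_traits_summary.csv").open() as fh:
        return TraitsTable.from_summary_csv(fh, weighting=weighting)


def reference_summary_frame() -> pd.DataFrame:
    """Raw packaged trait-summary table (percent scale, all printed columns)."""
    with resources.files("agstocks.fixtures").joinpath("species_traits_summary.csv").open() as fh:
        return pd.read_csv(fh)
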