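"""ESRI ASCII grid I/O and class-constant stock-map rendering.

The stock map assigns every cell of a categorical land-cover raster its
class's mean density (Mg/ha) — a class-constant surface, not per-pixel
biomass.  The ASCII grid format is plain text and readable by any desktop
GIS; georeferencing (corner, cell size, nodata) is copied from the input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .synthetic import ClassMap

__all__ = ["AsciiGrid", "write_ascii_grid", "read_ascii_grid", "render_stock_map"]


@dataclass
class AsciiGrid:
    values: np.ndarray
    cellsize: float
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    nodata: float = -9999.0


def write_ascii_grid(path, grid: AsciiGrid, fmt: str = "%.6g") -> None:
    arr = np.asarray(grid.values)
    header = (
        f"ncols {arr.shape[1]}\n"
        f"nrows {arr.shape[0]}\n"
        f"xllcorner {grid.xllcorner}\n"
        f"yllcorner {grid.yllcorner}\n"
        f"cellsize {grid.cellsize}\n"
        f"NODATA_value {grid.nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, arr, fmt=fmt)


def read_ascii_grid(path) -> AsciiGrid:
    meta: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            meta[key.lower()] = float(val)
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)
    if values.shape != (int(meta["nrows"]), int(meta["ncols"])):
        raise ValueError(f"{path}: grid shape does not match header")
    return AsciiGrid(
        values=values, cellsize=meta["cellsize"],
        xllcorner=meta.get("xllcorner", 0.0), yllcorner=meta.get("yllcorner", 0.0),
        nodata=meta.get("nodata_value", -9999.0),
    )


def render_stock_map(
    class_map: ClassMap,
    densities: Mapping[str, float],
    nodata: float = -9999.0,
) -> AsciiGrid:
    """Continuous density raster (Mg/ha) from a class map and class means.

    Every class present in the raster must have a density; nodata cells pass
    through unchanged.
    """
    present = np.unique(class_map.values[class_map.values != class_map.nodata])
    missing = [class_map.classes[i] for i in present
               if class_map.classes[i] not in densities]
    if missing:
        raise ValueError(f"no density estimate for raster classes: {missing}")
    lut = np.full(len(class_map.classes), nodata)
    for i in present:
        lut[i] = densities[class_map.classes[i]]
    out = np.where(class_map.values == class_map.nodata, nodata,
                   lut[np.clip(class_map.values, 0, len(lut) - 1)])
    return AsciiGrid(values=out, cellsize=class_map.cellsize_m, nodata=nodata)
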