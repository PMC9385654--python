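"""Gridded abiotic surfaces and scalar time-series curves.

Rasters are regular lon/lat grids carried as a small ``Raster`` class
with plain-text (ESRI ASCII grid) I/O, one file per variable per time
slice with the slice age encoded in the filename
(``<variable>_<age>ma.asc``). Time slices provided at coarse intervals
(e.g. every 5 Myr) are linearly interpolated in age; scalar curves
(global temperature, CO2) are CSVs with columns ``age_ma, value``.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Raster",
    "RasterStack",
    "Curve",
    "read_ascii_grid",
    "interpolate_time_slices",
]


@dataclass
class Raster:
    """A regular lon/lat grid. Row 0 is the northernmost row."""

    values: np.ndarray  # [nrows, ncols], np.nan marks no-data
    xll: float  # longitude of the lower-left corner
    yll: float  # latitude of the lower-left corner
    cellsize: float  # degrees

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def grid_matches(self, other: "Raster") -> bool:
        return (
            self.values.shape == other.values.shape
            and self.xll == other.xll
            and self.yll == other.yll
            and self.cellsize == other.cellsize
        )

    def cell_index(self, lon: float, lat: float) -> tuple[int, int]:
        """Row/column of the cell containing a point."""
        col = int(math.floor((lon - self.xll) / self.cellsize))
        row_from_bottom = int(math.floor((lat - self.yll) / self.cellsize))
        row = self.nrows - 1 - row_from_bottom
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise ValueError(f"point ({lon}, {lat}) outside the raster extent")
        return row, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        lon = self.xll + (col + 0.5) * self.cellsize
        lat = self.yll + (self.nrows - 1 - row + 0.5) * self.cellsize
        return lon, lat

    def sample(self, lon: float, lat: float, search_radius_cells: int = 3) -> float:
        """Value of the containing cell, nearest valid cell if no-data.

        The fallback scans rings of cells around the target up to
        ``search_radius_cells`` away and raises if none holds data.
        """
        row, col = self.cell_index(lon, lat)
        v = self.values[row, col]
        if np.isfinite(v):
            return float(v)
        for radius in range(1, search_radius_cells + 1):
            best = None
            for dr in range(-radius, radius + 1):
                for dc in range(-radius, radius + 1):
                    if max(abs(dr), abs(dc)) != radius:
                        continue
                    r, c = row + dr, col + dc
                    if 0 <= r < self.nrows and 0 <= c < self.ncols:
                        w = self.values[r, c]
                        if np.isfinite(w):
                            d2 = dr * dr + dc * dc
                            if best is None or d2 < best[0]:
                                best = (d2, float(w))
            if best is not None:
                return best[1]
        raise ValueError(
            f"no valid raster cell within {search_radius_cells} cells of "
            f"({lon}, {lat})"
        )

    def to_ascii(self, path, nodata: float = -9999.0) -> None:
        vals = np.where(np.isfinite(self.values), self.values, nodata)
        with open(path, "w") as fh:
            fh.write(f"ncols {self.ncols}\n")
            fh.write(f"nrows {self.nrows}\n")
            fh.write(f"xllcorner {self.xll}\n")
            fh.write(f"yllcorner {self.yll}\n")
            fh.write(f"cellsize {self.cellsize}\n")
            fh.write(f"NODATA_value {nodata}\n")
            for row in vals:
                fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(path) -> Raster:
    """Read a plain-text (ESRI ASCII) grid file."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"grid file {path} is missing header field {key!r}")
    values = np.loadtxt(lines[n_header:], dtype=float)
    values = np.atleast_2d(values)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"grid file {path}: data shape does not match header")
    if "nodata_value" in header:
        values = np.where(values == header["nodata_value"], np.nan, values)
    return Raster(
        values=values,
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cellsize=header["cellsize"],
    )


_AGE_RE = re.compile(r"_(\d+(?:\.\d+)?)ma\.", re.IGNORECASE)


class RasterStack:
    """Time-sliced rasters for one variable, indexed by slice age (Ma)."""

    def __init__(self, slices: dict[float, Raster]):
        if not slices:
            raise ValueError("empty raster stack")
        self.ages = sorted(slices)
        self.slices = {float(a): slices[a] for a in slices}
        ref = self.slices[self.ages[0]]
        for age in self.ages[1:]:
            if not self.slices[age].grid_matches(ref):
                raise ValueError("raster stack grids are not aligned")

    @classmethod
    def from_directory(cls, directory, variable: str) -> "RasterStack":
        """Load ``<variable>_<age>ma.asc`` files from a directory."""
        slices = {}
        for path in sorted(Path(directory).glob(f"{variable}_*ma.asc")):
            match = _AGE_RE.search(path.name)
            if match:
                slices[float(match.group(1))] = read_ascii_grid(path)
        if not slices:
            raise ValueError(f"no {variable!r} grids found in {directory}")
        return cls(slices)

    def at_age(self, query_age_ma: float) -> Raster:
        return interpolate_time_slices(self, query_age_ma)


def interpolate_time_slices(stack: RasterStack, query_age_ma: float) -> Raster:
    """Cellwise linear interpolation between the two bracketing slices.

    An exact slice age returns that slice; queries outside the covered
    age range clamp to the nearest slice with a warning.
    """
    ages = stack.ages
    if query_age_ma in stack.slices:
        return stack.slices[query_age_ma]
    if query_age_ma < ages[0] or query_age_ma > ages[-1]:
        warnings.warn(
            f"query age {query_age_ma} Ma outside slice range "
            f"[{ages[0]}, {ages[-1]}]; clamping to the nearest slice"
        )
        nearest = ages[0] if query_age_ma < ages[0] else ages[-1]
        return stack.slices[nearest]
    upper_pos = int(np.searchsorted(ages, query_age_ma))
    a0, a1 = ages[upper_pos - 1], ages[upper_pos]
    w = (query_age_ma - a0) / (a1 - a0)
    r0, r1 = stack.slices[a0], stack.slices[a1]
    return Raster(
        values=(1.0 - w) * r0.values + w * r1.values,
        xll=r0.xll,
        yll=r0.yll,
        cellsize=r0.cellsize,
    )


class Curve:
    """A scalar time series (e.g. global temperature, CO2) on an age grid."""

    def __init__(self, ages_ma, values):
        ages = np.asarray(ages_ma, dtype=float)
        vals = np.asarray(values, dtype=float)
        if ages.ndim != 1 or ages.shape != vals.shape or ages.size < 2:
            raise ValueError("curve needs matching 1-D ages and values, n >= 2")
        order = np.argsort(ages)
        self.ages = ages[order]
        self.values = vals[order]

    @classmethod
    def from_csv(cls, path) -> "Curve":
        frame = pd.read_csv(path)
        if not {"age_ma", "value"} <= set(frame.columns):
            raise ValueError(f"curve CSV {path} needs columns age_ma, value")
        return cls(frame["age_ma"].to_numpy(), frame["value"].to_numpy())

    def at(self, age_ma) -> np.ndarray | float:
        """Linear interpolation at an age; clamped at the curve's ends."""
        out = np.interp(np.asarray(age_ma, dtype=float), self.ages, self.values)
        return float(out) if np.isscalar(age_ma) else out

    def to_csv(self, path) -> None:
        pd.DataFrame({"age_ma": self.ages, "value": self.values}).to_csv(
            path, index=False
        )
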