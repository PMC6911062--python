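"""Regular-grid study region, covariate surfaces and ASCII-grid I/O.

The study region is a regular grid of square cells (study value: 1 x 1 km
cells on the IFBL reference grid).  Cells use a half-open convention
``[left, right) x [bottom, top)`` with the origin at the lower-left
corner, so every point in the extent maps to exactly one cell.  Cell-level
covariates are the proportion of wet landscape (W), the relative coverage
of valuable nature (V) and the relative forest cover (F), each in [0, 1];
point-referenced records inherit the value of their containing cell (no
interpolation — covariates only exist at cell resolution).

Surfaces are read and written as ESRI ASCII grids (.asc) with grid
metadata in a JSON sidecar; coordinates are (easting, northing) in km.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "Grid",
    "CovariateSurface",
    "HomeLocation",
    "make_grid",
    "locate_cell",
    "distance_to_home",
    "covariate_at",
    "read_ascii_grid",
    "write_ascii_grid",
]

NODATA = -9999.0


class OutOfDomainError(ValueError):
    """A point falls outside the grid extent (or in a masked cell where forbidden)."""


@dataclass(frozen=True)
class Grid:
    """Regular grid of square cells; values are stored row-major with row 0 at the bottom."""

    origin: tuple[float, float]  # lower-left corner (easting, northing) km
    cell_size: float  # km
    n_cols: int
    n_rows: int
    mask: np.ndarray | None = None  # (n_rows, n_cols) bool, True = inside study region

    def __post_init__(self) -> None:
        if self.cell_size <= 0 or self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid needs positive cell_size and at least one cell")
        if self.mask is not None and self.mask.shape != (self.n_rows, self.n_cols):
            raise ValueError("mask shape must be (n_rows, n_cols)")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def extent(self) -> tuple[float, float, float, float]:
        x0, y0 = self.origin
        return (x0, y0, x0 + self.n_cols * self.cell_size, y0 + self.n_rows * self.cell_size)

    @property
    def cell_area(self) -> float:
        return self.cell_size**2

    def cell_centers(self) -> np.ndarray:
        """(n_cells, 2) centers, row-major from the bottom-left cell."""
        x0, y0 = self.origin
        cols = x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size
        rows = y0 + (np.arange(self.n_rows) + 0.5) * self.cell_size
        xx, yy = np.meshgrid(cols, rows)
        return np.column_stack([xx.ravel(), yy.ravel()])

    def active(self) -> np.ndarray:
        """Flat boolean selector of unmasked cells."""
        if self.mask is None:
            return np.ones(self.n_cells, dtype=bool)
        return self.mask.ravel()

    def refine(self, factor: int) -> "Grid":
        """A grid over the same extent with cells ``factor`` times smaller."""
        if factor < 1 or int(factor) != factor:
            raise ValueError("refinement factor must be a positive integer")
        mask = None
        if self.mask is not None:
            mask = np.repeat(np.repeat(self.mask, factor, axis=0), factor, axis=1)
        return Grid(
            origin=self.origin,
            cell_size=self.cell_size / factor,
            n_cols=self.n_cols * factor,
            n_rows=self.n_rows * factor,
            mask=mask,
        )


@dataclass(frozen=True)
class CovariateSurface:
    """One cell-level covariate in [0, 1] (W, V or F); masked cells carry NaN."""

    grid: Grid
    name: str
    values: np.ndarray  # flat, length n_cells, row-major from bottom-left

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (self.grid.n_cells,):
            raise ValueError("values must be flat with one entry per grid cell")
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError(f"covariate {self.name!r} must lie in [0, 1]")
        object.__setattr__(self, "values", vals)


@dataclass(frozen=True)
class HomeLocation:
    """Reference point (collectors' residential municipality) for distance-to-home D(x)."""

    coordinates: tuple[float, float]


def make_grid(bbox, cell_size: float, mask_rule=None) -> Grid:
    """Grid covering ``bbox = (xmin, ymin, xmax, ymax)``; cell counts round up.

    ``mask_rule``, if given, is a vectorized predicate on cell-center
    coordinates returning True for cells inside the study region.
    """
    xmin, ymin, xmax, ymax = map(float, bbox)
    if not (xmax > xmin and ymax > ymin):
        raise ValueError(f"degenerate bbox {bbox}")
    if cell_size <= 0:
        raise ValueError("cell_size must be > 0")
    n_cols = int(np.ceil((xmax - xmin) / cell_size))
    n_rows = int(np.ceil((ymax - ymin) / cell_size))
    grid = Grid(origin=(xmin, ymin), cell_size=cell_size, n_cols=n_cols, n_rows=n_rows)
    if mask_rule is not None:
        centers = grid.cell_centers()
        mask = np.asarray(mask_rule(centers), dtype=bool).reshape(n_rows, n_cols)
        grid = Grid(grid.origin, grid.cell_size, n_cols, n_rows, mask=mask)
    return grid


def locate_cell(points, grid: Grid) -> np.ndarray:
    """Flat cell index for each point, half-open convention per axis.

    A point on an interior right/top edge belongs to the cell on the
    right/above.  Points on the outer right/top boundary of the extent are
    out of domain (the extent itself is half-open).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    x0, y0, x1, y1 = grid.extent
    cols = np.floor((pts[:, 0] - x0) / grid.cell_size).astype(int)
    rows = np.floor((pts[:, 1] - y0) / grid.cell_size).astype(int)
    bad = (cols < 0) | (cols >= grid.n_cols) | (rows < 0) | (rows >= grid.n_rows)
    if np.any(bad):
        raise OutOfDomainError(
            f"{bad.sum()} point(s) outside grid extent {grid.extent}: indices {np.flatnonzero(bad).tolist()}"
        )
    idx = rows * grid.n_cols + cols
    return idx if np.asarray(points).ndim == 2 else int(idx[0])


def distance_to_home(points, home: HomeLocation) -> np.ndarray | float:
    """Euclidean distance D(x) in km from each point to the home location."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d = np.hypot(pts[:, 0] - home.coordinates[0], pts[:, 1] - home.coordinates[1])
    return d if np.asarray(points).ndim == 2 else float(d[0])


def covariate_at(points, surface: CovariateSurface) -> np.ndarray | float:
    """Containing-cell covariate lookup (piecewise constant); masked cells give NaN."""
    idx = locate_cell(points, surface.grid)
    vals = surface.values[np.atleast_1d(idx)]
    if surface.grid.mask is not None:
        vals = np.where(surface.grid.active()[np.atleast_1d(idx)], vals, np.nan)
    return vals if np.asarray(points).ndim == 2 else float(vals[0])


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O.  Rows in the file run top to bottom; internal storage
# is row-major from the bottom-left, so rows are flipped on read/write.

def write_ascii_grid(path, grid: Grid, values, nodata: float = NODATA, units: str = "km") -> None:
    """Write a flat per-cell vector as an ESRI .asc file plus a JSON sidecar."""
    path = Path(path)
    vals = np.asarray(values, dtype=float).reshape(grid.n_rows, grid.n_cols)
    out = np.where(np.isfinite(vals), vals, nodata)
    if grid.mask is not None:
        out = np.where(grid.mask, out, nodata)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin[0]:.10g}\n"
        f"yllcorner {grid.origin[1]:.10g}\n"
        f"cellsize {grid.cell_size:.10g}\n"
        f"NODATA_value {nodata:.10g}\n"
    )
    body = "\n".join(" ".join(f"{v:.10g}" for v in row) for row in out[::-1])
    path.write_text(header + body + "\n")
    sidecar = {"units": units, "origin": list(grid.origin), "cell_size": grid.cell_size,
               "n_cols": grid.n_cols, "n_rows": grid.n_rows}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_ascii_grid(path, units: str = "km") -> tuple[Grid, np.ndarray]:
    """Read an ESRI .asc file; returns (grid, flat values) with NODATA as NaN.

    ``units='m'`` converts origin/cell size from metres to km on read.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    header: dict[str, float] = {}
    body_start = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            body_start = i + 1
        else:
            break
    scale = 1e-3 if units == "m" else 1.0
    nodata = header.get("nodata_value", NODATA)
    rows = np.array([[float(v) for v in line.split()] for line in lines[body_start:] if line.strip()])
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if rows.shape != (n_rows, n_cols):
        raise ValueError(f"grid body shape {rows.shape} does not match header ({n_rows}, {n_cols})")
    values = rows[::-1].ravel()
    values = np.where(values == nodata, np.nan, values)
    grid = Grid(
        origin=(header["xllcorner"] * scale, header["yllcorner"] * scale),
        cell_size=header["cellsize"] * scale,
        n_cols=n_cols,
        n_rows=n_rows,
    )
    return grid, values
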