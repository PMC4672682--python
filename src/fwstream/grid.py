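"""Grid geometry and raster containers.

All grids in fwstream share one convention: 0-based (row, col) indexing,
row-major storage, row 0 at the northern edge ("north-up"), cell-edge
registration in geographic (WGS84) coordinates.  The default cell size is
1/120 degree, i.e. 30 arc-seconds.

Two light containers are defined here:

``GridGeometry``
    the georeferencing of a raster: west/north edge, cell size, shape.
``Raster``
    a 2-D array plus its geometry and a NoData sentinel.  Used for every
    environmental variable, for elevation, and (with integer codes) for
    flow direction, Strahler order and masks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import GeometryError

#: default cell size: 30 arc-seconds in degrees
ARCSEC30 = 1.0 / 120.0

# ---------------------------------------------------------------------------
# D8 neighbour scheme
# ---------------------------------------------------------------------------
# Neighbour scan order is fixed (E, SE, S, SW, W, NW, N, NE) and doubles as
# the tie-break order for steepest descent, giving bit-reproducible routing.
D8_OFFSETS: tuple[tuple[int, int], ...] = (
    (0, 1),    # 0 E
    (1, 1),    # 1 SE
    (1, 0),    # 2 S
    (1, -1),   # 3 SW
    (0, -1),   # 4 W
    (-1, -1),  # 5 NW
    (-1, 0),   # 6 N
    (-1, 1),   # 7 NE
)
#: step length of each D8 direction in cell units
D8_DISTANCES: tuple[float, ...] = tuple(
    math.hypot(dr, dc) for dr, dc in D8_OFFSETS
)
#: flow-direction code for a terminal cell (drains off-grid or into NoData)
SINK: int = -1
#: flow-direction code for NoData cells
FD_NODATA: int = -2


@dataclass(frozen=True)
class GridGeometry:
    """Cell-edge registered north-up grid in geographic coordinates.

    Parameters
    ----------
    west, north : float
        Longitude of the western edge and latitude of the northern edge, in
        degrees.  Cell (0, 0) has its upper-left corner at (west, north).
    cellsize : float
        Cell size in degrees (square cells).
    nrows, ncols : int
        Grid shape.
    """

    west: float
    north: float
    cellsize: float
    nrows: int
    ncols: int

    def __post_init__(self) -> None:
        if self.cellsize <= 0:
            raise GeometryError(f"cell size must be positive, got {self.cellsize}")
        if self.nrows < 1 or self.ncols < 1:
            raise GeometryError(f"empty grid {self.nrows}x{self.ncols}")

    @property
    def east(self) -> float:
        return self.west + self.ncols * self.cellsize

    @property
    def south(self) -> float:
        return self.north - self.nrows * self.cellsize

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @classmethod
    def from_bounds(
        cls,
        west: float,
        east: float,
        south: float,
        north: float,
        cellsize: float = ARCSEC30,
        tol: float = 1e-9,
    ) -> "GridGeometry":
        """Build a geometry from edge coordinates.

        The spans must be integer multiples of ``cellsize`` to within ``tol``
        degrees; the near-global 30 arc-second layout (145W-180E, 39,000
        columns) is the motivating case.
        """
        if east <= west or north <= south:
            raise GeometryError("bounds must satisfy east>west and north>south")
        ncols_f = (east - west) / cellsize
        nrows_f = (north - south) / cellsize
        ncols = round(ncols_f)
        nrows = round(nrows_f)
        if abs(ncols_f - ncols) * cellsize > tol or abs(nrows_f - nrows) * cellsize > tol:
            raise GeometryError(
                f"spans ({east - west}, {north - south}) are not multiples of "
                f"cell size {cellsize}"
            )
        return cls(west=west, north=north, cellsize=cellsize, nrows=nrows, ncols=ncols)

    def matches(self, other: "GridGeometry", tol: float = 1e-12) -> bool:
        return (
            self.shape == other.shape
            and abs(self.west - other.west) <= tol
            and abs(self.north - other.north) <= tol
            and abs(self.cellsize - other.cellsize) <= tol
        )


def grid_shape(geometry: GridGeometry) -> tuple[int, int]:
    """Shape ``(nrows, ncols)`` of a geometry (convenience accessor)."""
    return geometry.shape


def default_geometry(nrows: int, ncols: int, cellsize: float = ARCSEC30) -> GridGeometry:
    """A placeholder geometry anchored at (0E, 0N) for synthetic grids."""
    return GridGeometry(west=0.0, north=0.0, cellsize=cellsize, nrows=nrows, ncols=ncols)


@dataclass
class Raster:
    """A 2-D data grid with geometry and NoData sentinel.

    ``values`` keeps its native dtype (float for continuous variables,
    integer for codes/counts); cells equal to ``nodata`` are invalid.
    """

    values: np.ndarray
    geometry: GridGeometry
    nodata: float | int | None = None
    units: str = ""
    crs: str = "EPSG:4326"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise GeometryError(f"raster must be 2-D, got shape {self.values.shape}")
        if self.values.shape != self.geometry.shape:
            raise GeometryError(
                f"values shape {self.values.shape} != geometry shape {self.geometry.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask, True where the cell holds data."""
        if self.nodata is None:
            if np.issubdtype(self.values.dtype, np.floating):
                return ~np.isnan(self.values)
            return np.ones(self.shape, dtype=bool)
        mask = self.values != self.nodata
        if np.issubdtype(self.values.dtype, np.floating):
            mask &= ~np.isnan(self.values)
        return mask

    def masked(self) -> np.ndarray:
        """Float copy with NoData cells as NaN."""
        out = self.values.astype(float, copy=True)
        out[~self.valid] = np.nan
        return out

    def with_values(self, values: np.ndarray, **kwargs) -> "Raster":
        """New raster sharing this geometry (and metadata unless overridden)."""
        out = replace(self, values=np.asarray(values))
        for key, val in kwargs.items():
            setattr(out, key, val)
        return out

    def require_same_geometry(self, other: "Raster | FlowDirectionGrid") -> None:
        if not self.geometry.matches(other.geometry):
            raise GeometryError("rasters are on different grid geometries")


# ElevationGrid and EnvGrid are the same container; the aliases make call
# signatures read like the domain they model.
ElevationGrid = Raster
EnvGrid = Raster


@dataclass
class FlowDirectionGrid:
    """Per-cell D8 drainage direction.

    ``codes`` holds 0..7 (index into :data:`D8_OFFSETS`), :data:`SINK` for
    terminal cells and :data:`FD_NODATA` outside the data area.  The induced
    cell-to-downstream-cell graph is a forest (acyclic, out-degree <= 1).
    """

    codes: np.ndarray
    geometry: GridGeometry

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != self.geometry.shape:
            raise GeometryError(
                f"codes shape {self.codes.shape} != geometry shape {self.geometry.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    @property
    def valid(self) -> np.ndarray:
        return self.codes != FD_NODATA

    def downstream_index(self) -> np.ndarray:
        """Flat index of each cell's downstream cell; -1 for sinks/NoData.

        The array is the whole donor graph in one vector: ``down[i]`` is the
        row-major index the cell ``i`` drains into.
        """
        nrows, ncols = self.shape
        down = np.full(nrows * ncols, -1, dtype=np.int64)
        codes = self.codes
        for code, (dr, dc) in enumerate(D8_OFFSETS):
            rr, cc = np.nonzero(codes == code)
            tr, tc = rr + dr, cc + dc
            ok = (tr >= 0) & (tr < nrows) & (tc >= 0) & (tc < ncols)
            src = rr[ok] * ncols + cc[ok]
            down[src] = tr[ok] * ncols + tc[ok]
            # flow pointing off-grid behaves as a sink; keep -1 for those
        return down


def neighbours(r: int, c: int, nrows: int, ncols: int):
    """Yield (code, nr, nc) for in-grid D8 neighbours in scan order."""
    for code, (dr, dc) in enumerate(D8_OFFSETS):
        nr, nc = r + dr, c + dc
        if 0 <= nr < nrows and 0 <= nc < ncols:
            yield code, nr, nc
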