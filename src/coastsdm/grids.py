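"""Core raster containers.

All grids live in WGS84 decimal degrees on a regular lat/lon lattice.
Rows are ordered north-to-south (row 0 is the northernmost row), columns
west-to-east, and cells are addressed by their centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["GridSpec", "RasterGrid"]

DEFAULT_NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular lat/lon raster.

    ``west``/``south``/``east``/``north`` are outer cell edges, so
    ``n_cols * cell_size == east - west`` (up to rounding) and likewise
    for rows.
    """

    n_rows: int
    n_cols: int
    west: float
    south: float
    cell_size: float
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid must have positive dimensions")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def east(self) -> float:
        return self.west + self.n_cols * self.cell_size

    @property
    def north(self) -> float:
        return self.south + self.n_rows * self.cell_size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def lon_centers(self) -> np.ndarray:
        return self.west + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def lat_centers(self) -> np.ndarray:
        """Latitudes of row centers, north to south (matching row order)."""
        return self.north - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def cell_index(self, lon: float, lat: float) -> tuple[int, int]:
        """(row, col) of the cell containing a point; raises if outside."""
        col = int(np.floor((lon - self.west) / self.cell_size))
        row = int(np.floor((self.north - lat) / self.cell_size))
        # points exactly on the east/north outer edge belong to the last cell
        if lon == self.east:
            col = self.n_cols - 1
        if lat == self.south + self.n_rows * self.cell_size:
            row = 0
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"point ({lon}, {lat}) outside grid")
        return row, col

    def contains(self, lon: float, lat: float) -> bool:
        return (self.west <= lon <= self.east) and (self.south <= lat <= self.north)

    def same_geometry(self, other: "GridSpec", tol: float = 1e-9) -> bool:
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and abs(self.west - other.west) <= tol
            and abs(self.south - other.south) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
        )


@dataclass
class RasterGrid:
    """A single-band raster: a :class:`GridSpec` plus a 2-D float array.

    Nodata cells carry ``spec.nodata`` in ``values`` and are excluded from
    every statistic computed downstream.
    """

    spec: GridSpec
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"values shape {self.values.shape} != spec shape {self.spec.shape}"
            )

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values) & (self.values != self.spec.nodata)

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]

    def with_values(self, values: np.ndarray) -> "RasterGrid":
        return RasterGrid(self.spec, values)

    def copy(self) -> "RasterGrid":
        return RasterGrid(self.spec, self.values.copy())

    @classmethod
    def full(cls, spec: GridSpec, fill: float) -> "RasterGrid":
        return cls(spec, np.full(spec.shape, float(fill)))

    def mask_where(self, drop: np.ndarray) -> "RasterGrid":
        """Return a copy with cells where ``drop`` is True set to nodata."""
        out = self.values.copy()
        out[np.asarray(drop, dtype=bool)] = self.spec.nodata
        return RasterGrid(self.spec, out)


def clipped_spec(spec: GridSpec, row0: int, row1: int, col0: int, col1: int) -> GridSpec:
    """Spec of the sub-grid rows[row0:row1], cols[col0:col1]."""
    return replace(
        spec,
        n_rows=row1 - row0,
        n_cols=col1 - col0,
        west=spec.west + col0 * spec.cell_size,
        south=spec.south + (spec.n_rows - row1) * spec.cell_size,
    )
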