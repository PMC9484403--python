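"""Raster and occurrence-table input/output, cleaning, clipping, masking.

Rasters are read and written as ESRI ASCII grids (the interchange format of
the pipeline) or single-band float GeoTIFFs.  Occurrences travel as CSV with
columns ``species,longitude,latitude``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

from .grids import GridSpec, RasterGrid, clipped_spec

__all__ = [
    "OccurrenceSet",
    "CleaningReport",
    "read_raster",
    "write_raster",
    "read_occurrences",
    "write_occurrences",
    "clean_occurrences",
    "clip_extent",
    "elevation_mask",
    "min_occurrence_filter",
]

log = logging.getLogger(__name__)

# Study extent: tropical/subtropical Americas.
STUDY_WEST, STUDY_EAST = -120.0, -32.0
STUDY_SOUTH, STUDY_NORTH = -36.0, 36.0

#: duplicate detection precision (decimal places of a degree, ~0.1 m)
COORD_DECIMALS = 6

_ASCII_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")

# GeoTIFF tag ids: pixel scale, tiepoint, GDAL nodata sentinel
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclass
class OccurrenceSet:
    """Cleaned presence records for one species."""

    species: str
    records: list[tuple[float, float]]  # (longitude, latitude)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def lons(self) -> np.ndarray:
        return np.array([r[0] for r in self.records], dtype=float)

    @property
    def lats(self) -> np.ndarray:
        return np.array([r[1] for r in self.records], dtype=float)


@dataclass
class CleaningReport:
    """Counts of records removed per cleaning rule."""

    n_input: int = 0
    n_retained: int = 0
    n_duplicates: int = 0
    n_zero_zero: int = 0
    n_out_of_extent: int = 0
    n_non_finite: int = 0
    n_unparseable: int = 0


class RasterFormatError(ValueError):
    """A raster file violates its declared format."""


def _format_from_path(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("ascii_grid", "geotiff"):
            raise ValueError(f"unknown raster format: {fmt!r}")
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "geotiff"
    return "ascii_grid"


def read_raster(path: str | Path, fmt: str | None = None) -> RasterGrid:
    """Read an ESRI ASCII grid or a single-band float GeoTIFF.

    The format is inferred from the file suffix unless ``fmt`` is given
    (``"ascii_grid"`` or ``"geotiff"``).
    """
    fmt = _format_from_path(path, fmt)
    if fmt == "ascii_grid":
        return _read_ascii(Path(path))
    return _read_geotiff(Path(path))


def write_raster(grid: RasterGrid, path: str | Path, fmt: str | None = None) -> None:
    """Write a raster; ASCII bodies use 6 significant digits."""
    fmt = _format_from_path(path, fmt)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    if fmt == "ascii_grid":
        _write_ascii(grid, Path(path))
    else:
        _write_geotiff(grid, Path(path))


def _read_ascii(path: Path) -> RasterGrid:
    header: dict[str, float] = {}
    body_start = 0
    with open(path) as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _ASCII_HEADER_KEYS + ("nodata_value",):
            try:
                header[parts[0].lower()] = float(parts[1])
            except ValueError as exc:
                raise RasterFormatError(
                    f"{path}: malformed header field {parts[0]!r}: {parts[1]!r}"
                ) from exc
            body_start = i + 1
        else:
            break
    for key in _ASCII_HEADER_KEYS:
        if key not in header:
            raise RasterFormatError(f"{path}: missing header field {key!r}")
    n_rows = int(header["nrows"])
    n_cols = int(header["ncols"])
    nodata = header.get("nodata_value", -9999.0)
    spec = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        west=header["xllcorner"],
        south=header["yllcorner"],
        cell_size=header["cellsize"],
        nodata=nodata,
    )
    try:
        values = np.loadtxt(lines[body_start:], ndmin=2)
    except ValueError as exc:
        raise RasterFormatError(f"{path}: unparseable body: {exc}") from exc
    if values.size != n_rows * n_cols:
        raise RasterFormatError(
            f"{path}: body has {values.size} values, header promises {n_rows * n_cols}"
        )
    return RasterGrid(spec, values.reshape(n_rows, n_cols))


def _write_ascii(grid: RasterGrid, path: Path) -> None:
    s = grid.spec
    with open(path, "w") as fh:
        fh.write(f"ncols {s.n_cols}\n")
        fh.write(f"nrows {s.n_rows}\n")
        fh.write(f"xllcorner {s.west:.10g}\n")
        fh.write(f"yllcorner {s.south:.10g}\n")
        fh.write(f"cellsize {s.cell_size:.10g}\n")
        fh.write(f"NODATA_value {s.nodata:.10g}\n")
        for row in grid.values:
            fh.write(" ".join(f"{v:.6g}" for v in row))
            fh.write("\n")


def _read_geotiff(path: Path) -> RasterGrid:
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        values = page.asarray().astype(float)
        if values.ndim != 2:
            raise RasterFormatError(f"{path}: expected a single-band raster")
        scale_tag = page.tags.get(_TAG_PIXEL_SCALE)
        tie_tag = page.tags.get(_TAG_TIEPOINT)
        if scale_tag is None or tie_tag is None:
            raise RasterFormatError(f"{path}: missing GeoTIFF georeferencing tags")
        sx, sy = scale_tag.value[0], scale_tag.value[1]
        if abs(sx - sy) > 1e-9:
            raise RasterFormatError(f"{path}: non-square cells unsupported")
        # tiepoint maps raster (0,0) corner to (west, north)
        west, north = tie_tag.value[3], tie_tag.value[4]
        nodata_tag = page.tags.get(_TAG_GDAL_NODATA)
        nodata = float(nodata_tag.value) if nodata_tag is not None else -9999.0
    n_rows, n_cols = values.shape
    spec = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        west=west,
        south=north - n_rows * sy,
        cell_size=sx,
        nodata=nodata,
    )
    return RasterGrid(spec, values)


def _write_geotiff(grid: RasterGrid, path: Path) -> None:
    s = grid.spec
    tifffile.imwrite(
        path,
        grid.values.astype(np.float64),
        extratags=[
            (_TAG_PIXEL_SCALE, "d", 3, (s.cell_size, s.cell_size, 0.0)),
            (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, s.west, s.north, 0.0)),
            (_TAG_GDAL_NODATA, "s", 0, f"{s.nodata:.10g}"),
        ],
    )


def read_occurrences(path: str | Path) -> pd.DataFrame:
    """Read a raw occurrence CSV (``species,longitude,latitude``)."""
    df = pd.read_csv(path)
    missing = {"species", "longitude", "latitude"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing occurrence columns {sorted(missing)}")
    return df


def write_occurrences(occ: OccurrenceSet, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "species": occ.species,
            "longitude": occ.lons,
            "latitude": occ.lats,
        }
    ).to_csv(path, index=False)


def clean_occurrences(
    raw: Iterable[tuple[float, float]] | pd.DataFrame,
    species: str = "",
    extent: tuple[float, float, float, float] = (
        STUDY_WEST,
        STUDY_EAST,
        STUDY_SOUTH,
        STUDY_NORTH,
    ),
) -> tuple[OccurrenceSet, CleaningReport]:
    """Drop duplicates, (0, 0) records, non-finite and out-of-extent points.

    Duplicates are exact coordinate matches after rounding to 6 decimal
    places (~0.1 m).  ``extent`` is (west, east, south, north); pass ``None``
    to skip the extent filter.  Returns the cleaned set and a per-rule count
    of removals.
    """
    if isinstance(raw, pd.DataFrame):
        if not species:
            uniq = raw["species"].unique()
            if len(uniq) == 1:
                species = str(uniq[0])
        rows: list = list(zip(raw["longitude"], raw["latitude"]))
    else:
        rows = list(raw)

    report = CleaningReport(n_input=len(rows))
    seen: set[tuple[float, float]] = set()
    kept: list[tuple[float, float]] = []
    for row in rows:
        try:
            lon, lat = float(row[0]), float(row[1])
        except (TypeError, ValueError, IndexError):
            report.n_unparseable += 1
            log.warning("dropping unparseable occurrence row: %r", row)
            continue
        if not (np.isfinite(lon) and np.isfinite(lat)):
            report.n_non_finite += 1
            continue
        if lon == 0.0 and lat == 0.0:
            report.n_zero_zero += 1
            continue
        if extent is not None:
            w, e, s, n = extent
            if not (w <= lon <= e and s <= lat <= n):
                report.n_out_of_extent += 1
                continue
        key = (round(lon, COORD_DECIMALS), round(lat, COORD_DECIMALS))
        if key in seen:
            report.n_duplicates += 1
            continue
        seen.add(key)
        kept.append((lon, lat))
    report.n_retained = len(kept)
    return OccurrenceSet(species=species, records=kept), report


def clip_extent(
    grid: RasterGrid, box: tuple[float, float, float, float]
) -> RasterGrid:
    """Clip to the cells whose centers fall inside (west, east, south, north).

    Values and cell alignment are preserved exactly; no resampling.
    """
    w, e, s, n = box
    if not (e > w and n > s):
        raise ValueError("box must satisfy east > west and north > south")
    spec = grid.spec
    lons = spec.lon_centers()
    lats = spec.lat_centers()
    cols = np.nonzero((lons >= w) & (lons <= e))[0]
    rows = np.nonzero((lats >= s) & (lats <= n))[0]
    if cols.size == 0 or rows.size == 0:
        raise ValueError("clip box does not overlap any cell center")
    r0, r1 = int(rows[0]), int(rows[-1]) + 1
    c0, c1 = int(cols[0]), int(cols[-1]) + 1
    return RasterGrid(
        clipped_spec(spec, r0, r1, c0, c1), grid.values[r0:r1, c0:c1].copy()
    )


def elevation_mask(
    grid: RasterGrid, elevation: RasterGrid, cutoff_m: float = 10.0
) -> RasterGrid:
    """Set cells with elevation strictly greater than ``cutoff_m`` to nodata.

    The coastal species modeled here do not occur on high ground, so
    training and projection are restricted to the low-elevation fringe.
    Cells where the elevation layer itself is nodata are also masked.
    """
    if not grid.spec.same_geometry(elevation.spec):
        raise ValueError("grid and elevation rasters must share a geometry")
    drop = ~elevation.valid_mask | (
        elevation.valid_mask & (elevation.values > cutoff_m)
    )
    return grid.mask_where(drop)


def min_occurrence_filter(occ: OccurrenceSet | Sequence, n_min: int = 50) -> bool:
    """Gate on cleaned sample size: at least ``n_min`` records (inclusive)."""
    return len(occ) >= n_min
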