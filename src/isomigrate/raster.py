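"""Georeferenced grid container and I/O.

A :class:`RasterGrid` holds a 2-D array of values with the simple
corner-origin / cell-center georeferencing used throughout the package:
``origin_lon, origin_lat`` is the geographic coordinate of the *outer
corner* of the cell at row 0, column 0, and cell centers sit half a cell
inward.  Rows conventionally run north to south, so ``cell_size_lat`` is
negative for grids written in the usual top-down orientation.

All coordinates are decimal degrees (WGS84 assumed); no reprojection is
supported.  Two on-disk formats are handled: single-band float64 GeoTIFF
(via :mod:`tifffile`, with ModelPixelScale / ModelTiepoint / GDAL_NODATA
tags) and ESRI ASCII grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

__all__ = [
    "RasterGrid",
    "RangeMask",
    "AlignmentError",
    "RasterFormatError",
    "read_raster",
    "write_raster",
    "apply_mask",
]

DEFAULT_NODATA = -9999.0

# GeoTIFF tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


class RasterFormatError(ValueError):
    """A raster file could not be parsed under the requested format."""


class AlignmentError(ValueError):
    """Two grids do not share shape and georeferencing."""


@dataclass
class RasterGrid:
    """A georeferenced 2-D value grid with a nodata sentinel.

    Parameters
    ----------
    values
        2-D float array, shape ``(n_rows, n_cols)``.  Invalid cells hold
        exactly ``nodata_value``.
    origin_lon, origin_lat
        Outer-corner coordinate of the cell at row 0, column 0 (degrees).
    cell_size_lon, cell_size_lat
        Degrees per cell; ``cell_size_lat`` is negative when rows run
        north to south.
    nodata_value
        Sentinel marking invalid cells.
    """

    values: np.ndarray
    origin_lon: float
    origin_lat: float
    cell_size_lon: float
    cell_size_lat: float
    nodata_value: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.cell_size_lon == 0 or self.cell_size_lat == 0:
            raise ValueError("cell sizes must be nonzero")
        if np.any(np.isnan(self.values)):
            # NaNs are accepted on input but normalised to the sentinel
            self.values = np.where(
                np.isnan(self.values), self.nodata_value, self.values
            )
        elif not np.all(np.isfinite(self.values)):
            raise ValueError("cells must be finite or the nodata sentinel")

    # -- basic properties -------------------------------------------------

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_mask(self) -> np.ndarray:
        """Boolean array, True where the cell holds a real value."""
        return self.values != self.nodata_value

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask()]

    # -- georeferencing ---------------------------------------------------

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """Geographic coordinate ``(lon, lat)`` of a cell's center."""
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"cell ({row}, {col}) outside grid {self.shape}")
        lon = self.origin_lon + (col + 0.5) * self.cell_size_lon
        lat = self.origin_lat + (row + 0.5) * self.cell_size_lat
        return lon, lat

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Grid-shaped arrays of cell-center longitudes and latitudes."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        lon = self.origin_lon + (cols + 0.5) * self.cell_size_lon
        lat = self.origin_lat + (rows + 0.5) * self.cell_size_lat
        return (
            np.broadcast_to(lon, self.shape).copy(),
            np.broadcast_to(lat[:, None], self.shape).copy(),
        )

    def index_of(self, lon: float, lat: float) -> tuple[int, int]:
        """Row/column of the cell containing a geographic point."""
        col = math.floor((lon - self.origin_lon) / self.cell_size_lon)
        row = math.floor((lat - self.origin_lat) / self.cell_size_lat)
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"point ({lon}, {lat}) outside grid extent")
        return row, col

    def same_georeference(self, other: "RasterGrid") -> bool:
        return self.shape == other.shape and np.allclose(
            [self.origin_lon, self.origin_lat,
             self.cell_size_lon, self.cell_size_lat],
            [other.origin_lon, other.origin_lat,
             other.cell_size_lon, other.cell_size_lat],
            rtol=0.0,
            atol=1e-9,
        )

    def require_aligned(self, other: "RasterGrid", what: str = "grid") -> None:
        if not self.same_georeference(other):
            raise AlignmentError(
                f"{what} is not aligned: shapes {self.shape} vs {other.shape}, "
                f"origins ({self.origin_lon}, {self.origin_lat}) vs "
                f"({other.origin_lon}, {other.origin_lat})"
            )

    # -- derived grids ----------------------------------------------------

    def with_values(self, values: np.ndarray) -> "RasterGrid":
        """New grid with the same georeferencing and different values."""
        return replace(self, values=np.asarray(values, dtype=float))

    def map_valid(self, func) -> "RasterGrid":
        """Apply ``func`` to valid cells; nodata cells propagate."""
        out = np.full(self.shape, self.nodata_value)
        ok = self.valid_mask()
        out[ok] = func(self.values[ok])
        return self.with_values(out)


@dataclass
class RangeMask:
    """A 0/1 raster delimiting the species range.

    Applied to probability surfaces so that no assignment mass falls
    outside the breeding distribution.
    """

    grid: RasterGrid
    description: str = ""

    def __post_init__(self) -> None:
        vals = self.grid.values
        ok = np.isin(vals, (0.0, 1.0)) | (vals == self.grid.nodata_value)
        if not np.all(ok):
            raise ValueError("mask values must be 0 or 1 (or nodata)")
        if not np.any(vals == 1.0):
            raise ValueError("mask selects no cells")

    def inside(self) -> np.ndarray:
        return self.grid.values == 1.0

    @property
    def n_inside(self) -> int:
        return int(self.inside().sum())


def apply_mask(surface: RasterGrid, mask: RangeMask) -> RasterGrid:
    """Set cells outside the range to nodata; inside cells are untouched."""
    surface.require_aligned(mask.grid, "range mask")
    out = np.where(mask.inside(), surface.values, surface.nodata_value)
    return surface.with_values(out)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_raster(grid: RasterGrid, path: str | Path,
                 format: str | None = None) -> None:
    """Write a grid as GeoTIFF or ESRI ASCII grid (inferred from suffix)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "ascii_grid":
        _write_ascii(grid, path)
    elif fmt == "geotiff":
        _write_geotiff(grid, path)
    else:
        raise ValueError(f"unknown raster format {fmt!r}")


def read_raster(path: str | Path, format: str | None = None) -> RasterGrid:
    """Read a GeoTIFF or ESRI ASCII grid file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "ascii_grid":
        return _read_ascii(path)
    if fmt == "geotiff":
        return _read_geotiff(path)
    raise ValueError(f"unknown raster format {fmt!r}")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".asc", ".agr", ".grd"}:
        return "ascii_grid"
    if suffix in {".tif", ".tiff"}:
        return "geotiff"
    raise ValueError(f"cannot infer raster format from suffix {suffix!r}")


def _write_ascii(grid: RasterGrid, path: Path) -> None:
    # ESRI ASCII supports only square cells; the header uses the
    # lower-left corner, data rows run north to south.
    if not math.isclose(abs(grid.cell_size_lon), abs(grid.cell_size_lat)):
        raise ValueError("ASCII grid requires square cells; use GeoTIFF")
    cell = abs(grid.cell_size_lon)
    xll = min(grid.origin_lon,
              grid.origin_lon + grid.n_cols * grid.cell_size_lon)
    yll = min(grid.origin_lat,
              grid.origin_lat + grid.n_rows * grid.cell_size_lat)
    rows = grid.values if grid.cell_size_lat < 0 else grid.values[::-1]
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {float(xll)!r}\n")
        fh.write(f"yllcorner {float(yll)!r}\n")
        fh.write(f"cellsize {float(cell)!r}\n")
        fh.write(f"NODATA_value {float(grid.nodata_value)!r}\n")
        for row in rows:
            # repr of a Python float round-trips bit-exactly
            fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")


def _read_ascii(path: Path) -> RasterGrid:
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner",
                       "xllcenter", "yllcenter", "cellsize", "nodata_value"}:
                if len(parts) != 2:
                    raise RasterFormatError(
                        f"malformed header line {line.strip()!r} in {path}"
                    )
                try:
                    header[key] = float(parts[1])
                except ValueError as exc:
                    raise RasterFormatError(
                        f"non-numeric header value for {key!r} in {path}"
                    ) from exc
            else:
                data_lines.append(line)
    for required in ("ncols", "nrows", "cellsize"):
        if required not in header:
            raise RasterFormatError(
                f"missing header field {required!r} in {path}"
            )
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    cell = header["cellsize"]
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    if "xllcorner" in header and "yllcorner" in header:
        xll, yll = header["xllcorner"], header["yllcorner"]
    elif "xllcenter" in header and "yllcenter" in header:
        xll = header["xllcenter"] - cell / 2
        yll = header["yllcenter"] - cell / 2
    else:
        raise RasterFormatError(f"missing xllcorner/xllcenter pair in {path}")
    try:
        values = np.array([float(v) for ln in data_lines for v in ln.split()])
    except ValueError as exc:
        raise RasterFormatError(f"non-numeric cell value in {path}") from exc
    if values.size != nrows * ncols:
        raise RasterFormatError(
            f"expected {nrows * ncols} cells, found {values.size} in {path}"
        )
    values = values.reshape(nrows, ncols)
    # stored top-down: origin is the upper-left corner, lat size negative
    return RasterGrid(
        values=values,
        origin_lon=xll,
        origin_lat=yll + nrows * cell,
        cell_size_lon=cell,
        cell_size_lat=-cell,
        nodata_value=nodata,
    )


def _write_geotiff(grid: RasterGrid, path: Path) -> None:
    import tifffile

    # ModelTiepoint maps raster (0,0) to the outer corner of cell (0,0);
    # ModelPixelScale is positive by convention, orientation top-down.
    if grid.cell_size_lat >= 0:
        values = grid.values[::-1]
        origin_lat = grid.origin_lat + grid.n_rows * grid.cell_size_lat
    else:
        values = grid.values
        origin_lat = grid.origin_lat
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3,
         (abs(grid.cell_size_lon), abs(grid.cell_size_lat), 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, grid.origin_lon, origin_lat, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, repr(grid.nodata_value)),
    ]
    tifffile.imwrite(path, values.astype(np.float64), extratags=extratags)


def _read_geotiff(path: Path) -> RasterGrid:
    import tifffile

    try:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            values = page.asarray()
            scale_tag = page.tags.get(_TAG_MODEL_PIXEL_SCALE)
            tie_tag = page.tags.get(_TAG_MODEL_TIEPOINT)
            nodata_tag = page.tags.get(_TAG_GDAL_NODATA)
            scale = scale_tag.value if scale_tag is not None else None
            tie = tie_tag.value if tie_tag is not None else None
            nodata_str = nodata_tag.value if nodata_tag is not None else None
    except tifffile.TiffFileError as exc:
        raise RasterFormatError(f"not a TIFF file: {path}") from exc
    if values.ndim != 2:
        raise RasterFormatError(f"expected single-band raster in {path}")
    if scale is None or tie is None:
        missing = "ModelPixelScale" if scale is None else "ModelTiepoint"
        raise RasterFormatError(f"missing GeoTIFF tag {missing} in {path}")
    sx, sy = scale[0], scale[1]
    if tie[0] != 0 or tie[1] != 0:
        raise RasterFormatError(f"unsupported non-corner tiepoint in {path}")
    nodata = float(nodata_str) if nodata_str is not None else DEFAULT_NODATA
    return RasterGrid(
        values=np.asarray(values, dtype=float),
        origin_lon=float(tie[3]),
        origin_lat=float(tie[4]),
        cell_size_lon=float(sx),
        cell_size_lat=-float(sy),
        nodata_value=nodata,
    )
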