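"""Rectangular elevation grids and ESRI ASCII grid I/O.

The grid convention used throughout the package: row 0 is the northernmost
row, indices are 0-based, and the center of cell (row, col) sits at
``origin + ((col + 0.5) * cell_size, -(row + 0.5) * cell_size)`` where
``origin`` is the outer (north-west) corner of the top-left cell.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DEMGrid", "GridParseError", "read_ascii_grid", "write_ascii_grid"]


class GridParseError(ValueError):
    """Raised when an ESRI ASCII grid file cannot be parsed."""


@dataclass
class DEMGrid:
    """A bare-earth elevation raster in meters.

    Parameters
    ----------
    elevations : 2-D float array
        Elevation in meters; entries under ``nodata_mask`` are ignored
        (stored as NaN).
    cell_size : float
        Edge length of a (square) cell in meters.
    nodata_mask : 2-D bool array, optional
        True where the cell carries no data. Defaults to all-False.
    origin : (float, float)
        (x, y) of the outer corner of the top-left cell, meters.
    """

    elevations: np.ndarray
    cell_size: float
    nodata_mask: np.ndarray | None = None
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        self.elevations = np.asarray(self.elevations, dtype=float)
        if self.elevations.ndim != 2:
            raise ValueError("elevations must be a 2-D array")
        if self.elevations.shape[0] < 2 or self.elevations.shape[1] < 2:
            raise ValueError(
                f"grid must be at least 2x2 cells, got {self.elevations.shape}"
            )
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.elevations.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.elevations.shape:
                raise ValueError("nodata_mask shape must match elevations")
        valid = ~self.nodata_mask
        if not np.all(np.isfinite(self.elevations[valid])):
            raise ValueError("non-nodata elevations must be finite")
        self.elevations = self.elevations.copy()
        self.elevations[self.nodata_mask] = np.nan
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.elevations.shape

    @property
    def n_rows(self) -> int:
        return self.elevations.shape[0]

    @property
    def n_cols(self) -> int:
        return self.elevations.shape[1]

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """Map (row, col) to the (x, y) of the cell center in meters."""
        x0, y0 = self.origin
        return (x0 + (col + 0.5) * self.cell_size,
                y0 - (row + 0.5) * self.cell_size)

    def point_to_index(self, x: float, y: float) -> tuple[int, int]:
        """Map a point in meters to the (row, col) of its enclosing cell."""
        x0, y0 = self.origin
        col = int(np.floor((x - x0) / self.cell_size))
        row = int(np.floor((y0 - y) / self.cell_size))
        return row, col

    def with_elevations(self, elevations: np.ndarray) -> "DEMGrid":
        """A copy of this grid carrying different elevation values."""
        return DEMGrid(elevations, self.cell_size,
                       nodata_mask=self.nodata_mask.copy(), origin=self.origin)


_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_ascii_grid(path) -> DEMGrid:
    """Read an ESRI ASCII grid (.asc) file into a :class:`DEMGrid`.

    The header must contain ncols, nrows, xllcorner, yllcorner and cellsize
    in the de-facto standard order; NODATA_value is optional (default -9999).
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    header: dict[str, float] = {}
    i = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _HEADER_KEYS + ("nodata_value",):
            try:
                header[parts[0].lower()] = float(parts[1])
            except ValueError:
                raise GridParseError(
                    f"{path}: line {i + 1}: non-numeric header value {parts[1]!r}")
        else:
            break
    else:
        i += 1
    for key in _HEADER_KEYS:
        if key not in header:
            raise GridParseError(f"{path}: missing header field {key!r}"
                                 " (xllcenter/yllcenter are not supported)")
    ncols = int(header["ncols"])
    nrows = int(header["nrows"])
    nodata = header.get("nodata_value", -9999.0)

    values: list[float] = []
    for j, line in enumerate(lines[i:], start=i + 1):
        for tok in line.split():
            try:
                values.append(float(tok))
            except ValueError:
                raise GridParseError(f"{path}: line {j}: non-numeric cell {tok!r}")
    if len(values) != nrows * ncols:
        raise GridParseError(
            f"{path}: expected {nrows * ncols} cells ({nrows}x{ncols}),"
            f" found {len(values)}")
    elev = np.array(values, dtype=float).reshape(nrows, ncols)
    mask = elev == nodata
    elev = elev.copy()
    elev[mask] = np.nan
    origin = (header["xllcorner"], header["yllcorner"] + nrows * header["cellsize"])
    return DEMGrid(elev, header["cellsize"], nodata_mask=mask, origin=origin)


def write_ascii_grid(grid: DEMGrid, path, nodata_value: float = -9999.0,
                     significant_digits: int = 6) -> None:
    """Write a :class:`DEMGrid` as an ESRI ASCII grid file.

    Masked cells are written as ``nodata_value``. Elevations are printed
    with ``significant_digits`` significant digits (default 6).
    """
    fmt = f"%.{significant_digits}g"
    x0, y0 = grid.origin
    yll = y0 - grid.n_rows * grid.cell_size
    vals = grid.elevations.copy()
    vals[grid.nodata_mask] = nodata_value
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {fmt % x0}\n")
        fh.write(f"yllcorner {fmt % yll}\n")
        fh.write(f"cellsize {fmt % grid.cell_size}\n")
        fh.write(f"NODATA_value {fmt % nodata_value}\n")
        for row in vals:
            fh.write(" ".join(fmt % v for v in row) + "\n")
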