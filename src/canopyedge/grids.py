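"""Planar raster grids and ESRI ASCII grid IO.

Coordinate frame used throughout the package: planar metres, origin at the
top-left corner of the grid, x increasing along columns, y increasing
downward along rows.  The centre of cell (row i, col j) is at
``(origin_x + (j + 0.5) * res, origin_y + (i + 0.5) * res)``.  Nodata is
``NaN`` in memory and a sentinel value (default -9999) on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["Raster", "coarsen_raster", "read_raster", "write_raster"]

DEFAULT_NODATA = -9999.0


@dataclass
class Raster:
    """A rectangular planar grid of real values.

    Parameters
    ----------
    values : ndarray of shape (nrows, ncols)
        Cell values; NaN marks nodata.
    resolution : float
        Cell size in metres (> 0).
    origin : (float, float)
        Planar (x, y) of the top-left corner.
    """

    values: np.ndarray
    resolution: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if not self.resolution > 0:
            raise ValueError(f"resolution must be > 0, got {self.resolution}")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) centre-coordinate arrays broadcast to the grid shape."""
        ny, nx = self.values.shape
        x = self.origin[0] + (np.arange(nx) + 0.5) * self.resolution
        y = self.origin[1] + (np.arange(ny) + 0.5) * self.resolution
        return np.broadcast_to(x, (ny, nx)), np.broadcast_to(y[:, None], (ny, nx))

    def aligned_with(self, other: "Raster", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and abs(self.resolution - other.resolution) <= atol
            and abs(self.origin[0] - other.origin[0]) <= atol
            and abs(self.origin[1] - other.origin[1]) <= atol
        )

    def copy(self) -> "Raster":
        return replace(self, values=self.values.copy())


def coarsen_raster(grid: Raster, factor: int, aggregator: str = "mean") -> Raster:
    """Aggregate ``factor`` x ``factor`` blocks of cells into one coarser cell.

    Blocks are padded with nodata when ``factor`` does not divide the grid
    dimensions; padded cells are excluded from the aggregate.  ``mean``
    ignores nodata; a coarse cell is nodata only when every contributing
    fine cell is nodata.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError(f"coarsening factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return grid.copy()
    ny, nx = grid.shape
    py = (-ny) % factor
    px = (-nx) % factor
    vals = np.pad(grid.values, ((0, py), (0, px)), constant_values=np.nan)
    blocks = vals.reshape(vals.shape[0] // factor, factor, vals.shape[1] // factor, factor)
    blocks = blocks.transpose(0, 2, 1, 3).reshape(vals.shape[0] // factor, vals.shape[1] // factor, -1)
    with np.errstate(invalid="ignore"):
        if aggregator == "mean":
            out = np.nanmean(blocks, axis=-1)
        elif aggregator == "max":
            out = np.nanmax(np.where(np.isnan(blocks), -np.inf, blocks), axis=-1)
            out[~np.isfinite(out)] = np.nan
        else:
            raise ValueError(f"unknown aggregator {aggregator!r}")
    return Raster(out, grid.resolution * factor, grid.origin)


def write_raster(grid: Raster, path, nodata: float = DEFAULT_NODATA) -> None:
    """Write an ESRI ASCII grid (.asc).

    The internal top-left origin is stored via ``yllcorner = origin_y +
    nrows * cellsize`` negated into the conventional upward geographic axis,
    i.e. geographic y = -internal y; ``read_raster`` inverts the mapping so a
    write/read round trip is the identity on values, resolution and origin.
    Values are written with 17 significant digits so the round trip is
    bit-exact for doubles.
    """
    ny, nx = grid.shape
    vals = np.where(np.isnan(grid.values), nodata, grid.values)
    header = (
        f"ncols {nx}\n"
        f"nrows {ny}\n"
        f"xllcorner {grid.origin[0]!r}\n"
        f"yllcorner {-(grid.origin[1] + ny * grid.resolution)!r}\n"
        f"cellsize {grid.resolution!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.17g")


def read_raster(path) -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_raster` (or compatible)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        ):
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"not an ESRI ASCII grid: missing {key} in {path}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    body = np.loadtxt(lines[n_header:], dtype=float, ndmin=2)
    if body.size != nrows * ncols:
        raise ValueError(
            f"truncated or malformed grid {path}: expected {nrows * ncols} values, got {body.size}"
        )
    vals = body.reshape(nrows, ncols)
    nodata = header.get("nodata_value")
    if nodata is not None:
        vals = np.where(vals == nodata, np.nan, vals)
    res = header["cellsize"]
    ox = header.get("xllcorner", 0.0)
    oy = -(header.get("yllcorner", 0.0)) - nrows * res
    return Raster(vals, res, (ox, oy))
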