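"""Topographic metrics on raster grids: TPI, TWI and distance to the forest edge.

TPI (topographic position index) is the elevation of a cell minus the mean
elevation of its surrounding neighbourhood: negative in valleys, positive on
ridges.  TWI (topographic wetness index) is ln(a / tan(beta)) with a the
specific catchment area from D8 flow routing and beta the local slope; high
values mark cells that accumulate soil moisture.  D_Edge is the Euclidean
distance from each cell centre to the nearest oil-palm cell centre.
"""

from __future__ import annotations

import heapq
import logging

import numpy as np
from scipy import ndimage

from .grids import Raster, coarsen_raster

__all__ = [
    "COVER_CLASSES",
    "compute_tpi",
    "compute_twi",
    "distance_to_edge",
    "disc_kernel",
]

log = logging.getLogger(__name__)

# Land-cover class codes shared across the package.
COVER_CLASSES = {"forest": 0, "oil_palm": 1, "clearcut": 2, "road": 3}

#: Radius of a circular 1-ha neighbourhood (pi * r^2 = 10,000 m^2).
ONE_HA_RADIUS_M = 56.41895835477563


def disc_kernel(radius_m: float, resolution_m: float, exclude_centre: bool = False) -> np.ndarray:
    """Boolean disc: cells whose centre lies within ``radius_m`` of the centre cell."""
    r_cells = radius_m / resolution_m
    n = int(np.floor(r_cells))
    ii, jj = np.mgrid[-n : n + 1, -n : n + 1]
    k = (ii**2 + jj**2) <= r_cells**2
    if exclude_centre:
        k[n, n] = False
    return k


def _neighbourhood_mean(values: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Mean of in-grid, non-nodata cells under ``kernel`` around each cell."""
    finite = np.isfinite(values)
    vals0 = np.where(finite, values, 0.0)
    kf = kernel.astype(float)
    num = ndimage.correlate(vals0, kf, mode="constant", cval=0.0)
    den = ndimage.correlate(finite.astype(float), kf, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def compute_tpi(
    dtm: Raster,
    radius_m: float = ONE_HA_RADIUS_M,
    working_res_m: float = 10.0,
    out_res_m: float = 30.0,
) -> Raster:
    """Topographic position index on the 30 m analysis grid.

    Pipeline: coarsen the DTM to 10 m by spatial averaging; per 10 m cell,
    TPI = z - mean(z over a circular 1-ha neighbourhood, centre excluded);
    smooth by taking the mean TPI within the same 1-ha neighbourhood
    (centre included); block-average to the analysis resolution.
    """
    if dtm.resolution > working_res_m + 1e-9:
        raise ValueError(
            f"DTM resolution {dtm.resolution} m is coarser than the {working_res_m} m working grid"
        )
    f = working_res_m / dtm.resolution
    if abs(f - round(f)) > 1e-9:
        raise ValueError("working resolution must be an integer multiple of the DTM resolution")
    z10 = coarsen_raster(dtm, int(round(f)), "mean")
    ny, nx = z10.shape
    if min(ny, nx) * working_res_m < 2 * radius_m:
        raise ValueError("DTM extent is smaller than one TPI neighbourhood")
    ring = disc_kernel(radius_m, working_res_m, exclude_centre=True)
    tpi10 = z10.values - _neighbourhood_mean(z10.values, ring)
    disc = disc_kernel(radius_m, working_res_m, exclude_centre=False)
    smoothed = _neighbourhood_mean(tpi10, disc)
    out_f = out_res_m / working_res_m
    if abs(out_f - round(out_f)) > 1e-9:
        raise ValueError("output resolution must be an integer multiple of the working resolution")
    return coarsen_raster(Raster(smoothed, working_res_m, z10.origin), int(round(out_f)), "mean")


# ---------------------------------------------------------------------------
# TWI: sink filling, D8 routing, flow accumulation
# ---------------------------------------------------------------------------

_D8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def fill_sinks(z: np.ndarray, epsilon: float = 1e-6) -> np.ndarray:
    """Priority-flood depression filling with a tiny gradient on flats.

    Every interior depression is raised to its spill elevation plus a small
    epsilon per step inward so that D8 routing always finds a downslope
    neighbour.
    """
    ny, nx = z.shape
    filled = np.full_like(z, np.inf)
    visited = np.zeros_like(z, dtype=bool)
    heap: list[tuple[float, int, int]] = []
    for i in range(ny):
        for j in (0, nx - 1):
            heapq.heappush(heap, (z[i, j], i, j))
            visited[i, j] = True
    for j in range(1, nx - 1):
        for i in (0, ny - 1):
            heapq.heappush(heap, (z[i, j], i, j))
            visited[i, j] = True
    while heap:
        zc, i, j = heapq.heappop(heap)
        filled[i, j] = zc
        for di, dj in _D8:
            ni, nj = i + di, j + dj
            if 0 <= ni < ny and 0 <= nj < nx and not visited[ni, nj]:
                visited[ni, nj] = True
                heapq.heappush(heap, (max(z[ni, nj], zc + epsilon), ni, nj))
    return filled


def d8_flow_accumulation(filled: np.ndarray) -> np.ndarray:
    """Number of cells draining through each cell (itself included)."""
    ny, nx = filled.shape
    recv = np.full((ny, nx, 2), -1, dtype=int)
    for i in range(ny):
        for j in range(nx):
            best = 0.0
            for di, dj in _D8:
                ni, nj = i + di, j + dj
                if 0 <= ni < ny and 0 <= nj < nx:
                    drop = (filled[i, j] - filled[ni, nj]) / np.hypot(di, dj)
                    if drop > best:
                        best = drop
                        recv[i, j] = (ni, nj)
    acc = np.ones((ny, nx))
    order = np.argsort(filled, axis=None)[::-1]  # high to low: donors before receivers
    for flat in order:
        i, j = divmod(flat, nx)
        ri, rj = recv[i, j]
        if ri >= 0:
            acc[ri, rj] += acc[i, j]
    return acc


def compute_twi(dtm: Raster, out_res_m: float = 30.0, min_tan_beta: float = 1e-4) -> Raster:
    """Topographic wetness index ln(a / tan beta) on the analysis grid.

    The DTM is coarsened to the analysis resolution first; sinks are filled;
    D8 flow accumulation gives the specific catchment area
    a = (cells x cell area) / cell width; slope comes from central
    differences with tan(beta) floored at ``min_tan_beta`` to keep flats
    finite.
    """
    f = out_res_m / dtm.resolution
    if abs(f - round(f)) > 1e-9:
        raise ValueError("analysis resolution must be an integer multiple of the DTM resolution")
    z30 = coarsen_raster(dtm, int(round(f)), "mean")
    z = z30.values
    if not np.isfinite(z).any():
        raise ValueError("DTM is entirely nodata")
    zf = np.where(np.isfinite(z), z, np.nanmax(z) + 1.0)  # nodata treated as high ground
    filled = fill_sinks(zf)
    acc = d8_flow_accumulation(filled)
    res = z30.resolution
    a = acc * res  # (cells * res^2) / res
    gy, gx = np.gradient(z, res)
    tan_beta = np.maximum(np.hypot(gx, gy), min_tan_beta)
    twi = np.log(a / tan_beta)
    twi[~np.isfinite(z)] = np.nan
    return Raster(twi, res, z30.origin)


def distance_to_edge(cover: Raster) -> Raster:
    """Euclidean distance (m) from each cell centre to the nearest oil-palm cell centre.

    Oil-palm cells themselves get 0.  If the cover contains no oil palm the
    raster is all +inf (no edge anywhere) and a warning is logged.
    """
    is_palm = cover.values == COVER_CLASSES["oil_palm"]
    if not is_palm.any():
        log.warning("cover contains no oil_palm cells; distance_to_edge is +inf everywhere")
        return Raster(np.full(cover.shape, np.inf), cover.resolution, cover.origin)
    d = ndimage.distance_transform_edt(~is_palm) * cover.resolution
    return Raster(d, cover.resolution, cover.origin)
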