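"""From labelled point samples or height rasters to the 30 m dTCH pixel table.

The chain mirrors a repeat-survey LiDAR workflow: ground returns are
triangulated into a DTM, canopy returns become a canopy height model (CHM),
the CHM is block-averaged into top-of-canopy height (TCH) pixels, the two
survey dates are differenced, and a fixed ledger of exclusions (non-forest
cover, clear-cut and road buffers, low first-survey point density, and a 1%
tail trim of dTCH) selects the analysis pixels.  Every exclusion is recorded
in an ordered audit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import QhullError

from .grids import Raster
from .terrain import COVER_CLASSES

__all__ = [
    "PIXEL_COLUMNS",
    "LedgerConfig",
    "FilterAudit",
    "grid_points_to_dtm",
    "build_chm",
    "tch_from_chm",
    "assemble_pixel_table",
    "apply_filter_ledger",
]

PIXEL_COLUMNS = [
    "x", "y", "tch_2014", "tch_2016", "delta_tch",
    "tpi", "twi", "d_edge", "density_2014", "excluded_by",
]


# ---------------------------------------------------------------------------
# Point gridding
# ---------------------------------------------------------------------------

def grid_points_to_dtm(points: pd.DataFrame, resolution_m: float = 1.0,
                       extent_m: tuple[float, float] | None = None) -> Raster:
    """Linear (TIN) interpolation of ground returns onto a regular grid.

    ``points`` needs columns x, y, z, is_ground.  Cells outside the convex
    hull of the ground points are nodata; canopy returns never influence the
    surface.
    """
    ground = points[points["is_ground"].astype(bool)]
    if len(ground) < 3:
        raise ValueError("need at least 3 ground points to triangulate a DTM")
    xy = ground[["x", "y"]].to_numpy(float)
    try:
        interp = LinearNDInterpolator(xy, ground["z"].to_numpy(float))
    except QhullError as exc:
        raise ValueError("ground points are collinear; cannot triangulate") from exc
    if extent_m is None:
        extent_m = (float(points["x"].max()), float(points["y"].max()))
    nx = max(int(np.ceil(extent_m[0] / resolution_m)), 1)
    ny = max(int(np.ceil(extent_m[1] / resolution_m)), 1)
    gx = (np.arange(nx) + 0.5) * resolution_m
    gy = (np.arange(ny) + 0.5) * resolution_m
    vals = interp(*np.meshgrid(gx, gy))
    return Raster(vals, resolution_m)


def build_chm(points: pd.DataFrame, dtm: Raster, resolution_m: float = 2.0) -> Raster:
    """Canopy height model: per-cell max of (z - ground) over non-ground returns.

    Heights below ground are clamped to 0; cells without canopy returns are
    nodata.  The CHM grid shares the DTM origin.
    """
    canopy = points[~points["is_ground"].astype(bool)]
    ny = int(np.ceil(dtm.shape[0] * dtm.resolution / resolution_m))
    nx = int(np.ceil(dtm.shape[1] * dtm.resolution / resolution_m))
    chm = np.full((ny, nx), -np.inf)
    if len(canopy):
        px = canopy["x"].to_numpy(float) - dtm.origin[0]
        py = canopy["y"].to_numpy(float) - dtm.origin[1]
        gi = np.clip((py / dtm.resolution).astype(int), 0, dtm.shape[0] - 1)
        gj = np.clip((px / dtm.resolution).astype(int), 0, dtm.shape[1] - 1)
        ground = dtm.values[gi, gj]
        ok = np.isfinite(ground)
        h = np.clip(canopy["z"].to_numpy(float)[ok] - ground[ok], 0.0, None)
        ci = np.clip((py[ok] / resolution_m).astype(int), 0, ny - 1)
        cj = np.clip((px[ok] / resolution_m).astype(int), 0, nx - 1)
        np.maximum.at(chm, (ci, cj), h)
    chm[~np.isfinite(chm)] = np.nan
    return Raster(chm, resolution_m, dtm.origin)


def tch_from_chm(chm: Raster, out_res_m: float = 30.0, min_valid_fraction: float = 0.5) -> Raster:
    """Top-of-canopy height: block mean of CHM cells within each analysis pixel.

    A pixel is valid only when at least ``min_valid_fraction`` of its
    sub-cells carry data.
    """
    f = out_res_m / chm.resolution
    if abs(f - round(f)) > 1e-9:
        raise ValueError(
            f"analysis resolution {out_res_m} is not a multiple of the CHM resolution {chm.resolution}"
        )
    f = int(round(f))
    ny, nx = chm.shape
    py, px = (-ny) % f, (-nx) % f
    vals = np.pad(chm.values, ((0, py), (0, px)), constant_values=np.nan)
    blocks = vals.reshape(vals.shape[0] // f, f, vals.shape[1] // f, f).transpose(0, 2, 1, 3)
    blocks = blocks.reshape(blocks.shape[0], blocks.shape[1], -1)
    valid = np.isfinite(blocks)
    frac = valid.sum(axis=-1) / (f * f)
    with np.errstate(invalid="ignore"):
        out = np.nanmean(blocks, axis=-1)
    out[frac < min_valid_fraction] = np.nan
    return Raster(out, out_res_m, chm.origin)


# ---------------------------------------------------------------------------
# Pixel table
# ---------------------------------------------------------------------------

def assemble_pixel_table(
    tch_2014: Raster,
    tch_2016: Raster,
    tpi: Raster,
    twi: Raster,
    d_edge: Raster,
    density: Raster,
    cover: Raster,
) -> pd.DataFrame:
    """One row per 30 m cell with dTCH = TCH_2016 - TCH_2014 and empty flags."""
    for name, r in (
        ("tch_2016", tch_2016), ("tpi", tpi), ("twi", twi),
        ("d_edge", d_edge), ("density", density), ("cover", cover),
    ):
        if not tch_2014.aligned_with(r):
            raise ValueError(f"raster {name} is not aligned with tch_2014 (origin/resolution/shape)")
    x, y = tch_2014.cell_centres()
    table = pd.DataFrame(
        {
            "x": x.ravel(),
            "y": y.ravel(),
            "tch_2014": tch_2014.values.ravel(),
            "tch_2016": tch_2016.values.ravel(),
            "tpi": tpi.values.ravel(),
            "twi": twi.values.ravel(),
            "d_edge": d_edge.values.ravel(),
            "density_2014": density.values.ravel(),
            "cover": cover.values.ravel().astype(int),
        }
    )
    table["delta_tch"] = table["tch_2016"] - table["tch_2014"]
    table["excluded_by"] = ""
    return table[PIXEL_COLUMNS + ["cover"]]


# ---------------------------------------------------------------------------
# Filter ledger
# ---------------------------------------------------------------------------

@dataclass
class LedgerConfig:
    """Toggles and thresholds for the pixel exclusion ledger."""

    exclude_nonforest: bool = True
    clearcut_buffer_m: float = 200.0
    road_buffer_m: float = 30.0
    min_density_pts_m2: float = 10.0
    trim_fraction: float = 0.01
    apply_clearcut_buffer: bool = True
    apply_road_buffer: bool = True
    apply_density_filter: bool = True
    apply_trim: bool = True


@dataclass
class FilterAudit:
    """Ordered record of (rule, rows newly removed, rows remaining)."""

    steps: list[tuple[str, int, int]] = field(default_factory=list)

    def add(self, rule: str, removed: int, remaining: int) -> None:
        if self.steps and remaining > self.steps[-1][2]:
            raise ValueError("remaining counts must be non-increasing")
        self.steps.append((rule, int(removed), int(remaining)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["rule", "rows_removed", "rows_remaining"])

    @property
    def final_remaining(self) -> int:
        return self.steps[-1][2] if self.steps else 0


def _buffer_mask(cover: Raster, klass: str, buffer_m: float) -> np.ndarray:
    """Cells within ``buffer_m`` (Euclidean, centre-to-centre) of any cell of ``klass``."""
    src = cover.values == COVER_CLASSES[klass]
    if not src.any():
        return np.zeros(cover.shape, dtype=bool)
    d = ndimage.distance_transform_edt(~src) * cover.resolution
    return d <= buffer_m


def apply_filter_ledger(
    table: pd.DataFrame, cover: Raster, cfg: LedgerConfig | None = None
) -> tuple[pd.DataFrame, FilterAudit]:
    """Apply the pixel exclusion ledger in its fixed order.

    Order: (0) rows with missing data, (1) non-forest cover (oil palm /
    clear-cut), (2) a 200 m buffer around clear-cut cells, (3) road cells
    plus a 30 m buffer, (4) first-survey point density below 10 pts/m2,
    (5) trim of the lower and upper 1% of dTCH among the rows surviving
    (0)-(4), by nearest rank (ceil(f*n) rows per tail, ties broken by row
    order).  Flags are recomputed from scratch on every call, so the ledger
    is idempotent: re-applying it flags the same rows and the audit records
    zero new removals.  The returned table keeps all rows; analysis rows are
    those with an empty ``excluded_by``.
    """
    if cfg is None:
        cfg = LedgerConfig()
    if len(table) == 0:
        raise ValueError("cannot apply filter ledger to an empty table")
    out = table.copy()
    previously_ok = (out["excluded_by"].fillna("") == "").to_numpy()
    audit = FilterAudit()
    nrows = len(out)
    flag_masks: dict[str, np.ndarray] = {}
    any_flag = np.zeros(nrows, dtype=bool)

    cov = out["cover"].to_numpy(int) if "cover" in out else np.full(nrows, COVER_CLASSES["forest"])

    def record(rule: str, hit: np.ndarray, flag: str) -> None:
        nonlocal any_flag
        hit = np.asarray(hit, dtype=bool)
        flag_masks[flag] = flag_masks.get(flag, np.zeros(nrows, dtype=bool)) | hit
        newly = hit & ~any_flag & previously_ok
        any_flag = any_flag | hit
        audit.add(rule, int(newly.sum()), int(nrows - any_flag.sum()))

    required = ["tch_2014", "tch_2016", "delta_tch", "tpi", "d_edge", "density_2014"]
    record("nodata", ~np.isfinite(out[required].to_numpy(float)).all(axis=1), "nodata")

    if cfg.exclude_nonforest:
        record("oil_palm", cov == COVER_CLASSES["oil_palm"], "oil_palm")
        record("clearcut", cov == COVER_CLASSES["clearcut"], "clearcut")

    # buffers need the raster geometry: map rows back to cells by centre coords
    gi = ((out["y"].to_numpy(float) - cover.origin[1]) / cover.resolution - 0.5).round().astype(int)
    gj = ((out["x"].to_numpy(float) - cover.origin[0]) / cover.resolution - 0.5).round().astype(int)
    inside = (gi >= 0) & (gi < cover.shape[0]) & (gj >= 0) & (gj < cover.shape[1])
    if not inside.all():
        raise ValueError("pixel table coordinates fall outside the cover raster")

    if cfg.apply_clearcut_buffer:
        m = _buffer_mask(cover, "clearcut", cfg.clearcut_buffer_m)
        record("clearcut_buffer", m[gi, gj], "clearcut_buffer")
    if cfg.apply_road_buffer:
        m = _buffer_mask(cover, "road", cfg.road_buffer_m)
        record("road_buffer", m[gi, gj], "road_buffer")
    if cfg.apply_density_filter:
        dens = out["density_2014"].to_numpy(float)
        record("low_density", np.isfinite(dens) & (dens < cfg.min_density_pts_m2), "low_density")

    if cfg.apply_trim and cfg.trim_fraction > 0:
        survivors = np.flatnonzero(~any_flag)
        n_surv = survivors.size
        r = int(np.ceil(cfg.trim_fraction * n_surv))
        hit = np.zeros(nrows, dtype=bool)
        if r > 0 and n_surv > 2 * r:
            order = survivors[np.argsort(out["delta_tch"].to_numpy(float)[survivors], kind="stable")]
            hit[order[:r]] = True
            hit[order[-r:]] = True
        record("trimmed", hit, "trimmed")

    labels = np.full(nrows, "", dtype=object)
    for flag in sorted(flag_masks):
        m = flag_masks[flag]
        labels[m] = np.where(labels[m] == "", flag, labels[m] + "|" + flag)
    out["excluded_by"] = labels
    return out, audit
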