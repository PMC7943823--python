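"""Seeded synthetic landscapes with the statistical structure the analysis assumes.

The generator emulates a fragmented logged-forest mosaic surveyed twice by
airborne LiDAR across a drought event: an undulating terrain whose lowlands
have been converted to oil palm, a logging-intensity gradient in initial
canopy height (TCH_2014, 0-64 m), and a canopy-height change (dTCH) field
whose deterministic part follows the asymptotic edge-effect model

    dTCH = b0 + b_tpi * TPI + b_tch * TCH_2014 - b * exp(-c * D_Edge)

plus Gaussian noise with an exponential spatial correlogram, split between a
nugget and a spatially structured component.  It also produces survey point
density with a height bias below 10 pts/m2, repeated field-plot censuses
with DBH/height/crown-area allometry, growth and mortality, and a daily
temperature / relative-humidity / precipitation series with an ENSO anomaly
window.  Everything is a deterministic function of the scene seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import Raster, coarsen_raster
from . import terrain as _terrain
from .terrain import COVER_CLASSES

__all__ = [
    "SceneConfig",
    "TerrainConfig",
    "CoverConfig",
    "CanopyConfig",
    "GeneratingModel",
    "NoiseConfig",
    "DensityConfig",
    "PlotsConfig",
    "ClimateConfig",
    "LandscapeScene",
    "gaussian_random_field",
    "generate_terrain",
    "generate_land_cover",
    "generate_canopy_pair",
    "generate_point_density",
    "generate_plot_inventory",
    "generate_microclimate",
    "generate_scene",
    "simulate_plot_dynamics_table",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class TerrainConfig:
    """Smoothed Gaussian random field over a regional cross-extent ramp."""

    base_elev_m: float = 300.0
    relief_amplitude_m: float = 100.0     # sd of the random field component
    correlation_length_m: float = 150.0   # Gaussian kernel length scale
    trend_fraction: float = 10.0          # ramp amplitude as multiple of relief


@dataclass
class CoverConfig:
    oil_palm_elev_quantile: float = 0.40  # lowlands converted to plantation
    n_clearcut_patches: int = 3
    clearcut_patch_radius_m: float = 150.0
    road_spacing_m: float = 1500.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.oil_palm_elev_quantile <= 1.0:
            raise ValueError("oil_palm_elev_quantile must lie in [0, 1]")
        if self.n_clearcut_patches < 0:
            raise ValueError("n_clearcut_patches must be >= 0")


@dataclass
class CanopyConfig:
    tch_min_m: float = 0.0
    tch_max_m: float = 64.0
    logging_gradient_length_m: float = 600.0

    def __post_init__(self) -> None:
        if not self.tch_min_m < self.tch_max_m:
            raise ValueError("tch_min_m must be < tch_max_m")


@dataclass
class GeneratingModel:
    """Coefficients of the asymptotic edge-effect model used as generating truth."""

    beta0: float = 0.6576
    beta_tpi: float = -0.02142
    beta_tch: float = -0.0172
    edge_amp: float = 0.8553
    edge_rate: float = 0.0049

    def deterministic(self, tpi, tch_2014, d_edge):
        tpi = np.asarray(tpi, dtype=float)
        return (
            self.beta0
            + self.beta_tpi * tpi
            + self.beta_tch * np.asarray(tch_2014, dtype=float)
            - self.edge_amp * np.exp(-self.edge_rate * np.asarray(d_edge, dtype=float))
        )


@dataclass
class NoiseConfig:
    sd_m: float = 0.9
    spatial_range_m: float = 90.0
    nugget_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.sd_m < 0:
            raise ValueError("noise sd must be >= 0")
        if not 0.0 <= self.nugget_fraction <= 1.0:
            raise ValueError("nugget_fraction must lie in [0, 1]")


@dataclass
class DensityConfig:
    """Lognormal first-survey point density with a linear height bias below threshold."""

    mean_pts_m2: float = 13.2
    sigma_log: float = 1.1
    correlation_length_m: float = 400.0
    bias_slope_m_per_pt: float = 0.2
    bias_threshold_pts_m2: float = 10.0

    def __post_init__(self) -> None:
        if self.mean_pts_m2 <= 0 or self.sigma_log < 0:
            raise ValueError("density parameters must be positive")

    def bias(self, density):
        """Additive TCH bias (m), <= 0, zero at and above the threshold."""
        d = np.asarray(density, dtype=float)
        return -self.bias_slope_m_per_pt * np.clip(self.bias_threshold_pts_m2 - d, 0.0, None)


@dataclass
class PlotsConfig:
    n_plots: int = 38
    plot_area_m2: float = 625.0
    stems_per_plot_mean: float = 40.0
    mortality_rate_per_yr: float = 0.02
    dbh_growth_mean_cm_yr: float = 0.35
    dbh_growth_sd_cm_yr: float = 0.25
    recruits_per_plot_per_census: float = 2.0
    # lognormal allometry ln H = a_h + b_h ln DBH + N(0, sd), same for crown area
    allom_a_h: float = 1.0986
    allom_b_h: float = 0.6
    allom_sd_h: float = 0.2
    allom_a_ca: float = -0.6931
    allom_b_ca: float = 1.2
    allom_sd_ca: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 <= self.mortality_rate_per_yr <= 1.0:
            raise ValueError("mortality_rate_per_yr must lie in [0, 1]")
        if self.n_plots < 1:
            raise ValueError("n_plots must be >= 1")


@dataclass
class ClimateConfig:
    """Aseasonal daily climate with an additive anomaly inside the event window."""

    start: str = "2013-06-01"
    end: str = "2018-10-31"
    baseline_t_c: float = 24.0
    baseline_rh_pct: float = 95.0
    t_noise_sd: float = 0.25
    rh_noise_sd: float = 1.5
    anomaly_t_c: float = 2.1
    anomaly_rh_pct: float = -5.6  # with +2.1 degC this doubles-and-a-bit VPD (~+140%)
    event_window: tuple[str, str] = ("2015-01-01", "2016-04-30")
    precip_mean_mm_day: float = 7.7
    precip_anomaly_factor: float = 0.72   # 169/235 mm per month during the event
    precip_wet_day_prob: float = 0.6


@dataclass
class SceneConfig:
    """Full parameterization of a synthetic scene, reproducible from the seed."""

    seed: int = 1
    extent_m: tuple[float, float] = (16000.0, 16000.0)
    base_resolution_m: float = 10.0
    analysis_resolution_m: float = 30.0
    terrain: TerrainConfig = field(default_factory=TerrainConfig)
    cover: CoverConfig = field(default_factory=CoverConfig)
    canopy: CanopyConfig = field(default_factory=CanopyConfig)
    generating_model: GeneratingModel = field(default_factory=GeneratingModel)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    density: DensityConfig = field(default_factory=DensityConfig)
    plots: PlotsConfig = field(default_factory=PlotsConfig)
    climate: ClimateConfig = field(default_factory=ClimateConfig)

    def __post_init__(self) -> None:
        if self.extent_m[0] <= 0 or self.extent_m[1] <= 0:
            raise ValueError("extent must be positive")
        if self.base_resolution_m <= 0:
            raise ValueError("base_resolution_m must be > 0")

    # named substreams so every stage draws from independent reproducible RNGs
    _STREAMS = ("terrain", "cover", "canopy", "noise", "density", "plots", "climate")

    def rng(self, stream: str) -> np.random.Generator:
        idx = self._STREAMS.index(stream)
        child = np.random.SeedSequence(self.seed).spawn(len(self._STREAMS))[idx]
        return np.random.default_rng(child)


@dataclass
class LandscapeScene:
    """All artifacts of one synthetic scene plus the generating truth."""

    config: SceneConfig
    dtm: Raster
    cover: Raster
    tch_2014: Raster           # observed (density-biased) first-survey TCH, 30 m
    tch_2016: Raster
    density_2014: Raster
    tpi: Raster
    twi: Raster
    d_edge: Raster
    truth: dict


# ---------------------------------------------------------------------------
# Random fields
# ---------------------------------------------------------------------------

def gaussian_random_field(
    shape: tuple[int, int],
    resolution_m: float,
    correlation_length_m: float,
    rng: np.random.Generator,
    kernel: str = "gaussian",
) -> np.ndarray:
    """Unit-variance stationary Gaussian field by circulant embedding (FFT).

    ``kernel`` selects the correlation function: ``gaussian``
    exp(-(d/L)^2) for smooth terrain-like surfaces, ``exponential``
    exp(-d/L) for the residual correlogram.  Negative embedding eigenvalues
    (possible for the exponential kernel on a finite torus) are clipped to
    zero, a standard approximation that slightly smooths the smallest scales.
    """
    from scipy.fft import next_fast_len

    ny, nx = shape
    # pad by several correlation lengths; beyond that the covariance is
    # negligible and full doubling would only slow the FFTs down
    pad = int(np.ceil(10.0 * correlation_length_m / resolution_m))
    big_ny = next_fast_len(ny + min(ny, pad))
    big_nx = next_fast_len(nx + min(nx, pad))
    dy = np.minimum(np.arange(big_ny), big_ny - np.arange(big_ny)) * resolution_m
    dx = np.minimum(np.arange(big_nx), big_nx - np.arange(big_nx)) * resolution_m
    dist = np.hypot(dy[:, None], dx[None, :])
    if kernel == "gaussian":
        cov = np.exp(-((dist / correlation_length_m) ** 2))
    elif kernel == "exponential":
        cov = np.exp(-dist / correlation_length_m)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    lam = np.clip(np.fft.fft2(cov).real, 0.0, None)
    white = rng.standard_normal((big_ny, big_nx))
    fld = np.fft.ifft2(np.sqrt(lam) * np.fft.fft2(white)).real
    return fld[:ny, :nx]


def _grid_shape(cfg: SceneConfig, resolution_m: float) -> tuple[int, int]:
    return (
        int(round(cfg.extent_m[1] / resolution_m)),
        int(round(cfg.extent_m[0] / resolution_m)),
    )


# ---------------------------------------------------------------------------
# Terrain and land cover
# ---------------------------------------------------------------------------

def generate_terrain(cfg: SceneConfig) -> Raster:
    """Bare-earth elevation at the base resolution: ramp + correlated relief."""
    shape = _grid_shape(cfg, cfg.base_resolution_m)
    t = cfg.terrain
    z = np.full(shape, t.base_elev_m)
    if t.relief_amplitude_m > 0:
        fld = gaussian_random_field(
            shape, cfg.base_resolution_m, t.correlation_length_m, cfg.rng("terrain")
        )
        ramp = (np.arange(shape[1]) + 0.5) / shape[1] - 0.5
        z = z + t.relief_amplitude_m * (fld + t.trend_fraction * ramp[None, :])
    return Raster(z, cfg.base_resolution_m)


def generate_land_cover(dtm: Raster, cfg: SceneConfig) -> Raster:
    """Cover classes at the analysis resolution.

    Cells below the configured elevation quantile become oil palm (the
    lowlands of the study region were almost entirely converted); clear-cut
    discs and straight one-cell-wide roads are stamped into the remaining
    forest.
    """
    f = cfg.analysis_resolution_m / dtm.resolution
    elev = coarsen_raster(dtm, int(round(f)), "mean")
    cov = np.full(elev.shape, COVER_CLASSES["forest"], dtype=float)
    q = cfg.cover.oil_palm_elev_quantile
    if q > 0:
        thresh = np.nanquantile(elev.values, q)
        cov[elev.values < thresh] = COVER_CLASSES["oil_palm"]
    rng = cfg.rng("cover")
    ny, nx = cov.shape
    res = cfg.analysis_resolution_m
    # clear-cut discs centred on randomly chosen forest cells
    forest_idx = np.flatnonzero(cov.ravel() == COVER_CLASSES["forest"])
    r_cells = cfg.cover.clearcut_patch_radius_m / res
    ii, jj = np.mgrid[0:ny, 0:nx]
    for _ in range(cfg.cover.n_clearcut_patches):
        if forest_idx.size == 0:
            break
        ci, cj = divmod(int(rng.choice(forest_idx)), nx)
        disc = ((ii - ci) ** 2 + (jj - cj) ** 2) <= r_cells**2
        cov[disc & (cov == COVER_CLASSES["forest"])] = COVER_CLASSES["clearcut"]
    # straight vertical roads at the configured spacing, forest cells only
    if cfg.cover.road_spacing_m > 0:
        spacing_cells = cfg.cover.road_spacing_m / res
        col = spacing_cells
        while col < nx:
            j = int(round(col))
            if j < nx:
                road = cov[:, j] == COVER_CLASSES["forest"]
                cov[road, j] = COVER_CLASSES["road"]
            col += spacing_cells
    return Raster(cov, res, elev.origin)


# ---------------------------------------------------------------------------
# Canopy pair and point density
# ---------------------------------------------------------------------------

def generate_canopy_pair(
    dtm: Raster, cover: Raster, cfg: SceneConfig
) -> tuple[Raster, Raster, dict]:
    """First- and second-survey TCH rasters at 30 m plus the generating truth.

    TCH_2014 is a rank-transform of a smooth logging-intensity field onto
    [tch_min, tch_max].  dTCH is the deterministic edge-effect surface
    evaluated at the scene's own TPI and D_Edge plus nugget + spatially
    correlated Gaussian noise; TCH_2016 = TCH_2014 + dTCH.
    """
    if not (cover.values == COVER_CLASSES["oil_palm"]).any():
        raise ValueError("cover has no oil_palm cells; D_Edge for the canopy model is undefined")
    res = cfg.analysis_resolution_m
    shape = cover.shape
    rng_c = cfg.rng("canopy")
    intensity = gaussian_random_field(shape, res, cfg.canopy.logging_gradient_length_m, rng_c)
    ranks = np.argsort(np.argsort(intensity.ravel())).reshape(shape)
    u = ranks / max(ranks.size - 1, 1)
    tch14 = cfg.canopy.tch_min_m + (cfg.canopy.tch_max_m - cfg.canopy.tch_min_m) * u

    tpi = _terrain.compute_tpi(dtm, out_res_m=res)
    d_edge = _terrain.distance_to_edge(cover)
    det = cfg.generating_model.deterministic(tpi.values, tch14, d_edge.values)

    n = cfg.noise
    noise = np.zeros(shape)
    if n.sd_m > 0:
        rng_n = cfg.rng("noise")
        nug = np.sqrt(n.nugget_fraction) * rng_n.standard_normal(shape)
        spat = 0.0
        if n.nugget_fraction < 1.0:
            spat = np.sqrt(1.0 - n.nugget_fraction) * gaussian_random_field(
                shape, res, n.spatial_range_m, rng_n, kernel="exponential"
            )
        noise = n.sd_m * (nug + spat)
    delta = det + noise
    truth = {
        "delta_deterministic": Raster(det, res, cover.origin),
        "coefficients": cfg.generating_model,
        "tpi": tpi,
        "d_edge": d_edge,
        "tch_2014_unbiased": Raster(tch14, res, cover.origin),
    }
    return (
        Raster(tch14, res, cover.origin),
        Raster(tch14 + delta, res, cover.origin),
        truth,
    )


def generate_point_density(tch_2014: Raster, cfg: SceneConfig) -> tuple[Raster, Raster]:
    """First-survey point density and the density-biased TCH_2014.

    Density is lognormal around the configured mean with spatial structure
    emulating flight-line coverage; below the 10 pts/m2 threshold the
    observed TCH is biased low, linear in the density shortfall.
    """
    d = cfg.density
    rng = cfg.rng("density")
    fld = gaussian_random_field(
        tch_2014.shape, tch_2014.resolution, d.correlation_length_m, rng
    )
    mu = np.log(d.mean_pts_m2) - 0.5 * d.sigma_log**2
    density = np.exp(mu + d.sigma_log * fld)
    biased = tch_2014.values + d.bias(density)
    return (
        Raster(density, tch_2014.resolution, tch_2014.origin),
        Raster(biased, tch_2014.resolution, tch_2014.origin),
    )


# ---------------------------------------------------------------------------
# Field plots
# ---------------------------------------------------------------------------

#: Census dates of the permanent-plot network emulated by the generator.
CENSUS_DATES = ("2013-01-15", "2013-12-15", "2014-11-15", "2015-12-15", "2017-02-15")


def generate_plot_inventory(cfg: SceneConfig, census_dates=CENSUS_DATES) -> pd.DataFrame:
    """Repeated stem censuses for the permanent plots.

    Returns a long table (plot_id, census_date, tree_id, dbh_cm, height_m,
    crown_area_m2, alive).  All living stems have DBH >= 10 cm; heights and
    crown areas follow lognormal power-law allometries; trees die as
    Bernoulli trials per year and keep their last DBH with alive=False;
    recruits enter later censuses with fresh ids.
    """
    p = cfg.plots
    rng = cfg.rng("plots")
    dates = pd.to_datetime(list(census_dates))
    rows = []
    next_id = 0

    def allometry(dbh):
        h = np.exp(p.allom_a_h + p.allom_b_h * np.log(dbh) + p.allom_sd_h * rng.standard_normal(dbh.shape))
        ca = np.exp(p.allom_a_ca + p.allom_b_ca * np.log(dbh) + p.allom_sd_ca * rng.standard_normal(dbh.shape))
        return h, ca

    for plot in range(p.n_plots):
        n0 = max(1, rng.poisson(p.stems_per_plot_mean))
        dbh = 10.0 + rng.exponential(12.0, n0)
        ids = np.arange(next_id, next_id + n0)
        next_id += n0
        alive = np.ones(n0, dtype=bool)
        h, ca = allometry(dbh)
        for d0, d1 in zip(dates[:-1], dates[1:], strict=True):
            for k in range(len(ids)):
                rows.append((plot, d0, ids[k], dbh[k], h[k], ca[k], alive[k]))
            yrs = (d1 - d0).days / 365.25
            growth = rng.normal(p.dbh_growth_mean_cm_yr, p.dbh_growth_sd_cm_yr, len(ids)) * yrs
            dbh = np.where(alive, np.maximum(dbh + growth, 10.0), dbh)
            die = rng.random(len(ids)) < (1.0 - (1.0 - p.mortality_rate_per_yr) ** yrs)
            alive = alive & ~die
            h, ca = allometry(dbh)
            n_rec = rng.poisson(p.recruits_per_plot_per_census)
            if n_rec:
                rdbh = 10.0 + rng.exponential(1.5, n_rec)
                rh, rca = allometry(rdbh)
                dbh = np.concatenate([dbh, rdbh])
                h = np.concatenate([h, rh])
                ca = np.concatenate([ca, rca])
                alive = np.concatenate([alive, np.ones(n_rec, dtype=bool)])
                ids = np.concatenate([ids, np.arange(next_id, next_id + n_rec)])
                next_id += n_rec
        for k in range(len(ids)):
            rows.append((plot, dates[-1], ids[k], dbh[k], h[k], ca[k], alive[k]))
    return pd.DataFrame(
        rows, columns=["plot_id", "census_date", "tree_id", "dbh_cm", "height_m", "crown_area_m2", "alive"]
    )


# ---------------------------------------------------------------------------
# Microclimate
# ---------------------------------------------------------------------------

def generate_microclimate(cfg: SceneConfig) -> pd.DataFrame:
    """Daily climate series (date, t_c, rh_pct, precip_mm).

    Aseasonal baseline with iid daily fluctuations; inside the event window
    temperature and relative humidity receive the configured additive
    anomalies and precipitation is scaled down, emulating the hot dry ENSO
    conditions.  RH is clamped to [0, 100].
    """
    c = cfg.climate
    dates = pd.date_range(c.start, c.end, freq="D")
    if len(dates) == 0:
        raise ValueError("climate series span is empty")
    w0, w1 = pd.Timestamp(c.event_window[0]), pd.Timestamp(c.event_window[1])
    if w0 < dates[0] or w1 > dates[-1]:
        raise ValueError("event_window must lie within the series span")
    rng = cfg.rng("climate")
    n = len(dates)
    in_event = (dates >= w0) & (dates <= w1)
    t = c.baseline_t_c + c.t_noise_sd * rng.standard_normal(n) + np.where(in_event, c.anomaly_t_c, 0.0)
    rh = c.baseline_rh_pct + c.rh_noise_sd * rng.standard_normal(n) + np.where(in_event, c.anomaly_rh_pct, 0.0)
    rh = np.clip(rh, 0.0, 100.0)
    wet = rng.random(n) < c.precip_wet_day_prob
    amounts = rng.gamma(1.2, c.precip_mean_mm_day / (1.2 * c.precip_wet_day_prob), n)
    precip = np.where(wet, amounts, 0.0) * np.where(in_event, c.precip_anomaly_factor, 1.0)
    return pd.DataFrame({"date": dates, "t_c": t, "rh_pct": rh, "precip_mm": precip})


# ---------------------------------------------------------------------------
# Whole-scene assembly and plot-level calibration helper
# ---------------------------------------------------------------------------

def generate_scene(cfg: SceneConfig, with_twi: bool = True) -> LandscapeScene:
    """Generate every raster artifact of a scene (plots/climate via their own ops).

    ``with_twi=False`` skips the (comparatively slow) wetness-index raster
    and stores nodata in its place; TWI is descriptive and not a covariate
    of the canopy-change model.
    """
    dtm = generate_terrain(cfg)
    cover = generate_land_cover(dtm, cfg)
    tch14, tch16, truth = generate_canopy_pair(dtm, cover, cfg)
    density, tch14_obs = generate_point_density(tch14, cfg)
    if with_twi:
        twi = _terrain.compute_twi(dtm, out_res_m=cfg.analysis_resolution_m)
    else:
        twi = Raster(np.full(cover.shape, np.nan), cover.resolution, cover.origin)
    return LandscapeScene(
        config=cfg,
        dtm=dtm,
        cover=cover,
        tch_2014=tch14_obs,
        tch_2016=tch16,
        density_2014=density,
        tpi=truth["tpi"],
        twi=twi,
        d_edge=truth["d_edge"],
        truth=truth,
    )


def simulate_plot_dynamics_table(
    n_plots: int,
    seed: int,
    beta0: float = 0.1,
    beta_mortality: float = -2.0,
    beta_growth: float = 5.0,
    r2_target: float = 0.77,
) -> pd.DataFrame:
    """Plot-level basal-area dynamics with noise calibrated to a target R^2.

    Draws per-plot basal-area mortality and growth (m^2 per plot), builds the
    field-estimated TCH change as a linear response, and sets the residual sd
    so that the expected coefficient of determination of the generating
    linear model equals ``r2_target``.  Used to emulate the strength of the
    plot-level relationship between canopy-height change and stand dynamics.
    """
    if not 0 < r2_target < 1:
        raise ValueError("r2_target must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    ba_mort = rng.gamma(1.5, 0.05, n_plots)
    ba_growth = rng.gamma(2.0, 0.04, n_plots)
    det = beta0 + beta_mortality * ba_mort + beta_growth * ba_growth
    sd = np.std(det) * np.sqrt((1.0 - r2_target) / r2_target)
    resp = det + rng.normal(0.0, sd, n_plots)
    return pd.DataFrame(
        {
            "plot_id": np.arange(n_plots),
            "ba_mortality": ba_mort,
            "ba_growth": ba_growth,
            "delta_tch_field": resp,
        }
    )
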