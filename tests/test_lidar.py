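import numpy as np
import pandas as pd
import pytest

from canopyedge.grids import Raster
from canopyedge.lidar import (
    LedgerConfig,
    apply_filter_ledger,
    assemble_pixel_table,
    build_chm,
    grid_points_to_dtm,
    tch_from_chm,
)
from canopyedge.terrain import COVER_CLASSES


class TestPointsToDTM:
    def test_plane_is_reproduced_exactly(self, rng):
        pts = pd.DataFrame(
            {"x": rng.uniform(0, 40, 3000), "y": rng.uniform(0, 40, 3000)}
        )
        pts["z"] = 2 * pts.x + 3 * pts.y
        pts["is_ground"] = True
        dtm = grid_points_to_dtm(pts, resolution_m=1.0, extent_m=(40, 40))
        gx = np.arange(40) + 0.5
        expected = 2 * gx[None, :] + 3 * gx[:, None]
        interior = np.s_[5:35, 5:35]
        np.testing.assert_allclose(dtm.values[interior], expected[interior], atol=1e-6)

    def test_canopy_points_never_influence_dtm(self, rng):
        ground = pd.DataFrame({"x": [0, 40, 0, 40.0], "y": [0, 0, 40, 40.0],
                               "z": [1.0, 1.0, 1.0, 1.0], "is_ground": True})
        canopy = pd.DataFrame({"x": rng.uniform(0, 40, 500), "y": rng.uniform(0, 40, 500),
                               "z": 99.0, "is_ground": False})
        dtm = grid_points_to_dtm(pd.concat([ground, canopy]), 1.0, (40, 40))
        assert np.nanmax(dtm.values) <= 1.0 + 1e-9

    def test_hand_triangle_barycentric_value(self):
        pts = pd.DataFrame(
            {"x": [0.0, 10.0, 0.0], "y": [0.0, 0.0, 10.0],
             "z": [0.0, 10.0, 10.0], "is_ground": True}
        )
        dtm = grid_points_to_dtm(pts, resolution_m=1.0, extent_m=(10, 10))
        # cell centre (4.5, 4.5): z = x + y by barycentric interpolation
        assert dtm.values[4, 4] == pytest.approx(9.0, abs=1e-9)

    def test_too_few_ground_points_rejected(self):
        pts = pd.DataFrame({"x": [0, 1.0], "y": [0, 1.0], "z": [0, 1.0], "is_ground": True})
        with pytest.raises(ValueError):
            grid_points_to_dtm(pts)

    def test_collinear_ground_points_rejected(self):
        pts = pd.DataFrame({"x": [0, 1, 2.0], "y": [0, 1, 2.0], "z": [0, 0, 0.0],
                            "is_ground": True})
        with pytest.raises(ValueError, match="collinear"):
            grid_points_to_dtm(pts)


class TestCHM:
    def flat_dtm(self):
        return Raster(np.zeros((10, 10)), 1.0)

    def make_points(self, rows):
        return pd.DataFrame(rows, columns=["x", "y", "z", "is_ground"])

    def test_single_canopy_point_height(self):
        pts = self.make_points([(1.0, 1.0, 25.0, False)])
        chm = build_chm(pts, self.flat_dtm(), resolution_m=2.0)
        assert chm.values[0, 0] == 25.0

    def test_max_of_two_points_in_cell(self):
        pts = self.make_points([(0.5, 0.5, 10.0, False), (1.5, 1.5, 18.0, False)])
        chm = build_chm(pts, self.flat_dtm(), resolution_m=2.0)
        assert chm.values[0, 0] == 18.0

    def test_point_below_ground_clamped_to_zero(self):
        pts = self.make_points([(1.0, 1.0, -3.0, False)])
        chm = build_chm(pts, self.flat_dtm(), resolution_m=2.0)
        assert chm.values[0, 0] == 0.0

    def test_empty_cells_are_nodata(self):
        pts = self.make_points([(1.0, 1.0, 5.0, False)])
        chm = build_chm(pts, self.flat_dtm(), resolution_m=2.0)
        assert np.isnan(chm.values[3, 3])


class TestTCH:
    def test_constant_chm_passes_through(self):
        chm = Raster(np.full((30, 30), 17.5), 2.0)
        tch = tch_from_chm(chm, out_res_m=30.0)
        assert tch.values.shape == (2, 2)
        assert np.allclose(tch.values, 17.5)

    def test_hand_mean_of_mixed_block(self):
        vals = np.empty(225)
        vals[:112] = 10.0
        vals[112:] = 20.0
        chm = Raster(vals.reshape(15, 15), 2.0)
        tch = tch_from_chm(chm, out_res_m=30.0)
        assert tch.values[0, 0] == pytest.approx((112 * 10 + 113 * 20) / 225)

    def test_mostly_nodata_pixel_is_nodata(self, rng):
        vals = np.full((15, 15), np.nan)
        mask = rng.random((15, 15)) < 0.4  # only 40% valid < 50% rule
        vals[mask] = 12.0
        tch = tch_from_chm(Raster(vals, 2.0), out_res_m=30.0)
        assert np.isnan(tch.values[0, 0])

    def test_misaligned_resolution_rejected(self):
        with pytest.raises(ValueError):
            tch_from_chm(Raster(np.ones((10, 10)), 7.0), out_res_m=30.0)


def toy_rasters(delta=None):
    """4x4 aligned raster stack for the assembly tests."""
    shape = (4, 4)
    t14 = Raster(np.full(shape, 12.0), 30.0)
    d = delta if delta is not None else 2.5
    t16 = Raster(t14.values + d, 30.0)
    z = lambda: Raster(np.zeros(shape), 30.0)
    cover = Raster(np.full(shape, COVER_CLASSES["forest"], dtype=float), 30.0)
    density = Raster(np.full(shape, 12.0), 30.0)
    return t14, t16, z(), z(), z(), density, cover


class TestAssemble:
    def test_delta_is_exact_difference(self):
        table = assemble_pixel_table(*toy_rasters())
        assert (table["delta_tch"] == 2.5).all()
        table0 = assemble_pixel_table(*toy_rasters(delta=0.0))
        assert (table0["delta_tch"] == 0.0).all()

    def test_rows_unique_by_coordinates(self):
        table = assemble_pixel_table(*toy_rasters())
        assert not table.duplicated(["x", "y"]).any()

    def test_misaligned_origin_rejected(self):
        t14, t16, *rest = toy_rasters()
        t16 = Raster(t16.values, 30.0, (15.0, 0.0))
        with pytest.raises(ValueError, match="aligned"):
            assemble_pixel_table(t14, t16, *rest)


def build_toy_scene(rng):
    """10x10 cover scene with every exclusion class represented."""
    f, p, c, r = (COVER_CLASSES[k] for k in ("forest", "oil_palm", "clearcut", "road"))
    cov = np.full((10, 10), float(f))
    cov[0, :8] = p                      # 8 oil-palm cells
    cov[5:7, 2:4] = c                   # 4 clear-cut cells
    cov[9, 3:8] = r                     # 5 road cells
    cover = Raster(cov, 30.0)
    shape = (10, 10)
    t14 = Raster(rng.uniform(5, 40, shape), 30.0)
    t16 = Raster(t14.values + rng.normal(0.2, 0.9, shape), 30.0)
    dens = Raster(np.full(shape, 14.0), 30.0)
    dens.values[3, 5:8] = 6.0           # low-density cells away from other flags
    zero = lambda: Raster(np.zeros(shape), 30.0)
    table = assemble_pixel_table(t14, t16, zero(), zero(), zero(), dens, cover)
    return table, cover


def brute_force_survivors(table, cover, cfg):
    """Exhaustive per-cell oracle for the structural filters + trim."""
    res = cover.resolution
    cells = {}
    ny, nx = cover.shape
    for i in range(ny):
        for j in range(nx):
            cells[(i, j)] = cover.values[i, j]
    flags = {}
    for idx, row in table.iterrows():
        i = int(row.y // res)
        j = int(row.x // res)
        fl = set()
        klass = cells[(i, j)]
        if klass == COVER_CLASSES["oil_palm"]:
            fl.add("oil_palm")
        if klass == COVER_CLASSES["clearcut"]:
            fl.add("clearcut")
        for (ii, jj), kk in cells.items():
            d = res * np.hypot(ii - i, jj - j)
            if kk == COVER_CLASSES["clearcut"] and d <= cfg.clearcut_buffer_m:
                fl.add("clearcut_buffer")
            if kk == COVER_CLASSES["road"] and d <= cfg.road_buffer_m:
                fl.add("road_buffer")
        if row.density_2014 < cfg.min_density_pts_m2:
            fl.add("low_density")
        flags[idx] = fl
    surv = [i for i, fl in flags.items() if not fl]
    r = int(np.ceil(cfg.trim_fraction * len(surv)))
    if r and len(surv) > 2 * r:
        ordered = sorted(surv, key=lambda i: table.loc[i, "delta_tch"])
        for i in ordered[:r] + ordered[-r:]:
            flags[i].add("trimmed")
    return {i for i, fl in flags.items() if not fl}


class TestFilterLedger:
    def test_survivors_match_exhaustive_oracle(self, rng):
        table, cover = build_toy_scene(rng)
        cfg = LedgerConfig()
        out, audit = apply_filter_ledger(table, cover, cfg)
        ours = set(out.index[out["excluded_by"] == ""])
        oracle = brute_force_survivors(table, cover, cfg)
        assert ours == oracle
        assert audit.final_remaining == len(oracle)

    def test_trim_removes_exactly_nearest_rank_counts(self, rng):
        n = 1000
        shape = (20, 50)
        t14 = Raster(np.full(shape, 20.0), 30.0)
        t16 = Raster(t14.values + rng.normal(0, 1, shape), 30.0)
        z = lambda: Raster(np.zeros(shape), 30.0)
        cover = Raster(np.full(shape, float(COVER_CLASSES["forest"])), 30.0)
        dens = Raster(np.full(shape, 14.0), 30.0)
        table = assemble_pixel_table(t14, t16, z(), z(), z(), dens, cover)
        out, audit = apply_filter_ledger(table, cover, LedgerConfig())
        trimmed = (out["excluded_by"] == "trimmed").sum()
        assert trimmed == 20  # 10 low + 10 high of 1000 survivors
        kept = out[out["excluded_by"] == ""]["delta_tch"]
        cut = out[out["excluded_by"] == "trimmed"]["delta_tch"]
        assert (cut < kept.min()).sum() == 10
        assert (cut > kept.max()).sum() == 10

    def test_all_filters_disabled_is_identity(self, rng):
        table, cover = build_toy_scene(rng)
        cfg = LedgerConfig(
            exclude_nonforest=False, apply_clearcut_buffer=False,
            apply_road_buffer=False, apply_density_filter=False, apply_trim=False,
        )
        out, audit = apply_filter_ledger(table, cover, cfg)
        assert (out["excluded_by"] == "").all()
        assert all(removed == 0 for _, removed, _ in audit.steps)

    def test_ledger_is_idempotent(self, rng):
        table, cover = build_toy_scene(rng)
        once, _ = apply_filter_ledger(table, cover)
        twice, audit2 = apply_filter_ledger(once, cover)
        pd.testing.assert_frame_equal(once, twice)
        assert all(removed == 0 for _, removed, _ in audit2.steps)

    def test_audit_counts_non_increasing(self, rng):
        table, cover = build_toy_scene(rng)
        _, audit = apply_filter_ledger(table, cover)
        remaining = [r for _, _, r in audit.steps]
        assert remaining == sorted(remaining, reverse=True)

    def test_empty_table_rejected(self, rng):
        _, cover = build_toy_scene(rng)
        with pytest.raises(ValueError):
            apply_filter_ledger(pd.DataFrame(columns=["excluded_by"]), cover)

    def test_density_bias_inflates_apparent_change(self, small_scene):
        # low-density pixels carry a negative first-survey height bias, so
        # their apparent dTCH exceeds that of the retained pixels
        from canopyedge.pipeline import build_pixel_table

        table, _ = build_pixel_table(small_scene)
        low = table["excluded_by"].str.contains("low_density")
        kept = table["excluded_by"] == ""
        assert table.loc[low, "delta_tch"].mean() > table.loc[kept, "delta_tch"].mean()
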