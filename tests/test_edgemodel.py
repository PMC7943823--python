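import numpy as np
import pandas as pd
import pytest

from canopyedge import edgemodel as em

from conftest import make_pixel_frame

TRUTH = np.array([0.6576, -0.02142, -0.0172, 0.8553, 0.0049])
EQ_PARAMS = dict(
    beta0=0.6576, beta_tpi=-0.02142, beta_tch=-0.0172, edge_amp=0.8553, edge_rate=0.0049
)
ASYM = em.ModelSpec("asymptotic", "asymptotic")


class TestCandidates:
    def test_contains_asymptotic_form(self):
        names = [s.name for s in em.build_candidates()]
        assert "asymptotic" in names
        assert "linear" in names

    def test_contains_interaction_variant(self):
        specs = {s.name: s for s in em.build_candidates()}
        inter = specs["asymptotic_interactions"]
        assert "beta_tch_tpi" in inter.param_names
        assert "beta_tch_d" in inter.param_names

    def test_nested_parameter_counts(self):
        ks = [s.n_params for s in em.build_candidates()]
        assert ks == sorted(ks)
        assert len(set(ks)) == len(ks)


class TestFitNLS:
    def test_noiseless_exact_recovery(self, rng):
        tab = make_pixel_frame(2000, rng, noise_sd=0.0)
        fit = em.fit_nls(ASYM, tab)
        np.testing.assert_allclose(fit.theta, TRUTH, atol=1e-6)
        assert fit.sigma**2 * fit.n < 1e-8  # residual sum of squares

    def test_noisy_recovery_within_three_se(self, rng):
        tab = make_pixel_frame(5000, rng, noise_sd=0.9)
        fit = em.fit_nls(ASYM, tab)
        se = np.array([fit.se[p] for p in ASYM.param_names])
        assert np.all(np.abs(fit.theta - TRUTH) <= 3 * se)

    def test_no_edge_effect_amplitude_near_zero(self, rng):
        truth0 = (0.6576, -0.02142, -0.0172, 0.0, 0.0049)
        tab = make_pixel_frame(5000, rng, noise_sd=0.9, truth=truth0)
        fit = em.fit_nls(ASYM, tab)
        assert abs(fit.params["edge_amp"]) <= 2 * fit.se["edge_amp"] + 1e-6

    def test_interaction_spec_noiseless_recovery(self, rng):
        spec = em.ModelSpec("asymptotic_interactions", "asymptotic", with_interactions=True)
        theta = np.array([0.65, -0.02, -0.017, 0.85, 0.005, 3e-4, -2e-6])
        tab = make_pixel_frame(3000, rng, noise_sd=0.0)
        tab["delta_tch"] = spec.predict(
            theta, tab.tpi, tab.tch_2014, tab.d_edge
        )
        fit = em.fit_nls(spec, tab)
        np.testing.assert_allclose(fit.theta, theta, atol=1e-5)

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(ValueError):
            em.fit_nls(ASYM, make_pixel_frame(30, rng))


class TestAIC:
    def test_formula(self):
        assert em.aic(5, -7849.5) == 15709.0

    def test_fewer_parameters_win_at_equal_likelihood(self):
        f1 = _dummy_fit("linear", k=3, loglik=-100.0)
        f2 = _dummy_fit("asymptotic", k=5, loglik=-100.0)
        best, tab = em.select_by_aic([f1, f2])
        assert best.spec.name == "linear"
        assert list(tab["delta_aic"])[0] == 0.0

    def test_differing_row_sets_rejected(self, rng):
        a = make_pixel_frame(300, rng)
        b = make_pixel_frame(300, rng)
        fa = em.fit_nls(em.ModelSpec("linear", "linear"), a)
        fb = em.fit_nls(ASYM, b)
        with pytest.raises(ValueError, match="differing"):
            em.select_by_aic([fa, fb])

    def test_true_model_selected_on_generated_data(self, rng):
        tab = make_pixel_frame(5000, rng, noise_sd=0.9)
        fits = [em.fit_nls(s, tab) for s in em.build_candidates()]
        best, _ = em.select_by_aic(fits)
        assert best.spec.kind == "asymptotic"


def _dummy_fit(name, k, loglik):
    spec = em.ModelSpec(name, "linear")
    return em.ModelFit(
        spec=spec, params={p: 0.0 for p in spec.param_names},
        cov=np.eye(spec.n_params), sigma=1.0, loglik=loglik,
        aic=em.aic(k, loglik), n=100, row_key=42,
    )


class TestGLS:
    def test_rho_to_zero_limit_equals_nls(self, rng):
        tab = make_pixel_frame(300, rng, noise_sd=0.5)
        nls = em.fit_nls(ASYM, tab)
        gls = em.fit_gls_spatial(ASYM, tab, rho=0.5)  # << pixel spacing
        np.testing.assert_allclose(gls.theta, nls.theta, atol=1e-4)

    def test_spatial_noise_inflates_intercept_se(self, rng):
        tab = make_pixel_frame(500, rng, noise_sd=0.9, spatial_range=90.0, extent=1500.0)
        nls = em.fit_nls(ASYM, tab)
        gls = em.fit_gls_spatial(ASYM, tab)
        assert gls.se["beta0"] >= nls.se["beta0"]

    def test_rho_recovery_within_factor_two(self):
        rng = np.random.default_rng(42)
        rhos = []
        for _ in range(10):
            g = np.arange(20) * 60.0
            xx, yy = np.meshgrid(g, g)
            xy = np.column_stack([xx.ravel(), yy.ravel()])
            n = len(xy)
            from scipy.spatial.distance import pdist, squareform

            C = np.exp(-squareform(pdist(xy)) / 90.0)
            L = np.linalg.cholesky(C + 1e-10 * np.eye(n))
            tpi = rng.normal(0, 7, n)
            tch = rng.uniform(0, 64, n)
            d = rng.uniform(0, 2000, n)
            y = ASYM.predict(TRUTH, tpi, tch, d) + 0.9 * (L @ rng.standard_normal(n))
            tab = pd.DataFrame(
                {"delta_tch": y, "tpi": tpi, "tch_2014": tch, "d_edge": d,
                 "x": xy[:, 0], "y": xy[:, 1]}
            )
            rhos.append(em.fit_gls_spatial(ASYM, tab).rho_m)
        med = np.median(rhos)
        assert 45.0 <= med <= 180.0

    def test_size_cap_enforced(self, rng):
        tab = make_pixel_frame(700, rng)
        with pytest.raises(ValueError, match="dense"):
            em.fit_gls_spatial(ASYM, tab, max_n=500)


class TestSubsetEnsemble:
    def test_same_seed_reproduces_ensemble(self, rng):
        tab = make_pixel_frame(3000, rng, noise_sd=0.9)
        a = em.subset_ensemble(tab, sizes=(500,), reps=5, seed=9)
        b = em.subset_ensemble(tab, sizes=(500,), reps=5, seed=9)
        np.testing.assert_array_equal(a[0].estimates, b[0].estimates)

    def test_cv_shrinks_with_subset_size(self, rng):
        tab = make_pixel_frame(6000, rng, noise_sd=0.9)
        res = em.subset_ensemble(tab, sizes=(500, 2500), reps=12, seed=3)
        assert np.all(res[1].cv_pct <= res[0].cv_pct)

    def test_median_close_to_full_table_fit(self, rng):
        tab = make_pixel_frame(8000, rng, noise_sd=0.9)
        res = em.subset_ensemble(tab, sizes=(2000,), reps=12, seed=3)[0]
        full = em.fit_nls(ASYM, tab)
        se = np.array([full.se[p] for p in ASYM.param_names])
        assert np.all(np.abs(res.median - full.theta) <= 2 * np.maximum(se, res.sd))

    def test_oversized_subset_rejected(self, rng):
        tab = make_pixel_frame(400, rng)
        with pytest.raises(ValueError):
            em.subset_ensemble(tab, sizes=(400,), reps=2)


class TestCorrectedIntervals:
    def fit(self, rng):
        return em.fit_nls(ASYM, make_pixel_frame(2000, rng, noise_sd=0.9))

    def test_full_sample_leaves_intervals_unchanged(self, rng):
        fit = self.fit(rng)
        tab = em.corrected_intervals(fit, n=1000, N=1000)
        assert np.all(tab["scale_factor"] == 1.0)

    def test_study_scale_factor(self, rng):
        tab = em.corrected_intervals(self.fit(rng), n=5000, N=36655)
        assert tab["scale_factor"].iloc[0] == pytest.approx(0.3694, abs=1e-4)

    def test_half_widths_shrink_exactly_as_sqrt_ratio(self, rng):
        fit = self.fit(rng)
        full = em.corrected_intervals(fit, n=36655, N=36655)
        sub = em.corrected_intervals(fit, n=5000, N=36655)
        ratio = (sub["hi"] - sub["lo"]) / (full["hi"] - full["lo"])
        np.testing.assert_allclose(ratio, np.sqrt(5000 / 36655), atol=1e-12)

    def test_invalid_sizes_rejected(self, rng):
        with pytest.raises(ValueError):
            em.corrected_intervals(self.fit(rng), n=10, N=5)


class TestPredictions:
    def test_interior_prediction_is_intercept(self):
        assert em.predict_delta_tch(EQ_PARAMS, 0.0, 0.0, np.array([1e9]))[0] == pytest.approx(0.6576)

    def test_edge_prediction_hand_value(self):
        val = em.predict_delta_tch(EQ_PARAMS, 0.0, 0.0, np.array([0.0]))[0]
        assert val == pytest.approx(-0.1977, abs=1e-4)

    def test_monotone_increasing_in_distance(self):
        d = np.linspace(0, 3000, 200)
        pred = em.predict_delta_tch(EQ_PARAMS, 0.0, 20.0, d)
        assert np.all(np.diff(pred) > 0)

    def test_delta_method_band_contains_point(self, rng):
        fit = em.fit_nls(ASYM, make_pixel_frame(2000, rng, noise_sd=0.9))
        pred, lo, hi = em.predict_delta_tch(
            fit.params, 0.0, 20.0, np.array([0.0, 100.0, 1000.0]), cov=fit.cov
        )
        assert np.all(lo < pred) and np.all(pred < hi)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            em.predict_delta_tch(EQ_PARAMS, 0.0, 0.0, np.array([-5.0]))


class TestEdgePenetration:
    def test_reference_canopy_hand_values(self):
        assert em.edge_penetration_distance(EQ_PARAMS, 0.0, 0.0) == pytest.approx(53.6, abs=0.1)
        assert em.edge_penetration_distance(EQ_PARAMS, 0.0, 5.0) == pytest.approx(82.2, abs=0.1)

    def test_no_crossing_when_interior_negative(self):
        # tall canopy: interior level A < 0, growth negative everywhere
        assert em.edge_penetration_distance(EQ_PARAMS, 0.0, 60.0) is None

    def test_no_crossing_when_amplitude_too_small(self):
        p = dict(EQ_PARAMS, edge_amp=0.1)
        assert em.edge_penetration_distance(p, 0.0, 0.0) is None

    def test_non_positive_rate_rejected(self):
        p = dict(EQ_PARAMS, edge_rate=0.0)
        with pytest.raises(ValueError):
            em.edge_penetration_distance(p, 0.0, 0.0)


class TestPredictionCurves:
    def make_ensemble(self, rng):
        tab = make_pixel_frame(4000, rng, noise_sd=0.9)
        return em.subset_ensemble(tab, sizes=(1500,), reps=8, seed=4)[0]

    def test_default_sets_give_six_curves(self, rng):
        curves = em.prediction_curves(self.make_ensemble(rng), n_total=36655)
        assert curves.groupby(["tch_2014", "tpi"]).ngroups == 6

    def test_valley_curve_above_hilltop_curve(self, rng):
        curves = em.prediction_curves(self.make_ensemble(rng), n_total=36655)
        for tch in (5.0, 20.0, 35.0):
            valley = curves[(curves.tch_2014 == tch) & (curves.tpi == -8.2)]
            hill = curves[(curves.tch_2014 == tch) & (curves.tpi == 9.0)]
            assert np.all(valley["delta_tch"].to_numpy() > hill["delta_tch"].to_numpy())

    def test_each_curve_monotone_in_distance(self, rng):
        curves = em.prediction_curves(self.make_ensemble(rng), n_total=36655)
        for _, g in curves.groupby(["tch_2014", "tpi"]):
            assert np.all(np.diff(g["delta_tch"].to_numpy()) > 0)

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            em.prediction_curves(self.make_ensemble(rng), 36655, d_grid=np.array([]))
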