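"""Occurrence processing, feature expansion, maxnet-style fitting, and evaluation."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

import eoniche as eo
from eoniche.enm import (
    FeatureExpansion,
    haversine_km,
    penalty_weights,
    _fc_complexity,
)


@pytest.fixture(scope="module")
def bg_points(driver_stack):
    region = xr.ones_like(driver_stack["Var1"], dtype=bool)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return eo.sample_background(region, 4000, seed=1)


@pytest.fixture(scope="module")
def presence_points(driver_stack):
    center = float(np.quantile(driver_stack["Var1"].values, 0.85))
    truth = eo.TrueSuitability("Var1", "logistic", center=center, slope=2.0)
    occ = eo.gen_occurrences(truth, driver_stack, 220, seed=2)
    return eo.thin_occurrences(occ, driver_stack)


@pytest.fixture(scope="module")
def fitted_model(driver_stack, presence_points, bg_points):
    return eo.fit_model(
        presence_points, bg_points, driver_stack,
        eo.ModelConfig(fc="lh", reg=1.0), list(driver_stack.data_vars),
    )


class TestThinning:
    def test_duplicates_collapse_to_one(self, driver_stack):
        pts = pd.DataFrame({"lon": [10.0] * 5, "lat": [-40.0] * 5})
        assert len(eo.thin_occurrences(pts, driver_stack)) == 1

    def test_distinct_cells_unchanged(self, driver_stack):
        lon = driver_stack["lon"].values
        lat = driver_stack["lat"].values
        pts = pd.DataFrame({"lon": lon[[3, 10, 20]], "lat": lat[[5, 15, 25]]})
        assert len(eo.thin_occurrences(pts, driver_stack)) == 3

    def test_pigeonhole_bound(self, driver_stack):
        rng = np.random.default_rng(3)
        # 100 points confined to a 10-cell longitude strip at one latitude
        lon = driver_stack["lon"].values[:10]
        pts = pd.DataFrame({
            "lon": rng.choice(lon, 100),
            "lat": np.full(100, float(driver_stack["lat"].values[8])),
        })
        out = eo.thin_occurrences(pts, driver_stack)
        assert len(out) <= 10

    def test_order_independent(self, driver_stack):
        rng = np.random.default_rng(4)
        pts = pd.DataFrame({
            "lon": rng.uniform(-30, 30, 50), "lat": rng.uniform(-50, 0, 50)
        })
        a = eo.thin_occurrences(pts, driver_stack)
        b = eo.thin_occurrences(pts.iloc[::-1].reset_index(drop=True), driver_stack)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_input_rejected(self, driver_stack):
        with pytest.raises(ValueError):
            eo.thin_occurrences(pd.DataFrame({"lon": [], "lat": []}), driver_stack)


class TestRegion:
    def test_buffer_includes_near_excludes_far(self, driver_stack):
        # at the equator 1 deg longitude ~ 111.19 km; 400 km in, 500 km out
        pt = pd.DataFrame({"lon": [0.0], "lat": [0.0]})
        region = eo.build_region(pt, driver_stack, "buffer_km", 450.0)
        lon = driver_stack["lon"].values
        lat = driver_stack["lat"].values
        j0 = int(np.argmin(np.abs(lat)))
        near = int(np.argmin(np.abs(lon - 400.0 / 111.19)))
        far = int(np.argmin(np.abs(lon - 500.0 / 111.19)))
        assert haversine_km(lon[near], lat[j0], 0.0, 0.0) < 450.0
        assert haversine_km(lon[far], lat[j0], 0.0, 0.0) > 450.0
        assert region.values[j0, near]
        assert not region.values[j0, far]

    def test_bounding_box(self, driver_stack):
        pts = pd.DataFrame({"lon": [0.0, 10.0], "lat": [0.0, 10.0]})
        region = eo.build_region(pts, driver_stack, "bounding_box")
        lon = driver_stack["lon"].values
        lat = driver_stack["lat"].values
        inside = region.values[
            int(np.argmin(np.abs(lat - 5.0))), int(np.argmin(np.abs(lon - 5.0)))
        ]
        outside = region.values[
            int(np.argmin(np.abs(lat - 5.0))), int(np.argmin(np.abs(lon - 20.0)))
        ]
        assert inside and not outside

    @pytest.mark.parametrize("mode", ["buffer_km", "bounding_box"])
    def test_occurrence_cells_always_inside(self, driver_stack, mode):
        rng = np.random.default_rng(5)
        pts = pd.DataFrame({
            "lon": rng.uniform(-170, 170, 20), "lat": rng.uniform(-80, 80, 20)
        })
        region = eo.build_region(pts, driver_stack, mode, 100.0 if mode == "buffer_km" else None)
        ii = np.abs(pts["lon"].to_numpy()[:, None] - driver_stack["lon"].values).argmin(1)
        jj = np.abs(pts["lat"].to_numpy()[:, None] - driver_stack["lat"].values).argmin(1)
        assert region.values[jj, ii].all()

    def test_unknown_mode_rejected(self, driver_stack):
        with pytest.raises(ValueError):
            eo.build_region(pd.DataFrame({"lon": [0.0], "lat": [0.0]}),
                            driver_stack, "voronoi")


class TestBackground:
    def test_exact_count_and_inside(self, driver_stack):
        pt = pd.DataFrame({"lon": [0.0], "lat": [0.0]})
        region = eo.build_region(pt, driver_stack, "buffer_km", 3000.0)
        bg = eo.sample_background(region, 500, seed=6)
        assert len(bg) == 500
        ii = np.abs(bg["lon"].to_numpy()[:, None] - driver_stack["lon"].values).argmin(1)
        jj = np.abs(bg["lat"].to_numpy()[:, None] - driver_stack["lat"].values).argmin(1)
        assert region.values[jj, ii].all()

    def test_seed_determinism(self, driver_stack):
        region = xr.ones_like(driver_stack["Var1"], dtype=bool)
        a = eo.sample_background(region, 200, seed=7)
        b = eo.sample_background(region, 200, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_uniformity_chi_square(self, driver_stack):
        from scipy.stats import chisquare

        # 50-cell region sampled with replacement
        mask = np.zeros(driver_stack["Var1"].shape, dtype=bool)
        mask[10, :50] = True
        region = xr.DataArray(mask, dims=("lat", "lon"),
                              coords={"lat": driver_stack["lat"],
                                      "lon": driver_stack["lon"]})
        with pytest.warns(UserWarning):
            bg = eo.sample_background(region, 5000, seed=8)
        counts = bg.groupby(["lon", "lat"]).size().to_numpy()
        counts = np.concatenate([counts, np.zeros(50 - counts.size)])
        assert chisquare(counts).pvalue > 0.01

    def test_empty_region_rejected(self, driver_stack):
        region = xr.zeros_like(driver_stack["Var1"], dtype=bool)
        with pytest.raises(ValueError):
            eo.sample_background(region, 10)


class TestScreening:
    def test_duplicate_predictor_resolved(self, driver_stack):
        ds = driver_stack.copy()
        ds["Var1_copy"] = ds["Var1"].copy()
        kept = eo.screen_predictors(ds, seed=9)
        assert ("Var1" in kept) != ("Var1_copy" in kept)

    def test_constant_predictor_dropped(self, driver_stack):
        ds = driver_stack.copy()
        ds["flat"] = xr.full_like(ds["Var1"], 3.0)
        kept = eo.screen_predictors(ds, seed=10)
        assert "flat" not in kept

    def test_independent_noise_all_retained(self, driver_stack):
        ds = driver_stack[["noise1", "noise2", "noise3"]]
        kept = eo.screen_predictors(ds, seed=11)
        assert set(kept) == {"noise1", "noise2", "noise3"}

    def test_all_constant_rejected(self, driver_stack):
        ds = xr.Dataset({"flat": xr.full_like(driver_stack["Var1"], 1.0)})
        with pytest.raises(ValueError):
            eo.screen_predictors(ds, seed=12)


class TestFeatures:
    def test_linear_only_counts(self):
        X = np.random.default_rng(0).normal(size=(100, 3))
        exp = FeatureExpansion(["a", "b", "c"], "l").fit(X)
        assert exp.transform(X).shape[1] == 3

    def test_lqp_counts(self):
        X = np.random.default_rng(0).normal(size=(100, 2))
        exp = FeatureExpansion(["a", "b"], "lqp").fit(X)
        assert exp.transform(X).shape[1] == 5  # 2 linear + 2 quadratic + 1 product

    def test_hinge_counts(self):
        X = np.random.default_rng(0).normal(size=(200, 1))
        exp = FeatureExpansion(["a"], "lh", n_knots=20).fit(X)
        assert exp.transform(X).shape[1] == 1 + 2 * 20

    def test_features_scaled_to_unit_interval(self):
        X = np.random.default_rng(0).normal(10.0, 5.0, size=(300, 2))
        exp = FeatureExpansion(["a", "b"], "lqh").fit(X)
        Z = exp.transform(X)
        assert Z.min() >= 0.0 and Z.max() <= 1.0 + 1e-12

    def test_invalid_fc_rejected(self):
        with pytest.raises(ValueError):
            FeatureExpansion(["a"], "xyz")

    def test_penalty_scales_with_class_and_sample_size(self):
        X = np.random.default_rng(0).normal(size=(100, 1))
        exp = FeatureExpansion(["a"], "lh").fit(X)
        lam = penalty_weights(exp, reg=2.0, n_presences=100)
        linear = lam[np.array(exp.feature_class) == "l"]
        hinge = lam[np.array(exp.feature_class) == "h"]
        assert (hinge > linear[0]).all()
        lam_small = penalty_weights(exp, reg=2.0, n_presences=25)
        assert lam_small[0] == pytest.approx(2.0 * lam[0])


class TestFit:
    def test_suitability_monotone_in_driver(self, fitted_model, driver_stack):
        from scipy.stats import spearmanr

        raster = eo.project(fitted_model, driver_stack)
        r = spearmanr(
            driver_stack["Var1"].values.ravel(), raster.values.ravel()
        ).statistic
        assert r > 0.9

    def test_huge_regularization_flattens_model(self, driver_stack, presence_points, bg_points):
        m = eo.fit_model(
            presence_points, bg_points, driver_stack,
            eo.ModelConfig(fc="lh", reg=1e6), list(driver_stack.data_vars),
        )
        assert np.allclose(m.coef, 0.0)
        raster = eo.project(m, driver_stack)
        assert np.nanstd(raster.values) == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_fit(self, driver_stack, presence_points, bg_points):
        cfg = eo.ModelConfig(fc="lh", reg=1.0, seed=0)
        a = eo.fit_model(presence_points, bg_points, driver_stack, cfg,
                         list(driver_stack.data_vars))
        b = eo.fit_model(presence_points, bg_points, driver_stack, cfg,
                         list(driver_stack.data_vars))
        np.testing.assert_array_equal(a.coef, b.coef)

    def test_too_few_presences_rejected(self, driver_stack, bg_points):
        pts = pd.DataFrame({"lon": [0.0] * 5, "lat": [-40.0, -30.0, -20.0, -10.0, 0.0]})
        with pytest.raises(ValueError, match="presences"):
            eo.fit_model(pts, bg_points, driver_stack,
                         eo.ModelConfig(fc="l"), list(driver_stack.data_vars))

    def test_json_roundtrip_reproduces_projection(self, fitted_model, driver_stack):
        clone = eo.NicheModel.from_json(fitted_model.to_json())
        a = eo.project(fitted_model, driver_stack)
        b = eo.project(clone, driver_stack)
        np.testing.assert_array_equal(a.values, b.values)


class TestEvaluate:
    def test_perfect_separation_gives_auc_one(self, driver_stack, fitted_model):
        # construct presences in the model's own top-scoring cells
        raster = eo.project(fitted_model, driver_stack)
        flat = raster.values.ravel()
        order = np.argsort(flat)
        top = order[-20:]
        bottom = order[:500]
        lat_i, lon_i = np.unravel_index(top, raster.shape)
        test_p = pd.DataFrame({"lon": raster["lon"].values[lon_i],
                               "lat": raster["lat"].values[lat_i]})
        lat_j, lon_j = np.unravel_index(bottom, raster.shape)
        bg = pd.DataFrame({"lon": raster["lon"].values[lon_j],
                           "lat": raster["lat"].values[lat_j]})
        ev = eo.evaluate(fitted_model, test_p, bg, driver_stack)
        assert ev.auc_test == pytest.approx(1.0)

    def test_training_omission_near_ten_percent(self, fitted_model, driver_stack,
                                                presence_points, bg_points):
        ev = eo.evaluate(fitted_model, presence_points, bg_points, driver_stack)
        n = len(presence_points)
        assert abs(ev.or_p10 - 0.10) <= 1.0 / n + 1e-12

    def test_omission_discrete_with_eleven_presences(self, fitted_model,
                                                     driver_stack, presence_points,
                                                     bg_points):
        ev = eo.evaluate(fitted_model, presence_points.iloc[:11], bg_points,
                         driver_stack)
        assert ev.n_test_presences == 11
        assert (ev.or_p10 * 11) == pytest.approx(round(ev.or_p10 * 11))

    def test_empty_presences_rejected(self, fitted_model, driver_stack, bg_points):
        with pytest.raises(ValueError):
            eo.evaluate(fitted_model, pd.DataFrame({"lon": [], "lat": []}),
                        bg_points, driver_stack)


class TestTune:
    def test_reg_grid_shape(self):
        grid = eo.default_config_grid()
        regs = sorted({c.reg for c in grid})
        assert regs == [1.0, 1.5, 2.0, 2.5, 3.0]
        assert len(grid) == 25

    def test_single_config_returned(self, driver_stack, presence_points, bg_points):
        cfg = eo.ModelConfig(fc="l", reg=1.0, k_folds=3)
        best, results = eo.tune(presence_points, bg_points, driver_stack,
                                [cfg], seed=13)
        assert best == cfg
        assert len(results) == 1

    def test_simplicity_preference_on_linear_truth(self, driver_stack,
                                                   presence_points, bg_points):
        configs = [eo.ModelConfig(fc=f, reg=1.0, k_folds=3) for f in ("l", "lqh")]
        best, results = eo.tune(presence_points, bg_points, driver_stack,
                                configs, seed=14)
        # data generated from a smooth monotone response: the simple set wins
        # unless the complex one beats it beyond a negligibility margin on
        # AUC or omission rate (the two earlier lexicographic keys)
        r = results.set_index("fc")
        complex_wins_margin = (
            r.loc["lqh", "auc"] - r.loc["l", "auc"] > 0.005
            or r.loc["l", "or_p10"] - r.loc["lqh", "or_p10"] > 0.01
        )
        assert best.fc == "l" or complex_wins_margin

    def test_complexity_order(self):
        assert (_fc_complexity("l") < _fc_complexity("lq")
                < _fc_complexity("lh") < _fc_complexity("lqh")
                < _fc_complexity("lqph"))


class TestEnsembleAndProjection:
    def test_projection_range_and_identity(self, fitted_model, driver_stack):
        a = eo.project(fitted_model, driver_stack)
        vals = a.values[np.isfinite(a.values)]
        assert (vals >= 0.0).all() and (vals <= 1.0).all()
        b = eo.project(fitted_model, driver_stack)
        np.testing.assert_array_equal(a.values, b.values)

    def test_missing_predictor_named(self, fitted_model, driver_stack):
        target = driver_stack.drop_vars("noise2")
        with pytest.raises(KeyError, match="noise2"):
            eo.project(fitted_model, target)

    def test_ensemble_mean_bounded_by_replicates(self, driver_stack,
                                                 presence_points, bg_points):
        cfg = eo.ModelConfig(fc="l", reg=1.0)
        mean_raster, mean_p10, models = eo.bootstrap_ensemble(
            presence_points, bg_points, driver_stack, cfg, reps=3, seed=15,
        )
        assert len(models) == 3
        reps = np.stack([eo.project(m, driver_stack).values for m in models])
        assert (mean_raster.values >= reps.min(axis=0) - 1e-12).all()
        assert (mean_raster.values <= reps.max(axis=0) + 1e-12).all()
        assert 0.0 <= mean_p10 <= 1.0

    def test_ensemble_variance_shrinks_with_reps(self, driver_stack,
                                                 presence_points, bg_points):
        cfg = eo.ModelConfig(fc="l", reg=1.0)

        def cell_sd(reps, seed):
            rasters = []
            for s in range(3):
                r, _, _ = eo.bootstrap_ensemble(
                    presence_points, bg_points, driver_stack, cfg,
                    reps=reps, seed=seed + s,
                )
                rasters.append(r.values)
            return np.nanmean(np.std(rasters, axis=0))

        assert cell_sd(8, 100) < cell_sd(1, 200)


class TestImportance:
    def test_single_predictor_gets_everything(self, driver_stack, presence_points,
                                              bg_points):
        m = eo.fit_model(presence_points, bg_points, driver_stack,
                         eo.ModelConfig(fc="l"), ["Var1"])
        imp = eo.permutation_importance(m, presence_points, bg_points,
                                        driver_stack, seed=16)
        assert imp["importance"].iloc[0] == pytest.approx(100.0)

    def test_zero_coefficient_predictor_zero_importance(self, fitted_model,
                                                        driver_stack,
                                                        presence_points, bg_points):
        imp = eo.permutation_importance(fitted_model, presence_points, bg_points,
                                        driver_stack, seed=17)
        coef_by_var = {}
        classes = fitted_model.expansion.feature_class
        vars_ = fitted_model.expansion.feature_var
        for j, v in enumerate(vars_):
            name = fitted_model.variables[v]
            coef_by_var[name] = coef_by_var.get(name, 0.0) + abs(fitted_model.coef[j])
        for _, row in imp.iterrows():
            if coef_by_var.get(row["variable"], 0.0) == 0.0:
                assert row["importance"] == pytest.approx(0.0)

    def test_true_driver_ranked_first(self, fitted_model, driver_stack,
                                      presence_points, bg_points):
        imp = eo.permutation_importance(fitted_model, presence_points, bg_points,
                                        driver_stack, seed=18)
        assert imp.iloc[0]["variable"] == "Var1"
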