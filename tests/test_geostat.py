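import numpy as np
import pandas as pd
import pytest

from qregions.geostat import (CoregionalizationModel, VariogramModel,
                              cokrige_grid, empirical_variogram, fit_lmc,
                              fit_variogram, krige_points, lmc_from_variogram,
                              loo_validate, spearman_screen, variogram_shape)
from qregions.raster import GridSpec, haversine_km


@pytest.fixture()
def five_sites():
    rng = np.random.default_rng(0)
    n = 5
    return pd.DataFrame({"lon": 110 + rng.uniform(0, 1, n),
                         "lat": 28 + rng.uniform(0, 1, n),
                         "z": rng.normal(2, 1, n),
                         "w": rng.normal(0, 1, n)})


class TestSpearman:
    def test_monotone_function_gives_rho_one(self):
        t = pd.DataFrame({"x": [1.0, 2, 3, 4, 5], "c": np.exp([1.0, 2, 3, 4, 5])})
        s = spearman_screen(t, ["c"], ["x"])
        assert s.table["rho"].iloc[0] == pytest.approx(1.0)

    def test_closed_form_small_case(self):
        t = pd.DataFrame({"x": [1, 2, 3, 4], "c": [2, 1, 4, 3]})
        s = spearman_screen(t, ["c"], ["x"])
        assert s.table["rho"].iloc[0] == pytest.approx(0.6)   # 1 - 6*4/(4*15)

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        c = x + rng.normal(0, 0.5, 30)
        t1 = pd.DataFrame({"x": x, "c": c})
        t2 = pd.DataFrame({"x": np.exp(x), "c": c ** 3})
        r1 = spearman_screen(t1, ["c"], ["x"]).table["rho"].iloc[0]
        r2 = spearman_screen(t2, ["c"], ["x"]).table["rho"].iloc[0]
        assert r1 == pytest.approx(r2)

    def test_constant_vector_skipped(self):
        t = pd.DataFrame({"x": [1.0, 1, 1, 1], "c": [1.0, 2, 3, 4]})
        with pytest.warns(UserWarning, match="constant"):
            s = spearman_screen(t, ["c"], ["x"])
        assert s.skipped == [("c", "x")] and len(s.table) == 0


class TestEmpiricalVariogram:
    def test_constant_field_zero_everywhere(self):
        t = pd.DataFrame({"lon": [110, 110.5, 111, 111.5],
                          "lat": [28.0] * 4, "z": [3.0] * 4})
        e = empirical_variogram(t.lon, t.lat, t.z)
        assert np.allclose(e["gamma"], 0.0)

    def test_single_pair_bin_value(self):
        # four sites; the nearest pair has values 0 and 2 -> gamma = 2
        t = pd.DataFrame({"lon": [110.0, 110.01, 113.0, 116.0],
                          "lat": [28.0] * 4, "z": [0.0, 2.0, 0.0, 0.0]})
        e = empirical_variogram(t.lon, t.lat, t.z, n_lags=30)
        first = e.iloc[0]
        assert first["n_pairs"] == 1 and first["gamma"] == pytest.approx(2.0)

    def test_white_noise_flat_at_variance(self):
        rng = np.random.default_rng(0)
        gammas = []
        for s in range(20):
            n = 60
            t = pd.DataFrame({"lon": 110 + rng.uniform(0, 2, n),
                              "lat": 28 + rng.uniform(0, 2, n),
                              "z": rng.normal(0, 2.0, n)})
            e = empirical_variogram(t.lon, t.lat, t.z, n_lags=6)
            gammas.append(e["gamma"].mean())
        assert np.mean(gammas) == pytest.approx(4.0, rel=0.1)


class TestFitVariogram:
    def test_noiseless_recovery(self):
        h = np.linspace(2, 120, 15)
        true = VariogramModel("spherical", 0.1, 0.9, 50.0)
        emp = pd.DataFrame({"h": h, "gamma": true(h),
                            "n_pairs": np.full(len(h), 30)})
        m = fit_variogram(emp, "spherical")
        assert m.nugget == pytest.approx(0.1, abs=1e-3)
        assert m.partial_sill == pytest.approx(0.9, abs=1e-3)
        assert m.range_km == pytest.approx(50.0, abs=1e-3)

    def test_family_formulas_at_range(self):
        sph = VariogramModel("spherical", 0.1, 0.9, 50.0)
        assert sph(50.0) == pytest.approx(1.0)
        exp_ = VariogramModel("exponential", 0.1, 0.9, 50.0)
        assert exp_(50.0) == pytest.approx(0.1 + 0.9 * (1 - np.exp(-3)))
        gau = VariogramModel("gaussian", 0.0, 1.0, 50.0)
        assert gau(50.0) == pytest.approx(1 - np.exp(-3))
        assert sph(0.0) == 0.0

    def test_degenerate_all_zero_returns_nugget_only(self):
        emp = pd.DataFrame({"h": [10.0, 20, 30], "gamma": [0.0, 0, 0],
                            "n_pairs": [5, 5, 5]})
        with pytest.warns(UserWarning, match="degenerate"):
            m = fit_variogram(emp)
        assert m.partial_sill == 0.0 and m.nugget == 0.0


class TestLMC:
    def test_duplicated_secondary_gives_equal_blocks(self, five_sites):
        rng = np.random.default_rng(3)
        n = 24
        t = pd.DataFrame({"lon": 110 + rng.uniform(0, 2, n),
                          "lat": 28 + rng.uniform(0, 2, n),
                          "z": rng.normal(0, 1, n)})
        t["w"] = t["z"]
        lmc = fit_lmc(t, "z", ["w"])
        assert np.allclose(lmc.b1[0, 0], lmc.b1[0, 1], atol=1e-8)
        assert np.allclose(lmc.b0[0, 0], lmc.b0[1, 1], atol=1e-8)

    def test_independent_fields_have_small_cross_structure(self):
        """Cross coefficients vanish (relative to the direct sill) as the
        number of sites grows, for independent primary/secondary fields."""
        from qregions.synth import gaussian_random_field
        rng = np.random.default_rng(4)
        ratios = []
        for _ in range(5):
            z = gaussian_random_field(50, 50, "exponential", 1.0, 10.0, rng)
            w = gaussian_random_field(50, 50, "exponential", 1.0, 10.0, rng)
            idx = np.unique(rng.integers(0, 2500, 80))[:60]
            rr, cc = idx // 50, idx % 50
            t = pd.DataFrame({"lon": 110 + (cc + 0.5) * 0.05,
                              "lat": 30 - (rr + 0.5) * 0.05,
                              "z": z[rr, cc], "w": w[rr, cc]})
            lmc = fit_lmc(t, "z", ["w"])
            sill = lmc.b0 + lmc.b1     # total (co)variance at the origin
            ratios.append(abs(sill[0, 1]) / sill[0, 0])
        assert np.mean(ratios) < 0.3

    def test_coefficient_matrices_are_psd(self, five_sites):
        rng = np.random.default_rng(5)
        n = 30
        t = pd.DataFrame({"lon": 110 + rng.uniform(0, 2, n),
                          "lat": 28 + rng.uniform(0, 2, n)})
        t["z"] = rng.normal(0, 1, n)
        t["w"] = 0.5 * t["z"] + rng.normal(0, 0.5, n)
        lmc = fit_lmc(t, "z", ["w"])
        assert np.linalg.eigvalsh(lmc.b0).min() >= -1e-10
        assert np.linalg.eigvalsh(lmc.b1).min() >= -1e-10


class TestKriging:
    def test_exact_interpolation_with_zero_nugget(self, five_sites):
        model = lmc_from_variogram(VariogramModel("exponential", 0.0, 1.0, 60.0),
                                   "z")
        pred, se = krige_points(model, five_sites,
                                five_sites.lon.to_numpy(),
                                five_sites.lat.to_numpy())
        assert np.max(np.abs(pred - five_sites.z.to_numpy())) < 1e-8
        assert np.max(se) < 1e-4

    def test_constant_field_predicts_constant(self, five_sites):
        t = five_sites.assign(z=2.72)
        model = lmc_from_variogram(VariogramModel("spherical", 0.3, 1.0, 40.0),
                                   "z")
        pred, _ = krige_points(model, t, [110.4, 110.9], [28.2, 28.7])
        assert np.allclose(pred, 2.72, atol=1e-10)

    def test_matches_dense_oracle_with_secondary(self, five_sites):
        """Cell solution equals a hand-assembled dense co-kriging system."""
        n = 5
        B0 = np.array([[0.05, 0.01], [0.01, 0.04]])
        B1 = np.array([[1.0, 0.5], [0.5, 0.8]])
        model = CoregionalizationModel(["z", "w"], "spherical", 80.0, B0, B1)
        x0, y0 = 110.4, 28.6
        pred, se = krige_points(model, five_sites, [x0], [y0])
        lon = five_sites.lon.to_numpy()
        lat = five_sites.lat.to_numpy()
        var_idx = np.array([0] * n + [1] * n)
        sites = np.concatenate([np.arange(n)] * 2)
        d = haversine_km(lon[sites][:, None], lat[sites][:, None],
                         lon[sites][None, :], lat[sites][None, :])
        K = np.empty((2 * n, 2 * n))
        for i in range(2 * n):
            for j in range(2 * n):
                K[i, j] = model.cross_covariance(var_idx[i], var_idx[j],
                                                 d[i, j])
        A = np.zeros((2 * n + 2, 2 * n + 2))
        A[:2 * n, :2 * n] = K
        A[2 * n, :n] = A[:n, 2 * n] = 1
        A[2 * n + 1, n:2 * n] = A[n:2 * n, 2 * n + 1] = 1
        d0 = np.asarray(haversine_km(lon, lat, x0, y0))
        rhs = np.zeros(2 * n + 2)
        rhs[:n] = model.cross_covariance(0, 0, d0)
        rhs[n:2 * n] = model.cross_covariance(1, 0, d0)
        rhs[2 * n] = 1
        sol = np.linalg.solve(A, rhs)
        z = np.concatenate([five_sites.z, five_sites.w])
        assert pred[0] == pytest.approx(sol[:2 * n] @ z, abs=1e-8)
        var_b = B0[0, 0] + B1[0, 0] - sol @ rhs
        assert se[0] == pytest.approx(np.sqrt(var_b), abs=1e-8)
        # unbiasedness constraints hold
        assert sol[:n].sum() == pytest.approx(1.0, abs=1e-10)
        assert sol[n:2 * n].sum() == pytest.approx(0.0, abs=1e-10)

    def test_grid_variant_matches_pointwise_and_nonneg_variance(self, five_sites):
        model = lmc_from_variogram(VariogramModel("spherical", 0.2, 1.0, 60.0),
                                   "z")
        spec = GridSpec(n_rows=6, n_cols=6, x_min=110.0, y_max=29.0,
                        dx=0.2, dy=0.2)
        pred, se = cokrige_grid(model, five_sites, spec)
        assert np.isfinite(pred.values).all()
        assert (se.values >= 0).all()
        lons, lats = spec.cell_centers()
        p1, s1 = krige_points(model, five_sites, [lons[2]], [lats[3]])
        assert pred.values[3, 2] == pytest.approx(p1[0], rel=1e-12)


class TestLoo:
    def test_smooth_field_low_rmse(self):
        """A noiseless smooth field interpolated with an adequate long-range
        model validates with near-zero errors."""
        rng = np.random.default_rng(0)
        n = 25
        lon = 110 + rng.uniform(0, 1, n)
        lat = 28 + rng.uniform(0, 1, n)
        z = np.sin(lon * 2) + np.cos(lat * 2)          # gently varying
        t = pd.DataFrame({"lon": lon, "lat": lat, "z": z})
        model = lmc_from_variogram(VariogramModel("gaussian", 0.0, 1.0, 300.0),
                                   "z")
        rep = loo_validate(model, t)
        assert rep.rmse < 0.05 * np.std(z)

    def test_calibrated_standardized_rmse(self):
        """With the true variogram supplied, the standardized RMSE sits near
        1 (well-calibrated kriging uncertainty)."""
        from qregions.synth import gaussian_random_field
        inband = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            fld = gaussian_random_field(60, 60, "exponential", 1.0, 12.0, rng)
            idx = np.unique(rng.integers(0, 3600, 40))[:26]
            rows, cols = idx // 60, idx % 60
            lons = 110 + (cols + 0.5) * 0.05
            lats = 30 - (rows + 0.5) * 0.05
            km = 0.05 * 111.195 * np.sqrt(np.cos(np.radians(28.5)))
            t = pd.DataFrame({"lon": lons, "lat": lats,
                              "z": fld[rows, cols]})
            model = lmc_from_variogram(
                VariogramModel("exponential", 0.0, 1.0, 12 * km), "z")
            rep = loo_validate(model, t)
            if 0.7 <= rep.standardized_rmse <= 1.3:
                inband += 1
        assert inband >= 8

    def test_mean_error_near_zero_on_symmetric_noise(self):
        rng = np.random.default_rng(7)
        mes = []
        for s in range(10):
            n = 20
            t = pd.DataFrame({"lon": 110 + rng.uniform(0, 2, n),
                              "lat": 28 + rng.uniform(0, 2, n),
                              "z": rng.normal(0, 1, n)})
            model = lmc_from_variogram(
                VariogramModel("exponential", 0.5, 0.5, 50.0), "z")
            mes.append(loo_validate(model, t).mean_error)
        assert abs(np.mean(mes)) < 0.1
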