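import numpy as np
import pandas as pd
import pytest

from qregions.occurrences import DesignTable
from qregions.maxent import (auc_presence_background, build_features,
                             evaluate_cv, evaluate_split, fit, predict,
                             project_to_raster, response_curve,
                             variable_importance)


def _design(labels, **cols):
    tab = pd.DataFrame(cols)
    tab.insert(0, "label", labels)
    tab.insert(1, "lon", 0.0)
    tab.insert(2, "lat", 0.0)
    return DesignTable(tab, [c for c in cols], background_n=int((np.asarray(labels) == 0).sum()))


@pytest.fixture(scope="module")
def toy():
    return _design([1, 1, 0, 0, 0], x=[0.9, 0.7, 0.1, 0.5, 0.9])


class TestFeatures:
    def test_linear_only_one_feature_per_variable(self):
        d = _design([1, 1, 0, 0], a=[1, 2, 3, 4.0], b=[0, 1, 0, 1.0],
                    c=[5, 6, 7, 8.0])
        fs = build_features(d, classes=("L",))
        assert len(fs.features) == 3

    def test_scaled_max_is_one_and_hinge_formula(self, toy):
        fs = build_features(toy, classes=("L",))
        F = fs.design_matrix(toy.table)
        assert F.max() == pytest.approx(1.0) and F.min() == pytest.approx(0.0)
        # forward hinge at knot 0.5 evaluated at scaled value 0.75 -> 0.5
        from qregions.maxent import Feature, FeatureSet
        fs2 = FeatureSet(bounds={"x": (0.0, 1.0)},
                         features=[Feature("x", "hinge_fwd", 0.5)])
        val = fs2.design_matrix(pd.DataFrame({"x": [0.75]}))[0, 0]
        assert val == pytest.approx(0.5)

    def test_constant_variable_warns_and_keeps_linear_only(self):
        d = _design([1, 1, 0, 0], a=[1, 2, 3, 4.0], c=[2, 2, 2, 2.0])
        with pytest.warns(UserWarning, match="constant"):
            fs = build_features(d)
        assert [f for f in fs.features if f.variable == "c"] == \
            [f for f in fs.features if f.variable == "c" and f.kind == "linear"]


class TestFit:
    def test_toy_coefficient_matches_brute_force(self, toy):
        """Single-feature fit equals an exhaustive grid search of the
        penalized objective on a 3-cell background universe."""
        fs = build_features(toy, classes=("L",))
        m = fit(toy, fs, rm=1.0, tol=1e-12, max_iter=5000)
        F_p = fs.design_matrix(toy.presence)
        F_b = fs.design_matrix(toy.background)
        beta = max(F_p.std(ddof=0), 1e-4) / np.sqrt(2)
        grid = np.linspace(-10, 10, 400001)
        vals = (F_p.mean() * grid
                - np.log(np.exp(F_b[:, 0][:, None] * grid[None, :]).sum(axis=0))
                - beta * np.abs(grid))
        lam_star = grid[np.argmax(vals)]
        assert m.coefficients[0] == pytest.approx(lam_star, abs=1e-3)

    def test_huge_regularization_shrinks_to_uniform(self, toy):
        fs = build_features(toy, classes=("L",))
        m = fit(toy, fs, rm=1e6)
        assert np.all(m.coefficients == 0.0)
        assert m.objective == pytest.approx(-np.log(3))
        raw = predict(m, toy.background, "raw")
        assert np.allclose(raw, 1.0 / 3.0)

    def test_separating_feature_gets_positive_weight(self):
        d = _design([1, 1, 0, 0, 0], x=[1, 1, 0, 0, 0.0])
        fs = build_features(d, classes=("L",))
        m = fit(d, fs)
        assert m.coefficients[0] > 0

    def test_raw_sums_to_one_over_background(self, default_design):
        fs = build_features(default_design)
        m = fit(default_design, fs, max_iter=60)
        raw = predict(m, default_design.background, "raw")
        assert raw.sum() == pytest.approx(1.0, abs=1e-9)
        assert m.entropy >= 0.0

    def test_objective_never_below_uniform(self, toy):
        fs = build_features(toy)
        m = fit(toy, fs)
        assert m.objective >= -np.log(3) - 1e-12
        assert m.gain >= -1e-12


class TestPredict:
    def test_cloglog_formula_and_range(self, toy):
        fs = build_features(toy, classes=("L",))
        m = fit(toy, fs)
        raw = predict(m, toy.table, "raw")
        p = predict(m, toy.table, "cloglog")
        assert np.allclose(p, 1.0 - np.exp(-np.exp(m.entropy) * raw))
        assert np.all((p >= 0) & (p <= 1))
        # e^H * q = ln 2 -> p = 0.5 by the cloglog definition
        q = np.log(2) / np.exp(m.entropy)
        assert 1.0 - np.exp(-np.exp(m.entropy) * q) == pytest.approx(0.5)

    def test_missing_variable_is_contract_error(self, toy):
        fs = build_features(toy, classes=("L",))
        m = fit(toy, fs)
        with pytest.raises(KeyError, match="missing"):
            predict(m, pd.DataFrame({"y": [1.0]}))


class TestAUC:
    def test_perfect_ranking_and_monotone_invariance(self):
        pres = np.array([0.9, 0.8, 0.7])
        bg = np.array([0.1, 0.2, 0.3, 0.05])
        assert auc_presence_background(pres, bg) == 1.0
        a1 = auc_presence_background(pres, bg)
        a2 = auc_presence_background(np.exp(5 * pres), np.exp(5 * bg))
        assert a1 == a2

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        aucs = [auc_presence_background(rng.normal(size=100),
                                        rng.normal(size=400))
                for _ in range(40)]
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)

    def test_k_exceeding_presences_is_an_error(self, toy):
        with pytest.raises(ValueError, match="presence"):
            evaluate_cv(toy, k=10)


class TestResponseCurves:
    def test_flat_model_flat_curve(self, toy):
        fs = build_features(toy, classes=("L",))
        m = fit(toy, fs, rm=1e6)
        r = response_curve(m, "x", toy)
        assert np.ptp(r.cloglog) == pytest.approx(0.0, abs=1e-12)

    def test_monotone_increasing_response(self):
        # presences overlap the background so the response stays below
        # exact 1.0 saturation and the argmax is unique
        d = _design([1] * 3 + [0] * 8, x=[0.6, 0.75, 0.9, 0.1, 0.2, 0.3,
                                          0.4, 0.5, 0.6, 0.7, 0.8])
        fs = build_features(d, classes=("L",))
        m = fit(d, fs)
        r = response_curve(m, "x", d)
        assert m.coefficients[0] > 0
        assert np.all(np.diff(r.cloglog) >= -1e-12)
        assert r.cloglog.max() < 1.0
        assert r.adaptive_threshold == pytest.approx(r.values[-1])

    def test_quadratic_optimum_recovered(self, small_bundle):
        """With a hump-shaped truth along one variable, the adaptive
        threshold (argmax of the response) lands near the true optimum."""
        rng = np.random.default_rng(0)
        n_bg = 3000
        x_bg = rng.uniform(0, 1, n_bg)
        # presence density peaks at x = 0.6
        x_all = rng.uniform(0, 1, 30000)
        p_all = np.exp(-((x_all - 0.6) / 0.12) ** 2)
        pres = rng.choice(x_all, size=300, replace=False,
                          p=p_all / p_all.sum())
        d = _design([1] * 300 + [0] * n_bg, x=np.concatenate([pres, x_bg]))
        fs = build_features(d, classes=("L", "Q"))
        m = fit(d, fs)
        r = response_curve(m, "x", d)
        assert abs(r.adaptive_threshold - 0.6) <= 0.1


class TestImportance:
    def test_contributions_sum_and_noise_has_no_gain(self, small_bundle):
        from qregions.occurrences import OccurrenceSet, assemble_design
        design = assemble_design(OccurrenceSet(small_bundle.presences),
                                 small_bundle.env, 1200, seed=0)
        sub_vars = ["cov1", "cov2", "noise1"]
        sub = DesignTable(design.table[["label", "lon", "lat"] + sub_vars].copy(),
                          sub_vars, design.background_n)
        fs = build_features(sub)
        vi = variable_importance(sub, fs, max_iter=150)
        assert sum(vi.percent_contribution.values()) == pytest.approx(100, abs=0.01)
        only_noise, _ = vi.jackknife["noise1"]
        only_cov1, _ = vi.jackknife["cov1"]
        assert only_noise < 0.2 * only_cov1
        for v, (only, _) in vi.jackknife.items():
            assert only <= vi.full_gain + 1e-6


class TestProjection:
    def test_projection_consistent_with_row_prediction(self, small_bundle,
                                                       default_design=None):
        from qregions.occurrences import OccurrenceSet, assemble_design
        design = assemble_design(OccurrenceSet(small_bundle.presences),
                                 small_bundle.env, 800, seed=0)
        fs = build_features(design)
        m = fit(design, fs, max_iter=100)
        surf = project_to_raster(m, small_bundle.env)
        assert np.nanmin(surf.values) >= 0 and np.nanmax(surf.values) <= 1
        spec = surf.spec
        row, col = 7, 11
        lon, lat = spec.cell_center(row, col)
        rowvals = {v: small_bundle.env.layers[v].values[row, col]
                   for v in fs.variables}
        direct = predict(m, pd.DataFrame([rowvals]), "cloglog")[0]
        assert surf.values[row, col] == pytest.approx(direct, rel=1e-12)

    def test_missing_layer_is_contract_error(self, small_bundle):
        from qregions.occurrences import OccurrenceSet, assemble_design
        from qregions.raster import RasterStack
        design = assemble_design(OccurrenceSet(small_bundle.presences),
                                 small_bundle.env, 500, seed=0)
        fs = build_features(design)
        m = fit(design, fs, max_iter=40)
        partial = RasterStack({"cov1": small_bundle.env.layers["cov1"]})
        with pytest.raises(KeyError, match="missing"):
            project_to_raster(m, partial)


def test_split_mode_runs(small_bundle):
    from qregions.occurrences import OccurrenceSet, assemble_design
    design = assemble_design(OccurrenceSet(small_bundle.presences),
                             small_bundle.env, 800, seed=0)
    auc = evaluate_split(design, train_fraction=0.75, seed=0, max_iter=80)
    assert 0.0 <= auc <= 1.0
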