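"""NIPALS PLS: closed-form oracles, OLS limit, bookkeeping and selection."""

import warnings

import numpy as np
import pytest

from pbaekit.pls import (
    fit_pls,
    loading_map,
    predict,
    rmse_scree,
    select_components,
    variable_response_correlations,
    variance_tables,
    ScreeCurve,
)


def _autoscale(M):
    return (M - M.mean(axis=0)) / M.std(axis=0, ddof=1)


@pytest.fixture
def fullrank_data():
    rng = np.random.default_rng(21)
    X = rng.standard_normal((30, 8))
    B = rng.standard_normal((8, 2))
    Y = X @ B + 0.3 * rng.standard_normal((30, 2))
    return X, Y


class TestFitPLS:
    def test_ols_equivalence_at_full_depth(self, fullrank_data):
        X, Y = fullrank_data
        model = fit_pls(X, Y, H=8)
        pls_pred = predict(model, X, 8)
        Xa = np.column_stack([np.ones(len(X)), X])
        ols_pred = Xa @ np.linalg.lstsq(Xa, Y, rcond=None)[0]
        np.testing.assert_allclose(pls_pred, ols_pred, atol=1e-8)

    def test_first_weight_is_xty_direction(self):
        rng = np.random.default_rng(22)
        X = rng.standard_normal((25, 6))
        y = rng.standard_normal(25)
        model = fit_pls(X, y, H=3)
        ref = _autoscale(X).T @ _autoscale(y[:, None])[:, 0]
        ref /= np.linalg.norm(ref)
        cos = abs(ref @ model.W[:, 0])
        assert cos >= 1 - 1e-10

    def test_score_orthogonality_and_weight_norms(self, fullrank_data):
        X, Y = fullrank_data
        model = fit_pls(X, Y, H=8)
        T = model.T
        G = T.T @ T
        norms = np.sqrt(np.diag(G))
        off = G - np.diag(np.diag(G))
        assert np.all(np.abs(off) < 1e-8 * np.outer(norms, norms))
        np.testing.assert_allclose(
            np.linalg.norm(model.W, axis=0), 1.0, atol=1e-10
        )
        WtW = model.W.T @ model.W
        assert np.max(np.abs(WtW - np.eye(model.H))) < 1e-8

    def test_noiseless_linear_fit_is_exact(self):
        rng = np.random.default_rng(23)
        T = rng.standard_normal((20, 3))
        P = rng.standard_normal((7, 3))
        X = T @ P.T
        B = rng.standard_normal((7, 1))
        Y = X @ B
        model = fit_pls(X, Y, H=3)
        assert model.r2y_cumulative[-1] >= 1 - 1e-10

    def test_sklearn_cross_check(self, fullrank_data):
        # independent implementation of the same model family
        from sklearn.cross_decomposition import PLSRegression

        X, Y = fullrank_data
        model = fit_pls(X, Y, H=4)
        sk = PLSRegression(n_components=4, scale=True, tol=1e-14, max_iter=10000).fit(X, Y)
        np.testing.assert_allclose(
            predict(model, X, 4), sk.predict(X), atol=1e-6
        )

    def test_h_too_large_rejected(self, fullrank_data):
        X, Y = fullrank_data
        with pytest.raises(ValueError):
            fit_pls(X, Y, H=9)

    def test_permutation_null_r2(self):
        rng = np.random.default_rng(24)
        X = rng.standard_normal((36, 10))
        y = X[:, 0] + 0.1 * rng.standard_normal(36)
        r2s = []
        for _ in range(200):
            yp = rng.permutation(y)
            m = fit_pls(X, yp, H=1)
            r2s.append(m.r2y_cumulative[0])
        assert np.mean(r2s) < 3.0 / (36 - 1) * 10  # p=10 descriptors inflate null


class TestPredict:
    def test_h0_predicts_means(self, fullrank_data):
        X, Y = fullrank_data
        model = fit_pls(X, Y, H=4)
        pred = predict(model, X, 0)
        np.testing.assert_allclose(pred, np.tile(Y.mean(axis=0), (len(X), 1)))

    def test_interpolation_limit(self):
        rng = np.random.default_rng(25)
        X = rng.standard_normal((15, 5))
        Y = X @ rng.standard_normal((5, 2))
        model = fit_pls(X, Y, H=5)
        np.testing.assert_allclose(predict(model, X, 5), Y, atol=1e-8)

    def test_heldout_exact_recovery_on_rank2_truth(self):
        rng = np.random.default_rng(26)
        T = rng.standard_normal((30, 2))
        P = rng.standard_normal((6, 2))
        X = T @ P.T
        B = rng.standard_normal((6, 1))
        Y = X @ B
        model = fit_pls(X[:20], Y[:20], H=2)
        np.testing.assert_allclose(predict(model, X[20:], 2), Y[20:], atol=1e-8)

    def test_column_mismatch_rejected(self, fullrank_data):
        X, Y = fullrank_data
        model = fit_pls(X, Y, H=2)
        with pytest.raises(ValueError):
            predict(model, X[:, :5], 2)


class TestScreeAndSelection:
    def test_noiseless_rank2_rmse_floor(self):
        rng = np.random.default_rng(27)
        T = rng.standard_normal((20, 2))
        X = T @ rng.standard_normal((6, 2)).T
        Y = X @ rng.standard_normal((6, 1))
        model = fit_pls(X, Y, H=4)
        scree = rmse_scree(model)
        assert scree.rmse[1] < 1e-10

    def test_rmse_nonincreasing_and_consistent_with_predict(self, fullrank_data):
        X, Y = fullrank_data
        model = fit_pls(X, Y, H=6)
        scree = rmse_scree(model)
        assert np.all(np.diff(scree.rmse) <= 1e-10)
        for h in (1, 3, 6):
            resid = _autoscale(Y) - (
                (predict(model, X, h) - model.y_means) / model.y_sds
            )
            ref = np.sqrt(np.mean(resid**2))
            assert scree.rmse[h - 1] == pytest.approx(ref, abs=1e-10)

    def test_variance_criterion_on_published_style_series(self):
        # cumulative X variance reaching 80% at the sixth component
        r2x_cum = np.array(
            [0.27, 0.45, 0.51, 0.67, 0.77, 0.82, 0.84, 0.87, 0.90, 0.93]
        )
        scree = ScreeCurve(h=np.arange(1, 11), rmse=np.linspace(1.0, 0.1, 10))
        sel = select_components(scree, r2x_cum, threshold=0.80)
        assert sel.h_variance == 6

    def test_constructed_single_knee(self):
        rmse = np.array([10.0, 5.0, 4.5, 4.4, 4.35, 4.3])
        scree = ScreeCurve(h=np.arange(1, 7), rmse=rmse)
        sel = select_components(scree, np.linspace(0.3, 0.95, 6))
        assert sel.h_elbow == 2

    def test_h_too_small_rejected(self):
        scree = ScreeCurve(h=np.arange(1, 3), rmse=np.array([1.0, 0.5]))
        with pytest.raises(ValueError):
            select_components(scree, np.array([0.5, 0.9]))

    def test_latent_dimension_recovered_on_simulated_libraries(self):
        from pbaekit.library import standardize
        from pbaekit.simulate import LibrarySimConfig, generate_library

        hits = 0
        n_runs = 30
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for s in range(n_runs):
                cfg = LibrarySimConfig(noise_seed=s, loadings_seed=500 + s)
                table, resp, _ = generate_library(cfg)
                m = fit_pls(standardize(table).to_frame(), np.log(resp), 10)
                sel = select_components(rmse_scree(m), m.r2x_cumulative)
                hits += sel.h_selected == cfg.n_latent
        assert hits / n_runs >= 0.9


class TestVarianceTables:
    def test_cumulative_is_running_sum(self, fullrank_data):
        X, Y = fullrank_data
        model = fit_pls(X, Y, H=6)
        vt = variance_tables(model)
        np.testing.assert_allclose(
            vt["X_R2_cum"], vt["X_R2"].cumsum(), atol=1e-12
        )
        np.testing.assert_allclose(
            vt["Y_R2_cum"], vt["Y_R2"].cumsum(), atol=1e-12
        )
        assert (vt["X_R2_cum"].diff().dropna() >= -1e-12).all()
        assert vt["X_R2_cum"].iloc[-1] <= 1 + 1e-12
        assert vt["Y_R2_cum"].iloc[-1] <= 1 + 1e-12

    def test_rank2_x_fully_explained_at_2(self):
        rng = np.random.default_rng(28)
        T = rng.standard_normal((20, 2))
        X = T @ rng.standard_normal((5, 2)).T
        Y = X @ rng.standard_normal((5, 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_pls(X, Y, H=2)
        assert model.r2x_cumulative[1] == pytest.approx(1.0, abs=1e-10)

    def test_matches_direct_frobenius_recomputation(self, fullrank_data):
        X, Y = fullrank_data
        model = fit_pls(X, Y, H=5)
        X0 = _autoscale(X)
        ssx0 = (X0**2).sum()
        for h in range(model.H):
            t = model.T[:, h]
            p = model.P[:, h]
            ref = (t @ t) * (p @ p) / ssx0
            assert model.r2x_per_component[h] == pytest.approx(ref, rel=1e-10)


class TestLoadingMap:
    def test_descriptor_equal_to_score_maps_to_unit_axis(self):
        rng = np.random.default_rng(29)
        X = rng.standard_normal((25, 5))
        Y = X @ rng.standard_normal((5, 2))
        model = fit_pls(X, Y, H=3)
        # craft a new model input whose first column IS t1
        X2 = np.column_stack([model.T[:, 0], X])
        model2 = fit_pls(X2, Y, H=2)
        lm = loading_map(model2)
        c1 = lm[lm["name"] == "var_0"].iloc[0]
        assert abs(c1["comp1"]) == pytest.approx(1.0, abs=1e-6)
        assert abs(c1["comp2"]) == pytest.approx(0.0, abs=1e-6)

    def test_coordinates_bounded_and_match_direct_correlation(self, fullrank_data):
        X, Y = fullrank_data
        model = fit_pls(X, Y, H=3)
        lm = loading_map(model)
        coords = lm[["comp1", "comp2"]].to_numpy()
        assert np.all(np.abs(coords) <= 1 + 1e-10)
        X0 = _autoscale(X)
        for j in range(X.shape[1]):
            r1 = np.corrcoef(X0[:, j], model.T[:, 0])[0, 1]
            assert lm.iloc[j]["comp1"] == pytest.approx(r1, abs=1e-12)


class TestVariableResponseCorrelations:
    def test_sign_matches_simple_regression(self):
        rng = np.random.default_rng(30)
        x = rng.standard_normal(30)
        y = 2.5 * x + 0.1 * rng.standard_normal(30)
        model = fit_pls(x[:, None], y, H=1)
        vr = variable_response_correlations(model, 1)
        assert vr["correlation"].iloc[0] > 0

    def test_planted_sign_pattern_recovered(self):
        rng = np.random.default_rng(31)
        hits, total = 0, 0
        for _ in range(100):
            t = rng.standard_normal(36)
            signs = rng.choice([-1.0, 1.0], size=8)
            X = np.outer(t, signs) + 0.3 * rng.standard_normal((36, 8))
            y = 2.0 * t
            model = fit_pls(X, y, H=1)
            vr = variable_response_correlations(model, 1)
            hits += int(np.sum(np.sign(vr["correlation"]) == signs))
            total += 8
        assert hits / total >= 0.95

    def test_degenerate_prediction_flagged(self):
        rng = np.random.default_rng(32)
        X = rng.standard_normal((10, 3))
        y = rng.standard_normal(10)
        model = fit_pls(X, y, H=1)
        model.Q = np.zeros_like(model.Q)  # force a constant prediction
        vr = variable_response_correlations(model, 1)
        assert vr["degenerate"].all()
        assert (vr["correlation"] == 0).all()
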