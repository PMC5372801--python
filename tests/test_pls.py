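"""PLS decomposition, permutation inference, VIP scores and LV selection."""

import itertools

import numpy as np
import pandas as pd
import pytest

from compartpls import (PLSModel, fit_pls, impute_features, permutation_test,
                        select_latent_variables, vip_scores)


def _centre(M):
    M = np.asarray(M, dtype=float)
    return M - M.mean(axis=0)


class TestFit:
    def test_perfectly_collinear_first_column(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=8)
        X = np.zeros((8, 4))
        X[:, 0] = y
        model = fit_pls(X, y, n_components=1, scale=False)
        np.testing.assert_allclose(model.weights[:, 0], [1, 0, 0, 0], atol=1e-12)
        assert model.explained_y[0] == pytest.approx(1.0)
        np.testing.assert_allclose(model.y_residual, 0.0, atol=1e-10)

    def test_first_weight_is_normalised_cross_covariance(self):
        """Closed form for the first PLS1 component: w ∝ X'y (centred)."""
        X = np.array([[1, 4, 2], [2, 1, 7], [3, 5, 1], [4, 2, 6], [5, 9, 3], [6, 3, 8]],
                     dtype=float)
        y = np.array([2.0, 1.0, 4.0, 3.0, 7.0, 5.0])
        model = fit_pls(X, y, n_components=1, scale=False)
        c = _centre(X).T @ _centre(y)
        np.testing.assert_allclose(model.weights[:, 0], c / np.linalg.norm(c),
                                   atol=1e-12)
        assert model.singular_values[0] == pytest.approx(np.linalg.norm(c))

    def test_first_weight_maximises_covariance(self):
        """Grid-search oracle: no random unit vector beats the fitted weight."""
        rng = np.random.default_rng(3)
        X, y = rng.normal(size=(10, 4)), rng.normal(size=10)
        model = fit_pls(X, y, n_components=1, scale=False)
        Xc, yc = _centre(X), _centre(y)
        best_fit = abs(yc @ (Xc @ model.weights[:, 0]))
        W = rng.normal(size=(20000, 4))
        W /= np.linalg.norm(W, axis=1, keepdims=True)
        best_random = np.abs(W @ (Xc.T @ yc)).max()
        assert best_fit >= best_random - 1e-9

    def test_y_orthogonal_to_predictors(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 3))
        y0 = rng.normal(size=12)
        Xc = _centre(X)
        # remove every predictor direction (and the mean) from y
        proj = Xc @ np.linalg.lstsq(Xc, _centre(y0), rcond=None)[0]
        y = _centre(y0) - proj
        model = fit_pls(X, y, n_components=1, scale=False)
        assert model.singular_values[0] == pytest.approx(0.0, abs=1e-9)
        assert model.explained_y[0] == pytest.approx(0.0, abs=1e-12)

    def test_reconstruction_identities(self, rng):
        X, y = rng.normal(size=(20, 5)), rng.normal(size=20)
        model = fit_pls(X, y, n_components=3, scale=True)
        Xc = (X - X.mean(0)) / X.std(0, ddof=1)
        yc = (y - y.mean())[:, None]
        np.testing.assert_allclose(
            Xc, model.x_scores @ model.x_loadings.T + model.x_residual, atol=1e-10)
        np.testing.assert_allclose(
            yc, model.x_scores @ model.y_loadings.T + model.y_residual, atol=1e-10)
        # unit-norm weights, orthogonal scores, sign convention
        np.testing.assert_allclose(np.linalg.norm(model.weights, axis=0), 1.0,
                                   atol=1e-12)
        G = model.x_scores.T @ model.x_scores
        np.testing.assert_allclose(G - np.diag(np.diag(G)), 0.0, atol=1e-8)
        for a in range(model.r):
            w = model.weights[:, a]
            assert w[np.argmax(np.abs(w))] > 0

    def test_full_rank_decomposition_explains_all_of_x(self, rng):
        X, y = rng.normal(size=(20, 5)), rng.normal(size=20)
        model = fit_pls(X, y, n_components=5, scale=True)
        assert model.explained_x.sum() == pytest.approx(1.0, abs=1e-10)
        assert model.explained_y.sum() <= 1.0 + 1e-12

    def test_row_permutation_invariance(self, rng):
        X, y = rng.normal(size=(15, 6)), rng.normal(size=15)
        order = rng.permutation(15)
        m0 = fit_pls(X, y, 2)
        m1 = fit_pls(X[order], y[order], 2)
        np.testing.assert_allclose(m0.singular_values, m1.singular_values, rtol=1e-10)
        np.testing.assert_allclose(m0.explained_y, m1.explained_y, rtol=1e-10)
        np.testing.assert_allclose(m0.weights, m1.weights, atol=1e-10)

    def test_matches_sklearn_pls_regression(self, rng):
        """Independent cross-check against scikit-learn's NIPALS PLS."""
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, y = rng.normal(size=(30, 6)), rng.normal(size=30)
        model = fit_pls(X, y, n_components=3, scale=False)
        sk = sklearn.PLSRegression(n_components=3, scale=False).fit(X, y)
        for a in range(3):
            ours, theirs = model.weights[:, a], sk.x_weights_[:, a]
            sign = np.sign(ours @ theirs)
            np.testing.assert_allclose(ours, sign * theirs, atol=1e-8)
            np.testing.assert_allclose(model.x_scores[:, a],
                                       sign * sk.x_scores_[:, a], atol=1e-6)
        yhat = (model.x_scores @ model.y_loadings.T)[:, 0] + y.mean()
        np.testing.assert_allclose(yhat, sk.predict(X).ravel(), atol=1e-6)

    @pytest.mark.parametrize("bad", [
        dict(n_components=0), dict(n_components=20),
    ])
    def test_component_bounds(self, rng, bad):
        X, y = rng.normal(size=(10, 4)), rng.normal(size=10)
        with pytest.raises(ValueError):
            fit_pls(X, y, **bad)

    def test_constant_y_rejected(self, rng):
        X = rng.normal(size=(10, 4))
        with pytest.raises(ValueError, match="zero variance"):
            fit_pls(X, np.ones(10), 1)

    def test_missing_values_rejected(self, rng):
        X = rng.normal(size=(10, 4))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit_pls(X, rng.normal(size=10), 1)


class TestPermutation:
    def test_exhaustive_enumeration_at_n5(self):
        """Monte-Carlo p agrees with all 5! = 120 permutations."""
        X = np.array([[1, 2], [2, 1], [3, 5], [4, 3], [5, 6]], dtype=float)
        y = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        Xc = (X - X.mean(0)) / X.std(0, ddof=1)
        yc = y - y.mean()
        obs = np.linalg.norm(Xc.T @ yc)
        null = [np.linalg.norm(Xc.T @ yc[list(perm)])
                for perm in itertools.permutations(range(5))]
        p_exact = np.mean(np.array(null) >= obs - 1e-12)

        res = permutation_test(X, y, component=1, n_permutations=5000, seed=11)
        assert res.observed == pytest.approx(obs)
        tol = 3 * np.sqrt(p_exact * (1 - p_exact) / 5000)
        assert abs(res.p_value - p_exact) <= tol + 1 / 5001

    def test_minimum_p_when_observed_dominates(self):
        rng = np.random.default_rng(5)
        y = np.arange(12, dtype=float)
        X = np.column_stack([y, rng.normal(size=12)])
        res = permutation_test(X, y, n_permutations=99, seed=1)
        assert res.p_value == pytest.approx(1 / 100)

    def test_constant_y_gives_p_one(self, rng):
        X = rng.normal(size=(8, 3))
        res = permutation_test(X, np.full(8, 4.2), n_permutations=200, seed=0)
        assert res.p_value == 1.0

    def test_seed_reproducibility(self, rng):
        X, y = rng.normal(size=(10, 4)), rng.normal(size=10)
        a = permutation_test(X, y, n_permutations=300, seed=9)
        b = permutation_test(X, y, n_permutations=300, seed=9)
        assert a.p_value == b.p_value
        np.testing.assert_array_equal(a.null_values, b.null_values)

    def test_second_component_null_is_valid(self, rng):
        """Looped (component > 1) path returns a p-value in (0, 1]."""
        X, y = rng.normal(size=(12, 5)), rng.normal(size=12)
        res = permutation_test(X, y, component=2, n_permutations=99, seed=2)
        assert 1 / 100 <= res.p_value <= 1.0


class TestVIP:
    def _model_with_weights(self, W, explained_y):
        W = np.asarray(W, dtype=float)
        p, r = W.shape
        return PLSModel(
            n=5, p=p, q=1, r=r, weights=W,
            x_scores=np.zeros((5, r)), y_scores=np.zeros((5, r)),
            x_loadings=np.zeros((p, r)), y_loadings=np.zeros((1, r)),
            singular_values=np.ones(r), explained_x=np.zeros(r),
            explained_y=np.asarray(explained_y, dtype=float),
            x_residual=np.zeros((5, p)), y_residual=np.zeros((5, 1)),
            x_mean=np.zeros(p), x_scale=np.ones(p), y_mean=np.zeros(1),
            scaled=True,
        )

    def test_hand_oracle_two_predictors(self):
        # one component, unit weights (0.8, 0.6): VIP = sqrt(2)*|w|
        model = self._model_with_weights([[0.8], [0.6]], [0.4])
        vip = vip_scores(model, 1)
        np.testing.assert_allclose(vip.vip, [1.131370, 0.848528], atol=1e-5)
        assert list(vip.selected) == [0]

    def test_single_predictor_is_one(self):
        model = self._model_with_weights([[1.0]], [0.3])
        assert vip_scores(model, 1).vip[0] == pytest.approx(1.0)

    def test_mean_square_is_one_on_fitted_models(self, rng):
        for _ in range(20):
            n, p = 15, int(rng.integers(2, 10))
            r = int(rng.integers(1, min(n - 1, p) + 1))
            model = fit_pls(rng.normal(size=(n, p)), rng.normal(size=n), r)
            vip = vip_scores(model)
            assert np.mean(vip.vip ** 2) == pytest.approx(1.0, abs=1e-10)

    def test_zero_explained_variance_rejected(self, rng):
        model = self._model_with_weights([[1.0], [0.0]], [0.0])
        with pytest.raises(ValueError, match="VIP undefined"):
            vip_scores(model, 1)


class TestSelection:
    def test_small_second_component_dropped(self):
        assert select_latent_variables([0.47, 0.03], [0.001, 0.001]) == 1

    def test_nonsignificant_second_component_dropped(self):
        assert select_latent_variables([0.47, 0.20], [0.001, 0.40]) == 1

    def test_all_nonsignificant_retains_none(self):
        assert select_latent_variables([0.3, 0.2], [0.2, 0.5]) == 0

    def test_rank_two_structure_retains_two(self):
        """Two strong orthogonal effects at negligible noise -> 2 LVs."""
        rng = np.random.default_rng(8)
        n = 40
        a = np.repeat([1.0, -1.0], n // 2)
        b = np.tile([1.0, -1.0], n // 2)  # orthogonal to a
        # the collinear a-b column pulls LV1 off the regression direction,
        # so a second latent variable is genuinely needed
        X = np.column_stack([a, b, a - b, 1e-2 * rng.normal(size=n)])
        y = a + 0.5 * b
        model = fit_pls(X, y, n_components=2, scale=False)
        ps = [permutation_test(X, y, component=c, n_permutations=999,
                               seed=c, scale=False).p_value for c in (1, 2)]
        assert select_latent_variables(model.explained_y, ps) == 2


class TestImputation:
    def _frame(self):
        return pd.DataFrame({"a": [1.0, np.nan, 3.0], "b": [4.0, 5.0, 6.0]},
                            index=["P0", "P1", "P2"])

    def test_mean_imputation(self):
        out = impute_features(self._frame(), "mean")
        assert out.loc["P1", "a"] == pytest.approx(2.0)

    def test_drop_strategy(self):
        out = impute_features(self._frame(), "drop")
        assert list(out.index) == ["P0", "P2"]

    def test_fully_missing_column_rejected(self):
        df = pd.DataFrame({"a": [np.nan, np.nan], "b": [1.0, 2.0]})
        with pytest.raises(ValueError, match="entirely missing"):
            impute_features(df, "mean")
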