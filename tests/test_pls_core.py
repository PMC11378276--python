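import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from naquant import correlation, cross_validate, fit_pls, fit_scaler, predict, rmse
from naquant.exceptions import (
    DegenerateResponseError,
    RankError,
    UndefinedCorrelationError,
)
from naquant.pls_core import make_splits


def _centered(rng, n, p):
    X = rng.normal(size=(n, p))
    y = rng.normal(size=n)
    return X - X.mean(axis=0), y - y.mean()


class TestMetrics:
    def test_perfect_fit(self):
        y = np.array([1.0, 2.0, 3.0])
        assert rmse(y, y) == 0.0
        assert correlation(y, y) == 1.0

    def test_hand_value(self):
        assert rmse(np.array([0.0, 0.0]), np.array([3.0, 4.0])) == pytest.approx(
            np.sqrt(25.0 / 2.0)
        )

    def test_affine_invariance(self, rng):
        y = rng.normal(size=20)
        yh = rng.normal(size=20)
        assert correlation(y, 3.0 * yh + 2.0) == pytest.approx(correlation(y, yh))
        assert correlation(y, -yh) == pytest.approx(-correlation(y, yh))

    def test_zero_variance_error(self):
        with pytest.raises(UndefinedCorrelationError):
            correlation(np.array([1.0, 1.0]), np.array([1.0, 2.0]))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            rmse(np.array([1.0]), np.array([1.0, 2.0]))

    def test_correlation_bounds(self, rng):
        for _ in range(20):
            y, yh = rng.normal(size=(2, 10))
            assert -1.0 <= correlation(y, yh) <= 1.0


class TestFitPls:
    def test_rank1_exact(self, rng):
        t = rng.normal(size=12)
        X = np.outer(t, rng.normal(size=6))
        y = X @ rng.normal(size=6)
        model = fit_pls(X, y, 1)
        assert rmse(y, X @ model.regression_vector) < 1e-10

    def test_full_rank_equals_ols(self, rng):
        X, y = _centered(rng, 8, 5)
        model = fit_pls(X, y, 5)
        b_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(X @ model.regression_vector, X @ b_ols, atol=1e-8)

    def test_matches_reference_library(self, rng):
        for _ in range(10):
            X = rng.normal(size=(10, 20))
            y = rng.normal(size=10)
            Xc, yc = X - X.mean(axis=0), y - y.mean()
            for lv in (1, 2, 3):
                mine = Xc @ fit_pls(Xc, yc, lv).regression_vector
                ref = PLSRegression(n_components=lv, scale=False).fit(X, y)
                assert np.allclose(mine + y.mean(), ref.predict(X).ravel(), atol=1e-8)

    def test_score_orthogonality_and_b_equivalence(self, rng):
        for _ in range(100):
            n, p = rng.integers(5, 15), rng.integers(3, 25)
            X, y = _centered(rng, int(n), int(p))
            lv = int(min(n - 1, p, 4))
            model = fit_pls(X, y, lv)
            T = model.scores
            gram = T.T @ T
            off = gram - np.diag(np.diag(gram))
            assert np.max(np.abs(off)) <= 1e-8 * np.max(np.diag(gram))
            # sequential-deflation prediction equals regression-vector path
            Xd = X.copy()
            y_seq = np.zeros(X.shape[0])
            for a in range(lv):
                t = Xd @ model.weights[:, a]
                y_seq += model.y_loadings[a] * t
                Xd -= np.outer(t, model.x_loadings[:, a])
            assert np.allclose(y_seq, X @ model.regression_vector, atol=1e-10)

    def test_rmsec_nonincreasing_in_lv(self, rng):
        X, y = _centered(rng, 15, 8)
        errs = [rmse(y, X @ fit_pls(X, y, a).regression_vector) for a in range(1, 7)]
        assert all(e2 <= e1 + 1e-12 for e1, e2 in zip(errs, errs[1:]))

    def test_rank_error(self, rng):
        X, y = _centered(rng, 5, 3)
        with pytest.raises(RankError):
            fit_pls(X, y, 4)

    def test_degenerate_response(self):
        X = np.array([[1.0, -1.0], [-1.0, 1.0]])
        y = np.zeros(2)
        with pytest.raises(DegenerateResponseError):
            fit_pls(X, y, 1)

    def test_predict_matches_fit(self, rng):
        X, y = _centered(rng, 10, 6)
        model = fit_pls(X, y, 3)
        assert np.allclose(predict(model, X), X @ model.regression_vector)
        assert np.allclose(predict(model, X[3]), (X @ model.regression_vector)[3])

    def test_duplicated_row_same_prediction(self, rng):
        X, y = _centered(rng, 10, 6)
        model = fit_pls(X, y, 2)
        preds = predict(model, np.vstack([X[0], X[0]]))
        assert preds[0] == preds[1]


class TestMakeSplits:
    def test_exhaustive_loo(self):
        splits = make_splits(6, leave_out=1, n_splits=6)
        assert sorted(int(s[0]) for s in splits) == list(range(6))

    def test_monte_carlo_shape(self):
        splits = make_splits(10, leave_out=3, n_splits=20, seed=0)
        assert len(splits) == 20
        for s in splits:
            assert len(set(s.tolist())) == 3

    def test_seed_reproducible(self):
        a = make_splits(10, 3, 5, seed=42)
        b = make_splits(10, 3, 5, seed=42)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_bad_args(self):
        with pytest.raises(ValueError):
            make_splits(3, leave_out=3, n_splits=5)


class TestCrossValidate:
    def test_noiseless_rank1(self, rng):
        t = np.linspace(1, 5, 12)
        X = np.outer(t, rng.normal(size=6))
        y = 2.0 * t
        cv = cross_validate(X, y, [1, 2], leave_out=3, n_splits=30, seed=0)
        assert cv.chosen_lv == 1
        assert cv.rmsecv_by_lv[1] < 1e-8

    def test_seed_determinism(self, rng):
        X = rng.normal(size=(12, 6))
        y = rng.normal(size=12)
        a = cross_validate(X, y, [1, 2, 3], n_splits=25, seed=5)
        b = cross_validate(X, y, [1, 2, 3], n_splits=25, seed=5)
        assert a.rmsecv_by_lv == b.rmsecv_by_lv
        assert a.chosen_lv == b.chosen_lv

    def test_exhaustive_loo_matches_bruteforce(self, rng):
        """LOO via cross_validate == hand-rolled LOO with the reference PLS."""
        X = rng.normal(size=(6, 4))
        y = rng.normal(size=6) + X @ np.array([1.0, -1.0, 0.5, 0.0])
        for lv in (1, 2):
            cv = cross_validate(
                X, y, [lv], leave_out=1, n_splits=6, scaling="autoscale"
            )
            residuals = []
            for i in range(6):
                tr = [j for j in range(6) if j != i]
                mu, sd = X[tr].mean(0), X[tr].std(0, ddof=1)
                ym, ys = y[tr].mean(), y[tr].std(ddof=1)
                ref = PLSRegression(n_components=lv, scale=False)
                ref.fit((X[tr] - mu) / sd, (y[tr] - ym) / ys)
                pred = ref.predict(((X[i] - mu) / sd)[None, :]).ravel()[0] * ys + ym
                residuals.append(y[i] - pred)
            expected = float(np.sqrt(np.mean(np.square(residuals))))
            assert cv.rmsecv_by_lv[lv] == pytest.approx(expected, abs=1e-8)

    def test_lv_beyond_rank_skipped(self, rng):
        X = rng.normal(size=(5, 3))
        y = rng.normal(size=5) + X[:, 0]
        cv = cross_validate(X, y, [1, 2, 3, 4], leave_out=1, n_splits=5, scaling=None)
        # training folds have 4 samples -> at most 3 components
        assert 4 not in cv.rmsecv_by_lv
        assert set(cv.rmsecv_by_lv) == {1, 2, 3}

    def test_one_se_rule_never_larger(self, rng):
        X = rng.normal(size=(20, 10))
        y = rng.normal(size=20) + X[:, 0] + 0.5 * X[:, 1]
        grid = [1, 2, 3, 4, 5]
        cv_min = cross_validate(X, y, grid, n_splits=30, seed=2)
        cv_1se = cross_validate(X, y, grid, n_splits=30, seed=2, lv_selection="one_se")
        assert cv_1se.chosen_lv <= cv_min.chosen_lv
        assert cv_1se.rmsecv_by_lv == cv_min.rmsecv_by_lv
        with pytest.raises(ValueError):
            cross_validate(X, y, grid, lv_selection="aic")

    def test_tie_breaks_to_smaller_lv(self, rng):
        t = np.linspace(1, 5, 10)
        X = np.outer(t, np.ones(3))
        y = t.copy()
        cv = cross_validate(X, y, [1, 2], leave_out=2, n_splits=10, scaling="center")
        assert cv.chosen_lv == 1
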