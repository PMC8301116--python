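import io

import numpy as np
import pytest

from nmrcal.pls import (CVResult, fit_pls, load_model, loo_cv, predict,
                        predict_spectra, save_model, select_n_lv,
                        select_n_lv_from_curve, vip_scores)
from nmrcal.preprocess import Pretreatment, WindowSet
from nmrcal.spectra_io import SpectraMatrix, ValidationError


def textbook_nipals_pls1(X, y, n_lv):
    """Independent reference NIPALS with the classical inner loop."""
    Xc = X - X.mean(axis=0)
    yc = (y - y.mean()).astype(float)
    T, P, Q, W = [], [], [], []
    for _ in range(n_lv):
        u = yc.copy()
        t_prev = np.zeros(len(yc))
        for _ in range(500):
            w = Xc.T @ u / (u @ u)
            w = w / np.linalg.norm(w)
            t = Xc @ w
            q = (yc @ t) / (t @ t)
            u = yc * q / (q * q) if q != 0 else yc
            if np.linalg.norm(t - t_prev) < 1e-12 * np.linalg.norm(t):
                break
            t_prev = t
        p = Xc.T @ t / (t @ t)
        Xc = Xc - np.outer(t, p)
        yc = yc - q * t
        T.append(t), P.append(p), Q.append(q), W.append(w)
    return (np.array(W).T, np.array(P).T, np.array(T).T, np.array(Q))


def random_instance(rng, n=6, p=8, n_lv=3):
    X = rng.normal(size=(n, p))
    y = rng.normal(size=n)
    return X, y, n_lv


class TestFitPLS:
    def test_exact_linear_single_component(self, rng):
        v = rng.normal(size=20)
        c = rng.uniform(1, 5, size=9)
        X = np.outer(c, v)
        y = 3.0 * c + 1.0
        m = fit_pls(X, y, 1)
        resid = predict(m, X) - y
        assert np.sqrt(np.mean(resid**2)) <= 1e-8
        assert np.corrcoef(predict(m, X), y)[0, 1] == pytest.approx(1.0)

    def test_full_rank_matches_least_squares(self, rng):
        for _ in range(20):
            X, y, _ = random_instance(rng, n=7, p=5)
            rank = np.linalg.matrix_rank(X - X.mean(axis=0))
            m = fit_pls(X, y, rank)
            Xc = X - X.mean(axis=0)
            yhat_ls = Xc @ np.linalg.pinv(Xc) @ (y - y.mean()) + y.mean()
            np.testing.assert_allclose(predict(m, X), yhat_ls, atol=1e-6)

    def test_matches_textbook_nipals(self, rng):
        for _ in range(20):
            X, y, a = random_instance(rng)
            m = fit_pls(X, y, a)
            W, P, T, q = textbook_nipals_pls1(X, y, a)
            for k in range(a):
                s = np.sign(W[:, k] @ m.weights[:, k])
                np.testing.assert_allclose(s * W[:, k], m.weights[:, k],
                                           atol=1e-8)
                np.testing.assert_allclose(s * P[:, k], m.x_loadings[:, k],
                                           atol=1e-8)
                np.testing.assert_allclose(s * T[:, k], m.x_scores[:, k],
                                           atol=1e-8)
                np.testing.assert_allclose(s * q[k], m.y_loadings[k],
                                           atol=1e-8)

    def test_matches_sklearn_predictions(self, rng):
        sklearn_pls = pytest.importorskip("sklearn.cross_decomposition")
        for _ in range(10):
            X, y, a = random_instance(rng, n=9, p=12)
            m = fit_pls(X, y, a)
            ref = sklearn_pls.PLSRegression(n_components=a, scale=False)
            ref.fit(X, y)
            np.testing.assert_allclose(predict(m, X),
                                       ref.predict(X).ravel(), atol=1e-8)

    def test_scores_orthogonal(self, rng):
        X, y, a = random_instance(rng, n=10, p=14, n_lv=4)
        m = fit_pls(X, y, a + 1)
        G = m.x_scores.T @ m.x_scores
        np.testing.assert_allclose(G - np.diag(np.diag(G)), 0, atol=1e-8)

    def test_deflation_reduces_x_residual_monotonically(self, rng):
        X, y, _ = random_instance(rng, n=8, p=10)
        Xc = X - X.mean(axis=0)
        m = fit_pls(X, y, 5)
        norms = [np.linalg.norm(Xc)]
        for a in range(1, 6):
            approx = m.x_scores[:, :a] @ m.x_loadings[:, :a].T
            norms.append(np.linalg.norm(Xc - approx))
        assert all(b < a for a, b in zip(norms, norms[1:]))

    def test_row_order_invariance(self, rng):
        X, y, a = random_instance(rng, n=8, p=9)
        perm = rng.permutation(8)
        m1 = fit_pls(X, y, a)
        m2 = fit_pls(X[perm], y[perm], a)
        np.testing.assert_allclose(m1.coef, m2.coef, atol=1e-9)
        assert m1.intercept == pytest.approx(m2.intercept, abs=1e-9)

    def test_rank_exceeded_raises_unless_capped(self, rng):
        v = rng.normal(size=10)
        X = np.outer(rng.uniform(1, 2, size=6), v)  # centered rank 1
        y = X[:, 0] + rng.normal(0, 0.01, 6)
        with pytest.raises(ValidationError, match="rank"):
            fit_pls(X, y, 3)
        m = fit_pls(X, y, 3, cap_to_rank=True)
        assert m.n_lv == 1

    @pytest.mark.parametrize("bad", ["constant_y", "nan_x", "too_few"])
    def test_degenerate_inputs_rejected(self, rng, bad):
        X, y, _ = random_instance(rng)
        if bad == "constant_y":
            y = np.full_like(y, 2.0)
        elif bad == "nan_x":
            X[0, 0] = np.nan
        elif bad == "too_few":
            X, y = X[:3], y[:3]
        with pytest.raises(ValidationError):
            fit_pls(X, y, 3)


class TestPredict:
    def test_training_self_consistency(self, rng):
        X, y, a = random_instance(rng, n=9, p=11)
        m = fit_pls(X, y, a)
        np.testing.assert_allclose(
            predict(m, X),
            m.x_mean @ m.coef * 0 + (X - m.x_mean) @ m.coef + m.y_mean,
            atol=1e-10)

    def test_duplicated_row_predicts_identically(self, rng):
        X, y, a = random_instance(rng)
        m = fit_pls(X, y, a)
        assert predict(m, X[2]) == pytest.approx(predict(m, X)[2], abs=1e-12)

    def test_grid_mismatch_rejected(self, rng):
        X, y, a = random_instance(rng)
        m = fit_pls(X, y, a)
        with pytest.raises(ValidationError, match="mismatch"):
            predict(m, np.ones((2, 5)))

    def test_zero_noise_mixture_recovered(self, rng):
        # forward simulation: y is a linear functional of a 3-component mixture
        bases = rng.normal(size=(3, 30))
        C = rng.uniform(0.5, 2.0, size=(12, 3))
        X = C @ bases
        y = C @ np.array([1.0, -2.0, 0.5])
        m = fit_pls(X, y, 3)
        np.testing.assert_allclose(predict(m, X), y, atol=1e-6)


class TestLOOCV:
    def test_perfect_model_limit(self, rng):
        v = rng.normal(size=15)
        c = rng.uniform(1, 4, size=10)
        X = np.outer(c, v)
        y = 2.0 * c
        cv = loo_cv(X, y, 1)
        assert cv.rmsecv_by_lv[0] <= 1e-6

    def test_matches_brute_force_oracle(self, rng):
        X, y, _ = random_instance(rng, n=10, p=12)
        a_max = 4
        cv = loo_cv(X, y, a_max)
        # oracle: explicit loop, separate refit per left-out sample and LV
        for a in range(1, a_max + 1):
            errs = []
            for i in range(10):
                keep = np.arange(10) != i
                m = fit_pls(X[keep], y[keep], a)
                errs.append(predict(m, X[i])[0] - y[i])
            np.testing.assert_allclose(cv.rmsecv_by_lv[a - 1],
                                       np.sqrt(np.mean(np.square(errs))),
                                       atol=1e-10)

    def test_pretreatment_refit_inside_folds(self, rng):
        grid = np.linspace(200.0, 20.0, 25)
        X = SpectraMatrix(tuple(f"s{i}" for i in range(12)), grid,
                          rng.normal(size=(12, 25)) + 10)
        y = rng.normal(size=12) + 5
        pre = Pretreatment(kind="msc")
        cv = loo_cv(X, y, 3, pretreatment=pre)
        # oracle: manual fold with pretreatment fit on the training part
        i = 0
        keep = np.arange(12) != i
        sub = SpectraMatrix(tuple(f"s{j}" for j in range(1, 12)), grid,
                            X.X[keep])
        sub_t, fitted = pre.fit_transform(sub)
        m = fit_pls(sub_t.X, y[keep], cv.chosen_lv)
        expected = predict(m, fitted.transform_array(X.X[i], grid))[0]
        assert cv.loo_predictions[0] == pytest.approx(expected, abs=1e-10)

    def test_rcv_not_above_calibration_r(self, default_set):
        # mirrors the universal pattern in calibration tables: LOO
        # correlation never beats the fitted correlation
        X, refs = default_set
        ids = X.sample_ids[:25]
        sub = X.subset(ids)
        for prop in ("protein", "fat"):
            y = refs.property_values(prop, ids)
            pre = Pretreatment(kind="snv")
            Xt, _ = pre.fit_transform(sub)
            m = fit_pls(Xt, y, 4)
            r_cal = np.corrcoef(predict(m, Xt), y)[0, 1]
            cv = loo_cv(sub, y, 4, pretreatment=pre, parsimony_tol=0.0)
            r_cv = np.corrcoef(cv.predictions_by_lv[:, 3], y)[0, 1]
            assert r_cv < r_cal


class TestSelectNLV:
    @pytest.mark.parametrize("curve,expected", [
        ([5.0, 3.0, 1.0, 1.0, 1.0], 3),      # plateau reached at 3
        ([5.0, 2.0, 1.99, 2.5], 2),          # 2.0 within 2% of min 1.99
        ([4.0], 1),                          # single entry
        ([1.0, 0.5, 0.49], 3),               # 0.5 is 2.04% above min 0.49
    ])
    def test_parsimony_rule(self, curve, expected):
        assert select_n_lv_from_curve(curve, 0.02) == expected

    def test_works_on_cv_result(self, rng):
        X, y, _ = random_instance(rng, n=12, p=6)
        cv = loo_cv(X, y, 3)
        assert select_n_lv(cv) == cv.chosen_lv


class TestVIP:
    def test_mean_squared_vip_is_one(self, rng):
        X, y, a = random_instance(rng, n=10, p=16)
        m = fit_pls(X, y, a)
        assert np.mean(vip_scores(m) ** 2) == pytest.approx(1.0, abs=1e-8)

    def test_single_lv_closed_form(self, rng):
        X, y, _ = random_instance(rng, n=8, p=10)
        m = fit_pls(X, y, 1)
        w = m.weights[:, 0]
        np.testing.assert_allclose(
            vip_scores(m), np.sqrt(10) * np.abs(w) / np.linalg.norm(w),
            atol=1e-10)

    def test_vip_localizes_informative_region(self, rng):
        # protein signal confined to 160-180 ppm; elsewhere interferents
        grid = np.linspace(220.0, 0.0, 400)
        protein_band = np.exp(-0.5 * ((grid - 170) / 4) ** 2)
        interferent = np.exp(-0.5 * ((grid - 60) / 6) ** 2)
        c_prot = rng.uniform(1, 3, size=20)
        c_intf = rng.uniform(1, 3, size=20)
        X = (np.outer(c_prot, protein_band) + np.outer(c_intf, interferent)
             + rng.normal(0, 0.005, size=(20, 400)))
        m = fit_pls(X, c_prot, 2)
        v = vip_scores(m)
        inside = (grid <= 180) & (grid >= 160)
        assert v[inside].mean() > v[~inside].mean()


class TestPersistence:
    def test_round_trip_predicts_bit_identically(self, default_set):
        X, refs = default_set
        ids = X.sample_ids[:20]
        sub = X.subset(ids)
        y = refs.property_values("protein", ids)
        pre = Pretreatment(kind="msc", windows=WindowSet(((220.0, 10.0),)))
        Xt, fitted = pre.fit_transform(sub)
        m = fit_pls(Xt, y, 3, property_name="protein", pretreatment=fitted,
                    grid=X.grid)
        buf = io.StringIO()
        save_model(m, buf)
        back = load_model(io.StringIO(buf.getvalue()))
        np.testing.assert_array_equal(back.coef, m.coef)
        np.testing.assert_array_equal(predict_spectra(back, X),
                                      predict_spectra(m, X))
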