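import numpy as np
import pandas as pd
import pytest

from leafspec_n import PlsConfig, SvmGridConfig, fit_plsda, fit_plsr, fit_svm
from leafspec_n.classical import (
    pls_coefficients,
    predict_model,
    predict_plsda,
    predict_plsr,
)
from tests.conftest import make_dataset


def two_gaussian_classes(rng, n=60, p=10, sep=6.0):
    X = np.vstack([rng.normal(0, 1, (n // 2, p)), rng.normal(sep, 1, (n // 2, p))])
    levels = ["low"] * (n // 2) + ["high"] * (n // 2)
    return make_dataset(X, level=levels, lnc=np.full(n, 30.0))


class TestPlsda:
    def test_separable_classes_predicted_perfectly(self, rng):
        train = two_gaussian_classes(rng)
        test = two_gaussian_classes(np.random.default_rng(99))
        h = fit_plsda(train, PlsConfig(max_latent_variables=5, seed=0))
        pred = predict_plsda(h, test)
        assert np.mean(pred == test.level) == 1.0

    def test_matches_indicator_least_squares_oracle(self, rng):
        # noiseless full-rank data, full components: PLS-DA == OLS on one-hot Y
        n, p = 40, 6
        X = rng.normal(size=(n, p))
        labels = np.where(X @ rng.normal(size=p) > 0, "high", "low")
        ds = make_dataset(X, level=list(labels), lnc=np.full(n, 30.0))
        h = fit_plsda(ds, PlsConfig(n_latent_variables=p))
        Y = np.column_stack([(labels == c).astype(float) for c in h.classes])
        Xc = X - X.mean(axis=0)
        Yc = Y - Y.mean(axis=0)
        B = np.linalg.lstsq(Xc, Yc, rcond=None)[0]
        pred_ols = np.argmax(Xc @ B + Y.mean(axis=0), axis=1)
        pred_pls = predict_plsda(h, ds)
        np.testing.assert_array_equal(pred_pls, np.asarray(h.classes)[pred_ols])

    def test_permuted_labels_score_near_chance(self, rng):
        n = 120
        X = rng.normal(size=(n, 15))
        labels = rng.permutation(["low", "high"] * (n // 2))
        ds = make_dataset(X, level=list(labels), lnc=np.full(n, 30.0))
        h = fit_plsda(ds, PlsConfig(max_latent_variables=3, seed=1))
        best_cv = max(h.meta["cv_accuracy"].values())
        assert best_cv < 0.70  # chance is 0.5; allow optimism from model selection

    def test_single_class_rejected(self, rng):
        ds = make_dataset(rng.normal(size=(10, 4)), level=["low"] * 10, lnc=np.full(10, 30.0))
        with pytest.raises(ValueError):
            fit_plsda(ds)


class TestPlsr:
    def test_exact_linear_recovery_in_three_components(self, rng):
        # with in-sample orthogonal bands the 3-dim Krylov space spans the
        # target, so 3 latent variables give an exact noiseless fit
        n, p = 60, 20
        A = rng.normal(size=(n, p))
        Q, _ = np.linalg.qr(A - A.mean(axis=0))
        beta = np.zeros(p)
        beta[[3, 9, 15]] = [1.0, -2.0, 0.5]
        y = Q @ beta
        train = make_dataset(Q, lnc=30.0 + y)
        Xt = rng.normal(size=(30, p))
        test = make_dataset(Xt, lnc=30.0 + Xt @ beta)
        h = fit_plsr(train, PlsConfig(n_latent_variables=3))
        pred = predict_plsr(h, test)
        ss_res = np.sum((pred - test.lnc) ** 2)
        ss_tot = np.sum((test.lnc - test.lnc.mean()) ** 2)
        assert 1 - ss_res / ss_tot > 1 - 1e-6

    def test_full_rank_equals_least_squares_oracle(self, rng):
        n, p = 50, 8
        X = rng.normal(size=(n, p))
        y = 30.0 + X @ rng.normal(size=p) + 0.1 * rng.normal(size=n)
        ds = make_dataset(X, lnc=y - y.min() + 1.0)
        h = fit_plsr(ds, PlsConfig(n_latent_variables=p))
        Xc = X - X.mean(axis=0)
        yc = ds.lnc - ds.lnc.mean()
        beta = np.linalg.lstsq(Xc, yc, rcond=None)[0]
        np.testing.assert_allclose(pls_coefficients(h), beta, atol=1e-8)

    def test_one_component_direction_proportional_to_xty(self, rng):
        n, p = 60, 12
        X = rng.normal(size=(n, p))
        y = X @ rng.normal(size=p) + 0.2 * rng.normal(size=n)
        y = (y - y.mean()) / y.std()
        ds = make_dataset(X, lnc=y + 50.0)
        h = fit_plsr(ds, PlsConfig(n_latent_variables=1))
        coef = pls_coefficients(h)
        Xc = X - X.mean(axis=0)
        w = Xc.T @ (ds.lnc - ds.lnc.mean())
        cos = abs(coef @ w) / (np.linalg.norm(coef) * np.linalg.norm(w))
        assert cos > 1 - 1e-8

    def test_cv_reproducible_under_seed(self, rng):
        X = rng.normal(size=(60, 30))
        y = X[:, 5] + 0.5 * rng.normal(size=60)
        ds = make_dataset(X, lnc=y - y.min() + 10.0)
        a = fit_plsr(ds, PlsConfig(max_latent_variables=6, seed=4))
        b = fit_plsr(ds, PlsConfig(max_latent_variables=6, seed=4))
        assert a.hyperparams == b.hyperparams
        assert a.meta["cv_rmse"] == b.meta["cv_rmse"]


class TestSvm:
    def test_grid_enumerates_289_pairs(self):
        grid = SvmGridConfig().grid()
        assert len(grid) == 289
        cs = sorted({c for c, _ in grid})
        assert cs[0] == 2.0**-8 and cs[-1] == 2.0**8

    def test_separable_data_selects_perfect_cv_cell(self, rng):
        train = two_gaussian_classes(rng, n=40, p=4, sep=8.0)
        small = SvmGridConfig(c_exponents=(-2, 0, 2, 4), g_exponents=(-4, -2, 0), seed=0)
        h = fit_svm(train, "classification", small)
        assert h.meta["cv_best_score"] == 1.0
        assert np.mean(predict_model(h, train) == train.level) == 1.0

    def test_svr_constant_target_predicts_constant(self, rng):
        X = rng.normal(size=(30, 5))
        ds = make_dataset(X, lnc=np.full(30, 25.0))
        small = SvmGridConfig(c_exponents=(0,), g_exponents=(0,))
        h = fit_svm(ds, "regression", small)
        pred = predict_model(h, ds)
        np.testing.assert_allclose(pred, 25.0, atol=0.11)  # epsilon-tube default 0.1

    def test_tie_break_prefers_smallest_c_then_g(self, rng):
        # constant labels per fold cannot be separated: all cells tie
        train = two_gaussian_classes(rng, n=24, p=3, sep=12.0)
        small = SvmGridConfig(c_exponents=(1, 3), g_exponents=(-3, -1), seed=0)
        h = fit_svm(train, "classification", small)
        assert (h.hyperparams["C"], h.hyperparams["gamma"]) == (2.0, 0.125)

    def test_degenerate_labels_rejected(self, rng):
        ds = make_dataset(rng.normal(size=(10, 3)), level=["low"] * 10, lnc=np.full(10, 30.0))
        with pytest.raises(ValueError):
            fit_svm(ds, "classification")
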