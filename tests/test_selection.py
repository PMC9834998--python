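import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from leafspec_n import (
    RandomFrogConfig,
    SaliencyConfig,
    SelectionResult,
    SpectraDataset,
    WplsConfig,
    random_frog,
    reduction_percent,
    saliency_select,
    subset_dataset,
    wpls_select,
)
from leafspec_n.classical import ModelHandle
from leafspec_n.selection import local_extrema
from leafspec_n import nn
from tests.conftest import make_dataset, planted_regression_data


class TestReductionPercent:
    @pytest.mark.parametrize(
        "k,total,expected",
        [(40, 2071, 98.07), (41, 2071, 98.02), (47, 2071, 97.73), (2071, 2071, 0.0)],
    )
    def test_printed_values(self, k, total, expected):
        assert reduction_percent(k, total) == pytest.approx(expected, abs=5e-3)

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            reduction_percent(5, 0)
        with pytest.raises(ValueError):
            reduction_percent(10, 5)


def brute_force_extrema(v):
    """Independent oracle: exhaustive neighbour scan with plateau collapse."""
    out = []
    n = len(v)
    for i in range(1, n - 1):
        li = i - 1
        while li > 0 and v[li] == v[i]:
            li -= 1
        ri = i + 1
        while ri < n - 1 and v[ri] == v[i]:
            ri += 1
        if v[li] == v[i] or v[ri] == v[i]:
            continue
        is_crest = v[i] > v[li] and v[i] > v[ri]
        is_trough = v[i] < v[li] and v[i] < v[ri]
        if (is_crest or is_trough) and (i == 0 or v[i - 1] != v[i]):
            out.append(i)
    return np.array(out, dtype=int)


class TestLocalExtrema:
    def test_sine_wave_matches_brute_force(self):
        x = np.sin(np.linspace(0, 8 * np.pi, 400))
        np.testing.assert_array_equal(local_extrema(x), brute_force_extrema(x))

    def test_plateau_takes_leftmost_point(self):
        v = np.array([0.0, 1.0, 1.0, 1.0, 0.0])
        np.testing.assert_array_equal(local_extrema(v), [1])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.integers(-5, 5), min_size=3, max_size=40))
    def test_random_curves_match_brute_force(self, vals):
        v = np.asarray(vals, dtype=float)
        np.testing.assert_array_equal(local_extrema(v), brute_force_extrema(v))


class TestWpls:
    def test_gaussian_bump_apex_selected_first(self, rng):
        # y depends on one band: the coefficient curve peaks there
        p = 80
        X = rng.normal(size=(200, p))
        bump = np.exp(-0.5 * ((np.arange(p) - 40) / 3.0) ** 2)
        y = X @ bump + 0.01 * rng.normal(size=200)
        ds = make_dataset(X, lnc=40.0 + y)
        res = wpls_select(ds, WplsConfig(k=1, n_latent_variables=5))
        assert res.selected_nm[0] == pytest.approx(40.0, abs=2)

    def test_selected_are_extrema_of_coefficient_curve(self, rng):
        ds, _ = planted_regression_data(rng)
        res = wpls_select(ds, WplsConfig(k=10, n_latent_variables=5))
        ext_wl = ds.wavelengths_nm[brute_force_extrema(_coef(ds))]
        assert set(res.selected_nm) <= set(ext_wl)

    def test_recovers_planted_bands(self, rng):
        ds, idx = planted_regression_data(rng)
        res = wpls_select(ds, WplsConfig(k=20, n_latent_variables=8))
        hits = sum(np.min(np.abs(res.selected_nm - i)) <= 1 for i in idx)
        assert hits >= 4

    def test_k_larger_than_extrema_returns_all_with_flag(self, rng):
        p = 30
        X = rng.normal(size=(50, p))
        y = X[:, 15] + 0.01 * rng.normal(size=50)
        ds = make_dataset(X, lnc=30.0 + y)
        res = wpls_select(ds, WplsConfig(k=10_000, n_latent_variables=3))
        assert res.config_echo["truncated"]
        assert len(res.selected_nm) == res.config_echo["n_extrema"]


def _coef(ds):
    from leafspec_n.classical import fit_plsr, pls_coefficients, PlsConfig

    return pls_coefficients(fit_plsr(ds, PlsConfig(n_latent_variables=5)))


class TestRandomFrog:
    def test_single_wavelength_gets_frequency_one(self, rng):
        X = rng.normal(size=(30, 1))
        ds = make_dataset(X, lnc=20.0 + X[:, 0] - X[:, 0].min())
        res = random_frog(ds, "regression", RandomFrogConfig(n_iterations=20, seed=0))
        assert res.scores[0] == 1.0
        assert list(res.selected_nm) == [0.0]

    def test_too_few_iterations_rejected(self):
        with pytest.raises(ValueError):
            RandomFrogConfig(n_iterations=5)

    def test_top_k_count_and_determinism(self, rng):
        ds, _ = planted_regression_data(rng, n=80, p=40)
        cfg = RandomFrogConfig(n_iterations=60, top_k=10, seed=3, cv_folds=3)
        a = random_frog(ds, "regression", cfg)
        b = random_frog(ds, "regression", cfg)
        assert len(a.selected_nm) == 10
        np.testing.assert_array_equal(a.scores, b.scores)
        np.testing.assert_array_equal(a.selected_nm, b.selected_nm)
        assert np.all((a.scores >= 0) & (a.scores <= 1))

    def test_recovers_planted_bands_across_seeds(self, rng):
        # small planted problem: informative bands should dominate the ranking
        successes = 0
        for seed in range(10):
            g = np.random.default_rng(seed)
            ds, idx = planted_regression_data(g, n=120, p=60, k=5, noise=0.05)
            cfg = RandomFrogConfig(
                n_iterations=150, top_k=40, seed=seed, cv_folds=3, inner_lv_max=6
            )
            res = random_frog(ds, "regression", cfg)
            hits = sum(i in res.selected_nm.astype(int) for i in idx)
            if hits >= 4:
                successes += 1
        assert successes >= 9

    def test_classification_task_runs(self, small_synthetic):
        from leafspec_n import fd_snv

        _, ds = small_synthetic
        pp = fd_snv(ds)
        res = random_frog(
            pp, "classification", RandomFrogConfig(n_iterations=30, top_k=5, seed=1, cv_folds=3)
        )
        assert len(res.selected_nm) == 5


def _linear_handle(w):
    """A trained scalar-output network computing w . x (linear stand-in)."""
    p = len(w)
    net = nn.Network([nn.Flatten(), nn.Dense(p, 1)], p, 1)
    net.init_params(0)
    net.layers[1].params["W"][:, 0] = np.asarray(w, dtype=np.float32)
    net.layers[1].params["b"][:] = 0.0
    return ModelHandle("cnnr", net, {}, {"trained": True})


class TestSaliency:
    def test_linear_model_ranking_equals_weight_ranking(self, rng):
        p = 50
        w = rng.normal(size=p)
        h = _linear_handle(w)
        X = rng.normal(size=(20, p))
        ds = make_dataset(X, lnc=np.full(20, 30.0))
        res = saliency_select(h, ds, SaliencyConfig(per_sample_top_k=10, final_top_k=10))
        expected = np.sort(np.argsort(-np.abs(w))[:10]).astype(float)
        np.testing.assert_array_equal(res.selected_nm, expected)

    def test_final_top_k_respected(self, rng):
        p = 60
        h = _linear_handle(rng.normal(size=p))
        ds = make_dataset(rng.normal(size=(10, p)), lnc=np.full(10, 30.0))
        res = saliency_select(h, ds, SaliencyConfig(final_top_k=40))
        assert len(res.selected_nm) == 40

    def test_untrained_model_rejected(self, rng):
        h = _linear_handle(rng.normal(size=10))
        h.meta["trained"] = False
        ds = make_dataset(rng.normal(size=(5, 10)), lnc=np.full(5, 30.0))
        with pytest.raises(ValueError):
            saliency_select(h, ds)

    def test_length_mismatch_rejected(self, rng):
        h = _linear_handle(rng.normal(size=10))
        ds = make_dataset(rng.normal(size=(5, 12)), lnc=np.full(5, 30.0))
        with pytest.raises(ValueError):
            saliency_select(h, ds)


class TestSubsetDataset:
    def test_select_all_is_identity(self, rng):
        ds, _ = planted_regression_data(rng, n=10, p=20)
        out = subset_dataset(ds, ds.wavelengths_nm)
        np.testing.assert_array_equal(out.spectra, ds.spectra)

    def test_subset_is_idempotent_and_sorted(self, rng):
        ds, _ = planted_regression_data(rng, n=10, p=20)
        wanted = [15.0, 3.0, 8.0]
        once = subset_dataset(ds, wanted)
        twice = subset_dataset(once, wanted)
        np.testing.assert_array_equal(once.wavelengths_nm, [3.0, 8.0, 15.0])
        np.testing.assert_array_equal(twice.spectra, once.spectra)

    def test_forty_column_subset(self, rng):
        wl = np.arange(430.0, 2501.0)
        ds = SpectraDataset(rng.normal(size=(3, wl.size)), wl)
        table2_rf = [594, 602, 776, 1104, 1109, 1139, 1144, 1196, 1232, 1242,
                     1274, 1472, 1473, 1490, 1516, 1534, 1568, 1597, 1600, 1604,
                     1615, 1619, 1620, 1663, 1671, 1741, 1742, 1797, 1897, 1953,
                     1958, 1963, 1989, 2012, 2047, 2103, 2106, 2134, 2135, 2211]
        out = subset_dataset(ds, np.asarray(table2_rf, dtype=float))
        assert out.n_wavelengths == 40

    def test_missing_wavelength_rejected(self, rng):
        ds, _ = planted_regression_data(rng, n=5, p=10)
        with pytest.raises(ValueError):
            subset_dataset(ds, [4.5])


def test_selection_result_json_round_trip(tmp_path, rng):
    res = SelectionResult(
        "wpls", np.arange(5.0), rng.random(5), np.array([1.0, 3.0]), {"k": 2}
    )
    path = tmp_path / "sel.json"
    res.to_json(path)
    back = SelectionResult.from_json(path)
    assert back.method == "wpls"
    np.testing.assert_allclose(back.scores, res.scores)
    np.testing.assert_array_equal(back.selected_nm, res.selected_nm)
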