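import numpy as np
import pytest

from leafspec_n import CnnTrainingProtocol, build_cnnc, build_cnnr, train_cnn, predict_cnn
from leafspec_n.cnn import cnnc_parameter_count, cnnr_parameter_count, predict_proba_cnn
from tests.conftest import make_dataset


def tiny_classification(rng, n=24, p=16, sep=4.0):
    X = np.vstack([rng.normal(0, 1, (n // 2, p)), rng.normal(sep, 1, (n // 2, p))])
    levels = ["low"] * (n // 2) + ["high"] * (n // 2)
    return make_dataset(X, level=levels, lnc=np.full(n, 30.0))


class TestBuilders:
    def test_classification_conv_hyperparameters(self):
        h = build_cnnc(64, 3)
        assert h.hyperparams["conv"] == {"filters": 16, "kernel_size": 3, "stride": 1}
        assert h.hyperparams["n_conv_blocks"] == 2

    def test_regression_conv_hyperparameters(self):
        h = build_cnnr(64)
        assert h.hyperparams["conv"] == {"filters": 32, "kernel_size": 3, "stride": 1}

    def test_parameter_count_matches_arithmetic_oracle(self):
        # layer-by-layer hand count for a 40-wavelength input
        h = build_cnnc(40, 3)
        # conv1 16*(1*3)+16; conv2 16*16*3+16; BN 16/16/64 pairs;
        # dense 16*10*64+64 (40 -> 20 -> 10 after two pools); out 64*3+3
        hand = (64) + (784) + (32 + 32 + 128) + (16 * 10 * 64 + 64) + (195)
        assert h.hyperparams["n_parameters"] == hand
        assert cnnc_parameter_count(40, 3) == hand

        hr = build_cnnr(40)
        hand_r = (32 * 3 + 32) + (32 * 32 * 3 + 32) + (2 + 64 + 64) + (
            32 * 40 * 64 + 64
        ) + (64 * 16 + 16) + 17
        assert hr.hyperparams["n_parameters"] == hand_r
        assert cnnr_parameter_count(40) == hand_r

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            build_cnnc(7, 3)
        with pytest.raises(ValueError):
            build_cnnr(4)


class TestProtocol:
    def test_learning_rate_schedule(self):
        proto = CnnTrainingProtocol()
        assert proto.lr_at(0) == pytest.approx(0.05)
        assert proto.lr_at(199) == pytest.approx(0.05)
        assert proto.lr_at(200) == pytest.approx(0.005)
        assert proto.lr_at(400) == pytest.approx(0.0005)

    def test_bad_protocol_rejected(self):
        with pytest.raises(ValueError):
            CnnTrainingProtocol(batch_size=0)
        with pytest.raises(ValueError):
            CnnTrainingProtocol(lr_initial=-1.0)


class TestTraining:
    def test_memorizes_tiny_dataset(self, rng):
        ds = tiny_classification(rng, n=8, p=16, sep=3.0)
        h = build_cnnc(16, 2)
        h = train_cnn(h, ds, None, CnnTrainingProtocol(max_epochs=120, patience=120, seed=0))
        assert np.mean(predict_cnn(h, ds) == ds.level) == 1.0

    def test_history_lr_follows_schedule(self, rng):
        ds = tiny_classification(rng)
        h = build_cnnc(16, 2)
        h = train_cnn(h, ds, None, CnnTrainingProtocol(max_epochs=5, patience=5, seed=0))
        hist = h.meta["history"]
        assert hist["lr"] == [0.05] * 5
        assert len(hist["train_loss"]) == h.meta["n_epochs_run"]

    def test_bit_identical_history_under_seed(self, rng):
        ds = tiny_classification(rng)
        runs = []
        for _ in range(2):
            h = build_cnnc(16, 2)
            h = train_cnn(h, ds, None, CnnTrainingProtocol(max_epochs=8, patience=8, seed=5))
            runs.append(h.meta["history"]["train_loss"])
        assert runs[0] == runs[1]

    def test_regression_fits_noiseless_linear_target(self, rng):
        n, p = 120, 16
        X = rng.normal(size=(n, p)).astype(np.float64)
        y = 30.0 + 3.0 * X[:, 4] - 2.0 * X[:, 11]
        ds = make_dataset(X, lnc=y)
        h = build_cnnr(p)
        # full schedule: the 1/10 decays at epochs 200 and 400 do the fine fitting
        h = train_cnn(h, ds, None, CnnTrainingProtocol(max_epochs=600, patience=600, seed=0))
        final_l1 = h.meta["history"]["train_loss"][-1]
        assert final_l1 < 0.05 * y.std()

    def test_early_stopping_on_stable_validation_loss(self, rng):
        ds = tiny_classification(rng)
        h = build_cnnc(16, 2)
        h = train_cnn(
            h, ds, ds, CnnTrainingProtocol(max_epochs=400, patience=10, seed=0)
        )
        assert h.meta["n_epochs_run"] < 400


@pytest.fixture(scope="module")
def trained():
    rng = np.random.default_rng(7)
    ds = tiny_classification(rng, n=32)
    h = build_cnnc(16, 2)
    h = train_cnn(h, ds, None, CnnTrainingProtocol(max_epochs=40, patience=40, seed=1))
    return h, ds


class TestPrediction:
    def test_untrained_model_rejected(self, rng):
        h = build_cnnc(16, 2)
        with pytest.raises(ValueError):
            predict_cnn(h, tiny_classification(rng))

    def test_duplicated_rows_predict_identically(self, trained):
        h, ds = trained
        dup = ds.take([0, 0, 3, 3])
        pred = predict_cnn(h, dup)
        assert pred[0] == pred[1] and pred[2] == pred[3]

    def test_prediction_invariant_to_sample_order(self, trained):
        h, ds = trained
        perm = np.random.default_rng(0).permutation(ds.n_samples)
        pred = predict_cnn(h, ds)
        pred_perm = predict_cnn(h, ds.take(perm))
        np.testing.assert_array_equal(pred_perm, pred[perm])

    def test_softmax_probabilities_sum_to_one(self, trained):
        h, ds = trained
        proba = predict_proba_cnn(h, ds)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_input_gradients_finite(self, trained):
        h, ds = trained
        units = np.zeros(ds.n_samples, dtype=int)
        g = h.model.input_gradient(ds.spectra, units)
        assert np.all(np.isfinite(g))
        assert g.shape == (ds.n_samples, 16)
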