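"""1-D convolutional networks for spectral classification and regression.

Two fixed architectures operate on a preprocessed spectrum of length L:

* **CNNC** (classification): two blocks of [conv(16 filters, kernel 3,
  stride 1) + ReLU -> max-pool 2/2 -> batch-norm], then dense(64) ->
  batch-norm -> dropout -> dense(n_classes). Trained with softmax
  cross-entropy and SGD.
* **CNNR** (regression): two blocks of [batch-norm -> conv(32 filters,
  kernel 3, stride 1) + ReLU], a final batch-norm, then dense(64) ->
  dense(16) -> dense(1). Trained with L1 loss and Adam.

Both use batch size 64 and a scheduled learning rate: 0.05 initially,
divided by ten every 200 epochs. Training stops when the monitored loss has
been stable for a patience window, or at ``max_epochs``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .classical import ModelHandle, _class_order
from .types import SpectraDataset


class TrainingError(RuntimeError):
    """Raised when the loss diverges (NaN/inf) during training."""


@dataclass(frozen=True)
class CnnTrainingProtocol:
    """Optimisation protocol for either CNN.

    ``loss``/``optimizer`` default to the architecture's native pairing
    (softmax cross-entropy + SGD for CNNC, L1 + Adam for CNNR) when left as
    ``"auto"``. The learning rate starts at ``lr_initial`` and is divided by
    ``lr_decay_factor`` every ``lr_decay_every`` epochs. Early stopping:
    training ends once the validation loss has not improved by more than
    ``min_delta`` for ``patience`` consecutive epochs.
    """

    loss: str = "auto"  # softmax_cross_entropy | l1 | auto
    optimizer: str = "auto"  # sgd | adam | auto
    batch_size: int = 64
    lr_initial: float = 0.05
    lr_decay_every: int = 200
    lr_decay_factor: float = 10.0
    max_epochs: int = 600
    patience: int = 100
    min_delta: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.lr_initial <= 0:
            raise ValueError("lr_initial must be positive")

    def lr_at(self, epoch: int) -> float:
        return self.lr_initial / self.lr_decay_factor ** (epoch // self.lr_decay_every)


def _check_length(n_wavelengths: int):
    if n_wavelengths < 8:
        raise ValueError(
            f"input length {n_wavelengths} too short: two pooling stages need >= 8"
        )


def build_cnnc(
    n_wavelengths: int, n_classes: int, dropout: float = 0.5, seed: int = 0
) -> ModelHandle:
    """Build the classification CNN (filters 16, kernel 3, stride 1)."""
    _check_length(n_wavelengths)
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    l1 = n_wavelengths // 2
    l2 = l1 // 2
    layers = [
        nn.Conv1d(1, 16, 3),
        nn.ReLU(),
        nn.MaxPool1d(2),
        nn.BatchNorm(16),
        nn.Conv1d(16, 16, 3),
        nn.ReLU(),
        nn.MaxPool1d(2),
        nn.BatchNorm(16),
        nn.Flatten(),
        nn.Dense(16 * l2, 64),
        nn.BatchNorm(64),
        nn.Dropout(dropout),
        nn.Dense(64, n_classes),
    ]
    net = nn.Network(layers, n_wavelengths, n_classes)
    net.init_params(seed)
    return ModelHandle(
        "cnnc",
        net,
        {
            "conv": {"filters": 16, "kernel_size": 3, "stride": 1},
            "n_conv_blocks": 2,
            "dense": 64,
            "dropout": dropout,
            "n_classes": n_classes,
            "n_parameters": net.n_parameters,
        },
        {"trained": False, "init_seed": seed},
    )


def build_cnnr(n_wavelengths: int, seed: int = 0) -> ModelHandle:
    """Build the regression CNN (filters 32, kernel 3, stride 1)."""
    _check_length(n_wavelengths)
    layers = [
        nn.BatchNorm(1),
        nn.Conv1d(1, 32, 3),
        nn.ReLU(),
        nn.BatchNorm(32),
        nn.Conv1d(32, 32, 3),
        nn.ReLU(),
        nn.BatchNorm(32),
        nn.Flatten(),
        nn.Dense(32 * n_wavelengths, 64),
        nn.Dense(64, 16),
        nn.Dense(16, 1),
    ]
    net = nn.Network(layers, n_wavelengths, 1)
    net.init_params(seed)
    return ModelHandle(
        "cnnr",
        net,
        {
            "conv": {"filters": 32, "kernel_size": 3, "stride": 1},
            "n_conv_blocks": 2,
            "dense": (64, 16),
            "n_parameters": net.n_parameters,
        },
        {"trained": False, "init_seed": seed},
    )


def cnnc_parameter_count(n_wavelengths: int, n_classes: int) -> int:
    """Closed-form parameter count of the classification architecture."""
    l2 = (n_wavelengths // 2) // 2
    conv1 = 16 * 1 * 3 + 16
    conv2 = 16 * 16 * 3 + 16
    bns = 2 * 16 + 2 * 16 + 2 * 64
    d1 = 16 * l2 * 64 + 64
    d2 = 64 * n_classes + n_classes
    return conv1 + conv2 + bns + d1 + d2


def cnnr_parameter_count(n_wavelengths: int) -> int:
    """Closed-form parameter count of the regression architecture."""
    conv1 = 32 * 1 * 3 + 32
    conv2 = 32 * 32 * 3 + 32
    bns = 2 * 1 + 2 * 32 + 2 * 32
    d = (32 * n_wavelengths * 64 + 64) + (64 * 16 + 16) + (16 * 1 + 1)
    return conv1 + conv2 + bns + d


def _resolve_protocol(kind: str, protocol: CnnTrainingProtocol):
    loss = protocol.loss
    opt = protocol.optimizer
    if loss == "auto":
        loss = "softmax_cross_entropy" if kind == "cnnc" else "l1"
    if opt == "auto":
        opt = "sgd" if kind == "cnnc" else "adam"
    return loss, opt


def train_cnn(
    h: ModelHandle,
    train: SpectraDataset,
    val: SpectraDataset | None = None,
    protocol: CnnTrainingProtocol | None = None,
) -> ModelHandle:
    """Train a built CNN handle in place; returns it with a loss history.

    Parameters are (re-)initialised from ``protocol.seed`` so a fixed seed
    plus fixed data reproduces the loss history bit for bit. The recorded
    history has one row per epoch: train loss, validation loss and the
    scheduled learning rate.
    """
    protocol = protocol or CnnTrainingProtocol()
    net: nn.Network = h.model
    if val is not None and not np.array_equal(val.wavelengths_nm, train.wavelengths_nm):
        raise ValueError("train and validation splits must share one wavelength axis")
    loss_name, opt_name = _resolve_protocol(h.kind, protocol)
    Xtr = train.spectra.astype(np.float32)
    if h.kind == "cnnc":
        classes = _class_order(train.level)
        if len(classes) < 2:
            raise ValueError("classification training needs >= 2 classes")
        if len(classes) != net.n_outputs:
            raise ValueError(
                f"network built for {net.n_outputs} classes, data has {len(classes)}"
            )
        idx = {c: i for i, c in enumerate(classes)}
        ytr = np.array([idx[c] for c in train.level], dtype=int)
        yval = (
            np.array([idx[c] for c in val.level], dtype=int) if val is not None else None
        )
        h.classes = classes
    else:
        ytr = train.lnc.astype(np.float32)
        if np.any(np.isnan(ytr)):
            raise ValueError("regression training requires lnc on every sample")
        yval = val.lnc.astype(np.float32) if val is not None else None
    Xval = val.spectra.astype(np.float32) if val is not None else None

    net.init_params(protocol.seed)
    loss_fn = nn.SoftmaxCrossEntropy() if loss_name == "softmax_cross_entropy" else nn.L1Loss()
    params = net.parameters()
    optimizer = nn.SGD(params) if opt_name == "sgd" else nn.Adam(params)
    shuffle_rng = np.random.default_rng((protocol.seed, 7))

    history = {"epoch": [], "train_loss": [], "val_loss": [], "lr": []}
    best = np.inf
    wait = 0
    n = Xtr.shape[0]
    for epoch in range(protocol.max_epochs):
        lr = protocol.lr_at(epoch)
        perm = shuffle_rng.permutation(n)
        total = 0.0
        for start in range(0, n, protocol.batch_size):
            sel = perm[start : start + protocol.batch_size]
            out = net.forward(Xtr[sel], training=True)
            loss = loss_fn.forward(out, ytr[sel])
            if not np.isfinite(loss):
                raise TrainingError(f"loss diverged at epoch {epoch}")
            net.backward(loss_fn.backward())
            optimizer.step(lr)
            total += loss * len(sel)
        train_loss = total / n
        if Xval is not None:
            out = _batched_forward(net, Xval)
            val_loss = (
                nn.SoftmaxCrossEntropy().forward(out, yval)
                if loss_name == "softmax_cross_entropy"
                else nn.L1Loss().forward(out, yval)
            )
        else:
            val_loss = train_loss
        history["epoch"].append(epoch)
        history["train_loss"].append(float(train_loss))
        history["val_loss"].append(float(val_loss))
        history["lr"].append(float(lr))
        if val_loss < best - protocol.min_delta:
            best = val_loss
            wait = 0
        else:
            wait += 1
            if wait >= protocol.patience:
                break
    h.meta.update(
        {
            "trained": True,
            "history": history,
            "protocol": {**asdict(protocol), "loss": loss_name, "optimizer": opt_name},
            "n_epochs_run": len(history["epoch"]),
        }
    )
    return h


def _batched_forward(net: nn.Network, X: np.ndarray, batch: int = 512) -> np.ndarray:
    outs = [net.forward(X[s : s + batch], training=False) for s in range(0, len(X), batch)]
    return np.concatenate(outs, axis=0)


def predict_cnn(h: ModelHandle, ds: SpectraDataset) -> np.ndarray:
    """Predict levels (CNNC) or LNC in g/kg (CNNR) in inference mode."""
    if not h.meta.get("trained", False):
        raise ValueError("model is not trained")
    out = _batched_forward(h.model, ds.spectra.astype(np.float32))
    if h.kind == "cnnc":
        return np.asarray([h.classes[i] for i in np.argmax(out, axis=1)], dtype=object)
    return out.ravel().astype(float)


def predict_proba_cnn(h: ModelHandle, ds: SpectraDataset) -> np.ndarray:
    """Softmax class probabilities of a trained CNNC (rows sum to 1)."""
    if h.kind != "cnnc":
        raise ValueError("probabilities are defined for the classification CNN only")
    if not h.meta.get("trained", False):
        raise ValueError("model is not trained")
    return nn.softmax(_batched_forward(h.model, ds.spectra.astype(np.float32)))
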