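"""Classical chemometric models: PLS-DA, PLSR, and RBF-SVM with grid search.

PLS-DA is PLS regression on a one-hot class-indicator matrix with an argmax
decision; PLSR is PLS1 on the nitrogen concentration. The number of latent
variables is tuned by five-fold cross-validation (accuracy for
classification, RMSE for regression) when not fixed. The SVMs use an RBF
kernel with C and gamma searched exhaustively over integer powers of two
from 2^-8 to 2^8 under five-fold cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC, SVR

from .types import LEVELS, SpectraDataset

FORMAT_VERSION = 1


@dataclass(frozen=True)
class PlsConfig:
    """Latent-variable settings for PLS-DA / PLSR.

    ``n_latent_variables=None`` means "choose by 5-fold CV" over
    ``1..max_latent_variables`` (capped by the data's rank limit).
    """

    max_latent_variables: int = 20
    n_latent_variables: Optional[int] = None
    cv_folds: int = 5
    seed: int = 0


@dataclass(frozen=True)
class SvmGridConfig:
    """RBF-SVM grid: C and gamma over 2^-8 .. 2^8, five-fold CV."""

    c_exponents: tuple = tuple(range(-8, 9))
    g_exponents: tuple = tuple(range(-8, 9))
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if not self.c_exponents or not self.g_exponents:
            raise ValueError("grids must be nonempty")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    def grid(self):
        """Enumerate every (C, gamma) pair, C-major, ascending."""
        return [
            (2.0**ce, 2.0**ge)
            for ce in sorted(self.c_exponents)
            for ge in sorted(self.g_exponents)
        ]


@dataclass
class ModelHandle:
    """A fitted model plus its chosen hyperparameters and CV metadata."""

    kind: str  # plsda | plsr | svc | svr | cnnc | cnnr
    model: object
    hyperparams: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)
    classes: Optional[tuple] = None
    format_version: int = FORMAT_VERSION

    @property
    def is_classifier(self) -> bool:
        return self.kind in ("plsda", "svc", "cnnc")


def _one_hot(labels: np.ndarray, classes: tuple) -> np.ndarray:
    idx = {c: i for i, c in enumerate(classes)}
    Y = np.zeros((labels.size, len(classes)))
    for i, lab in enumerate(labels):
        Y[i, idx[lab]] = 1.0
    return Y


def _class_order(labels: np.ndarray) -> tuple:
    uniq = list(dict.fromkeys(labels))
    known = [c for c in LEVELS if c in uniq]
    other = sorted(c for c in uniq if c not in LEVELS)
    return tuple(known + other)


def _max_lv(n_samples: int, n_features: int, cap: int) -> int:
    return max(1, min(cap, n_samples - 1, n_features))


def fit_plsda(train: SpectraDataset, cfg: PlsConfig | None = None) -> ModelHandle:
    """PLS-DA: one-hot indicator PLS with argmax decision."""
    cfg = cfg or PlsConfig()
    X = train.spectra
    y = train.level
    classes = _class_order(y)
    if len(classes) < 2:
        raise ValueError("PLS-DA needs at least two classes in the training set")
    Y = _one_hot(y, classes)
    lv_cap = _max_lv(X.shape[0], X.shape[1], cfg.max_latent_variables)
    cv_scores = {}
    if cfg.n_latent_variables is None:
        skf = StratifiedKFold(cfg.cv_folds, shuffle=True, random_state=cfg.seed)
        folds = list(skf.split(X, y))
        for lv in range(1, lv_cap + 1):
            correct = 0
            for tr, te in folds:
                m = PLSRegression(n_components=min(lv, len(tr) - 1), scale=False)
                m.fit(X[tr], Y[tr])
                pred = np.argmax(m.predict(X[te]), axis=1)
                correct += int(np.sum(pred == np.argmax(Y[te], axis=1)))
            cv_scores[lv] = correct / X.shape[0]
        n_lv = max(cv_scores, key=lambda k: (cv_scores[k], -k))
    else:
        n_lv = min(cfg.n_latent_variables, lv_cap)
    model = PLSRegression(n_components=n_lv, scale=False)
    model.fit(X, Y)
    return ModelHandle(
        "plsda",
        model,
        {"n_latent_variables": n_lv},
        {"seed": cfg.seed, "cv_accuracy": cv_scores},
        classes=classes,
    )


def predict_plsda(h: ModelHandle, ds: SpectraDataset) -> np.ndarray:
    scores = h.model.predict(ds.spectra)
    return np.asarray([h.classes[i] for i in np.argmax(scores, axis=1)], dtype=object)


def fit_plsr(train: SpectraDataset, cfg: PlsConfig | None = None) -> ModelHandle:
    """PLS1 regression of LNC on the spectra; exposes the coefficient curve."""
    cfg = cfg or PlsConfig()
    X = train.spectra
    y = train.lnc
    if np.any(np.isnan(y)):
        raise ValueError("PLSR requires lnc on every training sample")
    lv_cap = _max_lv(X.shape[0], X.shape[1], cfg.max_latent_variables)
    cv_scores = {}
    if cfg.n_latent_variables is None:
        kf = KFold(cfg.cv_folds, shuffle=True, random_state=cfg.seed)
        folds = list(kf.split(X))
        for lv in range(1, lv_cap + 1):
            sse = 0.0
            for tr, te in folds:
                m = PLSRegression(n_components=min(lv, len(tr) - 1), scale=False)
                m.fit(X[tr], y[tr])
                sse += float(np.sum((m.predict(X[te]).ravel() - y[te]) ** 2))
            cv_scores[lv] = float(np.sqrt(sse / X.shape[0]))
        n_lv = min(cv_scores, key=lambda k: (cv_scores[k], k))
    else:
        n_lv = min(cfg.n_latent_variables, lv_cap)
    model = PLSRegression(n_components=n_lv, scale=False)
    model.fit(X, y)
    return ModelHandle(
        "plsr",
        model,
        {"n_latent_variables": n_lv},
        {"seed": cfg.seed, "cv_rmse": cv_scores},
    )


def predict_plsr(h: ModelHandle, ds: SpectraDataset) -> np.ndarray:
    return h.model.predict(ds.spectra).ravel()


def pls_coefficients(h: ModelHandle) -> np.ndarray:
    """Per-wavelength regression coefficients of a fitted PLS model.

    For PLS-DA (multi-response) the per-class coefficient of largest
    magnitude is returned at each wavelength, keeping its sign, so the
    result is a single signed curve over the axis.
    """
    B = np.asarray(h.model.coef_)  # sklearn >=1.1: (n_targets, n_features)
    if B.ndim == 1:
        return B
    if B.shape[0] == 1:
        return B[0]
    pick = np.argmax(np.abs(B), axis=0)
    return B[pick, np.arange(B.shape[1])]


def fit_svm(
    train: SpectraDataset, task: str = "classification", cfg: SvmGridConfig | None = None
) -> ModelHandle:
    """RBF-SVM with exhaustive (C, gamma) grid search under 5-fold CV.

    Winner is the best mean CV score (accuracy for classification, negative
    RMSE for regression); ties resolve to the smallest C then smallest
    gamma. The winning pair is refit on the full training split.
    """
    cfg = cfg or SvmGridConfig()
    X = train.spectra
    if task == "classification":
        y = train.level
        classes = _class_order(y)
        if len(classes) < 2:
            raise ValueError("SVC needs at least two classes")
        splitter = StratifiedKFold(cfg.cv_folds, shuffle=True, random_state=cfg.seed)
        folds = list(splitter.split(X, y))
    elif task == "regression":
        y = train.lnc
        if np.any(np.isnan(y)):
            raise ValueError("SVR requires lnc on every training sample")
        classes = None
        splitter = KFold(cfg.cv_folds, shuffle=True, random_state=cfg.seed)
        folds = list(splitter.split(X))
    else:
        raise ValueError(f"unknown task {task!r}")

    best = (-np.inf, None)
    cv_table = []
    for C, g in cfg.grid():
        score = 0.0
        for tr, te in folds:
            if task == "classification":
                m = SVC(kernel="rbf", C=C, gamma=g)
                m.fit(X[tr], y[tr])
                score += float(np.mean(m.predict(X[te]) == y[te])) * len(te)
            else:
                m = SVR(kernel="rbf", C=C, gamma=g)
                m.fit(X[tr], y[tr])
                score -= float(np.sum((m.predict(X[te]) - y[te]) ** 2))
        score /= X.shape[0]
        if task == "regression":
            score = -np.sqrt(-score)
        cv_table.append((C, g, score))
        if score > best[0]:  # strict: earlier (smaller C, then gamma) wins ties
            best = (score, (C, g))
    C, g = best[1]
    model = (SVC if task == "classification" else SVR)(kernel="rbf", C=C, gamma=g)
    model.fit(X, y)
    return ModelHandle(
        "svc" if task == "classification" else "svr",
        model,
        {"C": C, "gamma": g},
        {"seed": cfg.seed, "cv_best_score": best[0], "n_grid": len(cv_table)},
        classes=classes,
    )


def predict_model(h: ModelHandle, ds: SpectraDataset) -> np.ndarray:
    """Dispatch prediction for any classical model handle."""
    if h.kind == "plsda":
        return predict_plsda(h, ds)
    if h.kind == "plsr":
        return predict_plsr(h, ds)
    if h.kind in ("svc", "svr"):
        return h.model.predict(ds.spectra)
    raise ValueError(f"unknown model kind {h.kind!r}")
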