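"""Characteristic-wavelength selection.

Three selectors rank the 2071-variable axis and keep a small subset:

* **random frog** — a reversible-jump-MCMC-flavoured subset search. From the
  current variable subset a candidate of a size drawn around the current one
  is proposed (adding random variables or deleting the least important);
  the candidate replaces the current subset if its cross-validated PLS error
  is lower, otherwise with a small probability proportional to the error
  ratio. Each variable's score is the fraction of iterations whose accepted
  subset contained it; the top-k (default 40) are kept.
* **WPLS** — the local extrema (crests and troughs) of a PLS model's
  regression-coefficient curve, largest |coefficient| first.
* **saliency map** — per-sample absolute gradients of a trained CNN's output
  with respect to the input spectrum; each sample marks its top wavelengths
  and the selection frequency across samples ranks the axis.

Ties are broken by ascending wavelength throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from .classical import _class_order, _one_hot, fit_plsda, fit_plsr, pls_coefficients, PlsConfig
from .types import SpectraDataset


@dataclass
class SelectionResult:
    """Per-wavelength scores plus the chosen subset."""

    method: str  # random_frog | wpls | saliency
    wavelengths_nm: np.ndarray
    scores: np.ndarray
    selected_nm: np.ndarray
    config_echo: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "method": self.method,
            "wavelengths_nm": np.asarray(self.wavelengths_nm).tolist(),
            "scores": np.asarray(self.scores).tolist(),
            "selected_nm": np.asarray(self.selected_nm).tolist(),
            "config_echo": self.config_echo,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SelectionResult":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            d["method"],
            np.asarray(d["wavelengths_nm"], dtype=float),
            np.asarray(d["scores"], dtype=float),
            np.asarray(d["selected_nm"], dtype=float),
            d.get("config_echo", {}),
        )


@dataclass(frozen=True)
class RandomFrogConfig:
    n_iterations: int = 10_000
    init_subset_size: int = 2  # Q0
    subset_variance_factor: float = 0.3  # theta
    accept_prob_factor: float = 0.1  # eta
    inner_lv_max: int = 10
    cv_folds: int = 5
    top_k: int = 40
    candidate_expansion: int = 3  # surplus factor when growing the subset
    seed: int = 0

    def __post_init__(self):
        if self.n_iterations < 10:
            raise ValueError("n_iterations must be >= 10")
        if self.init_subset_size < 1:
            raise ValueError("init_subset_size must be >= 1")
        if not (0.0 < self.accept_prob_factor < 1.0):
            raise ValueError("accept_prob_factor must lie in (0, 1)")
        if self.subset_variance_factor <= 0:
            raise ValueError("subset_variance_factor must be positive")


@dataclass(frozen=True)
class WplsConfig:
    n_latent_variables: Optional[int] = None  # None -> choose by CV
    k: int = 40
    max_latent_variables: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")


@dataclass(frozen=True)
class SaliencyConfig:
    per_sample_top_k: int = 40
    final_top_k: int = 40
    seed: int = 0


def _top_k_by_score(wl: np.ndarray, scores: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k best scores; ties resolve to ascending wavelength."""
    order = np.lexsort((wl, -scores))
    sel = np.sort(order[:k])
    return sel


def _targets(ds: SpectraDataset, task: str):
    if task == "regression":
        y = ds.lnc
        if np.any(np.isnan(y)):
            raise ValueError("regression selection requires lnc on every sample")
        return y, None
    if task == "classification":
        labels = ds.level
        classes = _class_order(labels)
        if len(classes) < 2:
            raise ValueError("classification selection needs >= 2 classes")
        return _one_hot(labels, classes), labels
    raise ValueError(f"unknown task {task!r}")


class _InnerPls:
    """Cached 5-fold CV error and coefficient importance for subsets."""

    def __init__(self, X, Y, labels, task, lv_max, folds, seed):
        self.X, self.Y, self.labels, self.task, self.lv_max = X, Y, labels, task, lv_max
        kf = KFold(folds, shuffle=True, random_state=seed)
        self.folds = list(kf.split(X))

    def _n_comp(self, q, n_train):
        return max(1, min(self.lv_max, q, n_train - 1))

    def cv_error(self, cols: np.ndarray) -> float:
        Xs = self.X[:, cols]
        err = 0.0
        for tr, te in self.folds:
            m = PLSRegression(n_components=self._n_comp(len(cols), len(tr)), scale=False)
            m.fit(Xs[tr], self.Y[tr])
            pred = m.predict(Xs[te])
            if self.task == "classification":
                hit = np.argmax(pred, axis=1) == np.argmax(self.Y[te], axis=1)
                err += float(np.sum(~hit))
            else:
                err += float(np.sum((pred.ravel() - self.Y[te]) ** 2))
        n = self.X.shape[0]
        return err / n if self.task == "classification" else float(np.sqrt(err / n))

    def importance(self, cols: np.ndarray) -> np.ndarray:
        m = PLSRegression(n_components=self._n_comp(len(cols), self.X.shape[0]), scale=False)
        m.fit(self.X[:, cols], self.Y)
        B = np.asarray(m.coef_)
        B = B.reshape(-1, len(cols)) if B.ndim > 1 else B[None, :]
        return np.max(np.abs(B), axis=0)


def random_frog(
    ds: SpectraDataset, task: str = "regression", cfg: RandomFrogConfig | None = None
) -> SelectionResult:
    """Random-frog variable selection with an inner PLS model.

    Scores are selection frequencies over the accepted subsets of
    ``n_iterations`` iterations; ``selected_nm`` is the top-k by frequency.
    Fully reproducible under ``cfg.seed``.
    """
    cfg = cfg or RandomFrogConfig()
    rng = np.random.default_rng(cfg.seed)
    p = ds.n_wavelengths
    Y, labels = _targets(ds, task)
    inner = _InnerPls(
        ds.spectra, Y, labels, task, cfg.inner_lv_max, cfg.cv_folds, cfg.seed
    )
    q0 = min(cfg.init_subset_size, p)
    current = np.sort(rng.choice(p, size=q0, replace=False))
    try:
        err_cur = inner.cv_error(current)
    except Exception as exc:  # noqa: BLE001 - annotate with context
        raise RuntimeError(f"inner model failed on the initial subset: {exc}") from exc
    counts = np.zeros(p, dtype=np.int64)
    all_cols = np.arange(p)
    for it in range(cfg.n_iterations):
        q = len(current)
        q_star = int(round(rng.normal(q, cfg.subset_variance_factor * q)))
        q_star = max(1, min(p, q_star))
        if q_star > q:
            # draw a surplus of random candidates, keep the most important
            pool = np.setdiff1d(all_cols, current, assume_unique=False)
            n_draw = min(cfg.candidate_expansion * (q_star - q), pool.size)
            extra = rng.choice(pool, size=n_draw, replace=False)
            union = np.sort(np.concatenate([current, extra]))
            imp = inner.importance(union)
            keep = np.argsort(-imp, kind="stable")[:q_star]
            candidate = np.sort(union[keep])
        elif q_star < q:
            imp = inner.importance(current)
            keep = np.argsort(-imp, kind="stable")[:q_star]
            candidate = np.sort(current[keep])
        else:
            candidate = current
        if candidate is not current and not np.array_equal(candidate, current):
            try:
                err_cand = inner.cv_error(candidate)
            except Exception as exc:  # noqa: BLE001
                raise RuntimeError(f"inner model failed at iteration {it}: {exc}") from exc
            if err_cand <= err_cur:
                accept = True
            else:
                ratio = err_cur / err_cand if err_cand > 0 else 1.0
                accept = rng.random() < cfg.accept_prob_factor * ratio
            if accept:
                current, err_cur = candidate, err_cand
        counts[current] += 1
    scores = counts / cfg.n_iterations
    k = min(cfg.top_k, p)
    sel = _top_k_by_score(ds.wavelengths_nm, scores, k)
    return SelectionResult(
        "random_frog",
        ds.wavelengths_nm.copy(),
        scores,
        ds.wavelengths_nm[sel],
        {"task": task, **asdict(cfg)},
    )


def local_extrema(values: np.ndarray) -> np.ndarray:
    """Indices of strict local crests and troughs of a curve.

    A point is an extremum when strictly greater (crest) or strictly smaller
    (trough) than both neighbours; a flat plateau that qualifies contributes
    its leftmost point. Endpoints are not extrema.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    out = []
    i = 1
    # collapse equal-valued runs, compare run value against both sides
    run_start = 0
    runs = []  # (start, end_exclusive, value)
    j = 0
    while j < n:
        k = j
        while k + 1 < n and v[k + 1] == v[j]:
            k += 1
        runs.append((j, k + 1, v[j]))
        j = k + 1
    for r in range(1, len(runs) - 1):
        s, e, val = runs[r]
        left = runs[r - 1][2]
        right = runs[r + 1][2]
        if (val > left and val > right) or (val < left and val < right):
            out.append(s)
    return np.asarray(out, dtype=int)


def wpls_select(
    ds: SpectraDataset, cfg: WplsConfig | None = None, task: str = "regression"
) -> SelectionResult:
    """Wavelengths at the crests/troughs of the PLS coefficient curve.

    Fits PLSR (or PLS-DA for classification), locates the local extrema of
    the per-wavelength regression-coefficient curve and returns the ``k``
    extrema of largest magnitude, sorted by wavelength. Scores are
    |coefficient| over the whole axis.
    """
    cfg = cfg or WplsConfig()
    pls_cfg = PlsConfig(
        max_latent_variables=cfg.max_latent_variables,
        n_latent_variables=cfg.n_latent_variables,
        seed=cfg.seed,
    )
    handle = fit_plsr(ds, pls_cfg) if task == "regression" else fit_plsda(ds, pls_cfg)
    coef = pls_coefficients(handle)
    ext = local_extrema(coef)
    echo = {"task": task, "n_latent_variables": handle.hyperparams["n_latent_variables"],
            "k": cfg.k, "n_extrema": int(ext.size), "truncated": False}
    if ext.size == 0:
        sel = np.array([], dtype=int)
        echo["truncated"] = True
    elif cfg.k >= ext.size:
        sel = np.sort(ext)
        if cfg.k > ext.size:
            echo["truncated"] = True
    else:
        order = np.lexsort((ds.wavelengths_nm[ext], -np.abs(coef[ext])))
        sel = np.sort(ext[order[: cfg.k]])
    return SelectionResult(
        "wpls", ds.wavelengths_nm.copy(), np.abs(coef), ds.wavelengths_nm[sel], echo
    )


def saliency_select(
    model, ds: SpectraDataset, cfg: SaliencyConfig | None = None
) -> SelectionResult:
    """Saliency-map selection from a trained CNN.

    For each sample the absolute gradient of the model output (the
    true-class logit for classification, the scalar output for regression)
    with respect to the input spectrum is computed; each sample marks its
    ``per_sample_top_k`` largest-gradient wavelengths, and the score of a
    wavelength is the fraction of samples marking it.
    """
    cfg = cfg or SaliencyConfig()
    net = model.model
    if not model.meta.get("trained", False):
        raise ValueError("saliency requires a trained CNN model")
    if net.input_length != ds.n_wavelengths:
        raise ValueError(
            f"model expects {net.input_length} wavelengths, dataset has {ds.n_wavelengths}"
        )
    if model.kind == "cnnc":
        labels = ds.level
        idx = {c: i for i, c in enumerate(model.classes)}
        units = np.array([idx[lab] for lab in labels], dtype=int)
    else:
        units = None
    grads = net.input_gradient(ds.spectra, units)  # (n, L)
    sal = np.abs(grads)
    p = ds.n_wavelengths
    k_each = min(cfg.per_sample_top_k, p)
    marks = np.zeros(p, dtype=np.int64)
    for row in sal:
        top = np.argpartition(-row, k_each - 1)[:k_each] if k_each < p else np.arange(p)
        marks[top] += 1
    scores = marks / ds.n_samples
    sel = _top_k_by_score(ds.wavelengths_nm, scores, min(cfg.final_top_k, p))
    return SelectionResult(
        "saliency",
        ds.wavelengths_nm.copy(),
        scores,
        ds.wavelengths_nm[sel],
        {"kind": model.kind, **asdict(cfg)},
    )


def subset_dataset(ds: SpectraDataset, selected_nm: Sequence[float]) -> SpectraDataset:
    """Restrict to the selected wavelengths (ascending); metadata untouched."""
    wanted = np.unique(np.asarray(selected_nm, dtype=float))
    pos = np.searchsorted(ds.wavelengths_nm, wanted)
    bad = (pos >= ds.n_wavelengths) | (ds.wavelengths_nm[np.minimum(pos, ds.n_wavelengths - 1)] != wanted)
    if np.any(bad):
        missing = wanted[bad][:5]
        raise ValueError(f"wavelengths not on the axis: {missing.tolist()}")
    return ds.with_columns(pos)


def reduction_percent(n_selected: int, n_total: int) -> float:
    """Percent reduction in variable count, to two decimals."""
    if n_total <= 0 or n_selected < 0 or n_selected > n_total:
        raise ValueError("need 0 <= n_selected <= n_total with n_total > 0")
    return round(100.0 * (1.0 - n_selected / n_total), 2)
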