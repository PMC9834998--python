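"""Metrics, nitrogen-level binning, and identification from predicted LNC.

Classification is scored by accuracy (%) and a low/medium/high confusion
matrix; regression by the coefficient of determination R^2 = 1 - SS_res /
SS_tot (SS_tot about the split's own mean) and RMSE in g/kg. A regression
model can also be used qualitatively: its predicted LNC values are binned
with the same cutpoints as the true values and scored as a classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import LEVELS, SpectraDataset


@dataclass(frozen=True)
class NitrogenLevelScheme:
    """Two LNC cutpoints (g/kg) mapping concentration to low/medium/high.

    Defaults (25.01, 35.0) sit inside the gaps between the observed class
    ranges 14.99-25.00, 25.02-34.96 and 35.02-52.46, so every sample of
    those ranges bins to its class.
    """

    t1: float = 25.01
    t2: float = 35.0

    def __post_init__(self):
        if not self.t1 < self.t2:
            raise ValueError("cutpoints must satisfy t1 < t2")


def bin_lnc(lnc, scheme: NitrogenLevelScheme | None = None):
    """Map LNC (g/kg) to {low, medium, high}: low < t1 <= medium < t2 <= high."""
    scheme = scheme or NitrogenLevelScheme()
    arr = np.asarray(lnc, dtype=float)
    out = np.where(arr < scheme.t1, "low", np.where(arr < scheme.t2, "medium", "high"))
    out = out.astype(object)
    return out if arr.ndim else out.item()


def accuracy(true_levels, pred_levels) -> float:
    """Percent of correctly classified samples."""
    t = np.asarray(true_levels, dtype=object)
    p = np.asarray(pred_levels, dtype=object)
    if t.shape != p.shape or t.size == 0:
        raise ValueError("label vectors must be nonempty and of equal length")
    return float(100.0 * np.mean(t == p))


def confusion(true_levels, pred_levels, classes=LEVELS):
    """Confusion matrix (rows = true, cols = predicted) plus row proportions."""
    t = np.asarray(true_levels, dtype=object)
    p = np.asarray(pred_levels, dtype=object)
    idx = {c: i for i, c in enumerate(classes)}
    M = np.zeros((len(classes), len(classes)), dtype=int)
    for ti, pi in zip(t, p):
        M[idx[ti], idx[pi]] += 1
    rows = M.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(rows > 0, M / np.maximum(rows, 1), 0.0)
    return M, prop


def r2_rmse(true_lnc, pred_lnc):
    """(R^2, RMSE): R^2 = 1 - SS_res/SS_tot; RMSE in the data's units."""
    y = np.asarray(true_lnc, dtype=float)
    yhat = np.asarray(pred_lnc, dtype=float)
    if y.shape != yhat.shape or y.size == 0:
        raise ValueError("vectors must be nonempty and of equal length")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined: true values are constant")
    ss_res = float(np.sum((y - yhat) ** 2))
    rmse = float(np.sqrt(np.mean((y - yhat) ** 2)))
    return 1.0 - ss_res / ss_tot, rmse


def _splits_present(ds: SpectraDataset):
    return [s for s in ("cal", "val", "pre") if np.any(ds.split == s)]


def evaluate_classifier(predict_fn, ds: SpectraDataset) -> pd.DataFrame:
    """Per-split accuracy and confusion for any ``predict(ds) -> levels``."""
    rows = []
    for split in _splits_present(ds):
        sub = ds.subset_split(split)
        pred = predict_fn(sub)
        M, _ = confusion(sub.level, pred)
        rows.append(
            {"split": split, "n": sub.n_samples, "accuracy": accuracy(sub.level, pred),
             "confusion": M}
        )
    return pd.DataFrame(rows)


def evaluate_regressor(predict_fn, ds: SpectraDataset) -> pd.DataFrame:
    """Per-split R^2 and RMSE for any ``predict(ds) -> lnc`` callable."""
    rows = []
    for split in _splits_present(ds):
        sub = ds.subset_split(split)
        r2, rmse = r2_rmse(sub.lnc, predict_fn(sub))
        rows.append({"split": split, "n": sub.n_samples, "r2": r2, "rmse": rmse})
    return pd.DataFrame(rows)


def identify_from_regression(
    predict_fn, ds: SpectraDataset, scheme: NitrogenLevelScheme | None = None
) -> pd.DataFrame:
    """Classify by binning regression predictions with the level cutpoints.

    Predicted LNC values are binned with the same scheme as the true values;
    per-split accuracy and confusion of the induced classification are
    reported.
    """
    scheme = scheme or NitrogenLevelScheme()
    rows = []
    for split in _splits_present(ds):
        sub = ds.subset_split(split)
        pred_levels = bin_lnc(predict_fn(sub), scheme)
        true_levels = bin_lnc(sub.lnc, scheme)
        M, _ = confusion(true_levels, pred_levels)
        rows.append(
            {
                "split": split,
                "n": sub.n_samples,
                "accuracy": accuracy(true_levels, pred_levels),
                "confusion": M,
            }
        )
    return pd.DataFrame(rows)
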