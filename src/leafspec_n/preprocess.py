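"""First-derivative + standard normal variate (FD+SNV) preprocessing.

The chain applied before all modelling: a Savitzky-Golay first derivative
with respect to wavelength removes additive baseline, then a per-spectrum
standard normal variate transform (centre, divide by the sample standard
deviation) removes multiplicative scatter. Order is fixed: FD then SNV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .types import DegenerateSpectrumError, SpectraDataset, Spectrum


@dataclass(frozen=True)
class PreprocessConfig:
    """Savitzky-Golay derivative settings for the FD step.

    ``derivative_window`` is in grid points (odd), ``derivative_polyorder``
    the fitted polynomial degree. ``mode`` selects the estimator:
    ``"savgol"`` (default) or ``"diff"``, a plain central-difference
    cross-check.
    """

    derivative_window: int = 7
    derivative_polyorder: int = 2
    mode: str = "savgol"

    def __post_init__(self):
        if self.derivative_window % 2 == 0:
            raise ValueError("derivative_window must be odd")
        if self.derivative_window < self.derivative_polyorder + 1:
            raise ValueError("derivative_window must be >= polyorder + 1")
        if self.mode not in ("savgol", "diff"):
            raise ValueError(f"unknown derivative mode {self.mode!r}")


def _fd_matrix(X: np.ndarray, wl: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    if cfg.mode == "diff":
        return np.gradient(X, wl, axis=-1)
    if X.shape[-1] < cfg.derivative_window:
        raise ValueError(
            f"spectrum length {X.shape[-1]} below derivative window {cfg.derivative_window}"
        )
    delta = float(np.mean(np.diff(wl)))
    # mode="interp" fits the edge polynomial, keeping output length equal to input
    return savgol_filter(
        X,
        window_length=cfg.derivative_window,
        polyorder=cfg.derivative_polyorder,
        deriv=1,
        delta=delta,
        axis=-1,
        mode="interp",
    )


def first_derivative(s: Spectrum, cfg: PreprocessConfig | None = None) -> Spectrum:
    """Savitzky-Golay first derivative of reflectance w.r.t. wavelength (nm)."""
    cfg = cfg or PreprocessConfig()
    d = _fd_matrix(s.reflectance[None, :], s.wavelengths_nm, cfg)[0]
    return Spectrum(s.wavelengths_nm, d)


def _snv_matrix(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=-1, keepdims=True)
    sd = X.std(axis=-1, ddof=1, keepdims=True)
    if np.any(sd <= 0):
        bad = int(np.flatnonzero(sd.ravel() <= 0)[0])
        raise DegenerateSpectrumError(
            f"zero-variance spectrum (row {bad}): SNV undefined"
        )
    return (X - mu) / sd


def snv(s: Spectrum) -> Spectrum:
    """Standard normal variate: centre and scale to unit sample sd (n-1)."""
    return Spectrum(s.wavelengths_nm, _snv_matrix(s.reflectance[None, :])[0])


def fd_snv(ds: SpectraDataset, cfg: PreprocessConfig | None = None) -> SpectraDataset:
    """Row-wise first derivative then SNV; metadata untouched."""
    cfg = cfg or PreprocessConfig()
    flat = np.ptp(ds.spectra, axis=1) == 0
    if np.any(flat):
        raise DegenerateSpectrumError(
            f"constant spectrum (row {int(np.flatnonzero(flat)[0])}): FD+SNV undefined"
        )
    X = _fd_matrix(ds.spectra, ds.wavelengths_nm, cfg)
    X = _snv_matrix(X)
    return SpectraDataset(X, ds.wavelengths_nm, ds.meta.copy())
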