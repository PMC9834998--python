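"""Core containers: single spectra, spectra datasets, split specifications.

A :class:`SpectraDataset` is a wide reflectance matrix (rows = leaf samples,
columns = wavelengths on a shared, strictly increasing nm axis) together with
per-sample metadata: measured leaf nitrogen concentration (LNC, g/kg dry
mass), the three-level nitrogen category, measurement environment, cultivar,
and a calibration/validation/prediction split tag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

LEVELS = ("low", "medium", "high")
SPLITS = ("cal", "val", "pre")
#: metadata column names reserved in the wide-CSV layout; every other column
#: is interpreted as a wavelength in nm.
RESERVED_COLUMNS = ("lnc", "level", "environment", "cultivar", "split")


class AxisMismatchError(ValueError):
    """Spectra do not share one wavelength axis."""


class EmptyInputError(ValueError):
    """An operation received no spectra."""


class DegenerateSpectrumError(ValueError):
    """A spectrum has zero variance where a spread is required."""


@dataclass(frozen=True)
class Spectrum:
    """A single reflectance spectrum on a strictly increasing nm axis."""

    wavelengths_nm: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self):
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        refl = np.asarray(self.reflectance, dtype=float)
        if wl.ndim != 1 or refl.ndim != 1:
            raise ValueError("wavelengths and reflectance must be 1-D")
        if wl.shape != refl.shape:
            raise ValueError(
                f"length mismatch: {wl.size} wavelengths vs {refl.size} reflectance values"
            )
        if wl.size == 0:
            raise EmptyInputError("empty spectrum")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(refl)):
            raise ValueError("reflectance contains non-finite values")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "reflectance", refl)

    def __len__(self) -> int:
        return self.wavelengths_nm.size


def _default_meta(n: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lnc": np.full(n, np.nan),
            "level": pd.array([pd.NA] * n, dtype="string"),
            "environment": pd.array(["lab"] * n, dtype="string"),
            "cultivar": pd.array([pd.NA] * n, dtype="string"),
            "split": pd.array(["unassigned"] * n, dtype="string"),
        }
    )


@dataclass
class SpectraDataset:
    """Aligned reflectance matrix plus per-sample metadata.

    Parameters
    ----------
    spectra
        ``(n_samples, n_wavelengths)`` reflectance matrix.
    wavelengths_nm
        Shared wavelength axis in nm, strictly increasing.
    meta
        Per-sample metadata with the reserved columns ``lnc`` (g/kg),
        ``level`` (low/medium/high), ``environment`` (lab/field),
        ``cultivar`` and ``split`` (cal/val/pre/unassigned). Missing columns
        are filled with defaults.
    """

    spectra: np.ndarray
    wavelengths_nm: np.ndarray
    meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        X = np.asarray(self.spectra, dtype=float)
        if X.ndim != 2:
            raise ValueError("spectra must be a 2-D matrix")
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        if wl.ndim != 1 or wl.size != X.shape[1]:
            raise ValueError("wavelength axis length must equal the number of columns")
        if wl.size and not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.meta is None:
            meta = _default_meta(X.shape[0])
        else:
            meta = self.meta.reset_index(drop=True).copy()
            for col, default in zip(
                RESERVED_COLUMNS, (np.nan, pd.NA, "lab", pd.NA, "unassigned")
            ):
                if col not in meta.columns:
                    meta[col] = default
        if len(meta) != X.shape[0]:
            raise ValueError(
                f"metadata rows ({len(meta)}) do not match spectra rows ({X.shape[0]})"
            )
        lnc = pd.to_numeric(meta["lnc"], errors="coerce").to_numpy(dtype=float)
        if np.any(lnc[~np.isnan(lnc)] <= 0):
            raise ValueError("lnc must be positive where present")
        self.spectra = X
        self.wavelengths_nm = wl
        self.meta = meta

    @property
    def n_samples(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.spectra.shape[1]

    @property
    def lnc(self) -> np.ndarray:
        return pd.to_numeric(self.meta["lnc"], errors="coerce").to_numpy(dtype=float)

    @property
    def level(self) -> np.ndarray:
        return self.meta["level"].to_numpy(dtype=object)

    @property
    def split(self) -> np.ndarray:
        return self.meta["split"].to_numpy(dtype=object)

    def row(self, i: int) -> Spectrum:
        return Spectrum(self.wavelengths_nm, self.spectra[i])

    def take(self, idx: Sequence[int] | np.ndarray) -> "SpectraDataset":
        idx = np.asarray(idx, dtype=int)
        return SpectraDataset(
            self.spectra[idx], self.wavelengths_nm, self.meta.iloc[idx].reset_index(drop=True)
        )

    def subset_split(self, split: str) -> "SpectraDataset":
        mask = self.split == split
        return self.take(np.flatnonzero(mask))

    def with_columns(self, col_idx: np.ndarray) -> "SpectraDataset":
        col_idx = np.asarray(col_idx, dtype=int)
        return SpectraDataset(
            self.spectra[:, col_idx], self.wavelengths_nm[col_idx], self.meta.copy()
        )


@dataclass(frozen=True)
class SplitSpec:
    """Stratified cal/val/pre split proportions with a seed.

    Per stratum of size n the counts are ``cal = floor(f_cal*n)``,
    ``val = round(f_val*n)`` and ``pre`` the remainder; assignment within the
    stratum is random under ``seed``.
    """

    fractions: tuple = (0.6, 0.2, 0.2)
    stratify_by_level: bool = True
    seed: int = 0

    def __post_init__(self):
        f = tuple(float(x) for x in self.fractions)
        if len(f) != 3 or any(not (0.0 < x < 1.0) for x in f):
            raise ValueError("fractions must be three values each in (0, 1)")
        if abs(sum(f) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {sum(f)}")
        object.__setattr__(self, "fractions", f)
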