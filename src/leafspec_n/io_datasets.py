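"""Reading, writing, assembling and splitting spectra datasets.

Implements the acquisition-averaging protocol (five scans per leaf region,
three regions per leaf), trimming to the 430-2500 nm working range, the
stratified calibration/validation/prediction split, and a wide-CSV
round-trip format (one row per sample; wavelength columns named by nm;
metadata under reserved names).
"""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    AxisMismatchError,
    EmptyInputError,
    RESERVED_COLUMNS,
    SpectraDataset,
    SplitSpec,
    Spectrum,
)


class ParseError(ValueError):
    """A CSV cell or row could not be interpreted."""


def _mean_spectrum(spectra: Sequence[Spectrum]) -> Spectrum:
    if len(spectra) == 0:
        raise EmptyInputError("no spectra to average")
    axis = spectra[0].wavelengths_nm
    for s in spectra[1:]:
        if s.wavelengths_nm.shape != axis.shape or not np.array_equal(
            s.wavelengths_nm, axis
        ):
            raise AxisMismatchError("spectra do not share one wavelength axis")
    stacked = np.stack([s.reflectance for s in spectra])
    return Spectrum(axis, stacked.mean(axis=0))


def average_scans(scans: Sequence[Spectrum]) -> Spectrum:
    """Average repeated instrument scans of one leaf region.

    The acquisition protocol records five scans per measurement; their
    element-wise arithmetic mean is the region spectrum.
    """
    return _mean_spectrum(scans)


def average_regions(region_spectra: Sequence[Spectrum]) -> Spectrum:
    """Average the (typically three) region spectra into one leaf spectrum."""
    return _mean_spectrum(region_spectra)


def trim_wavelengths(ds: SpectraDataset, lo_nm: float, hi_nm: float) -> SpectraDataset:
    """Restrict the dataset to wavelengths in ``[lo_nm, hi_nm]`` inclusive.

    On a 1-nm grid, trimming to 430-2500 nm leaves 2071 variables.
    """
    if lo_nm >= hi_nm:
        raise ValueError(f"lo_nm ({lo_nm}) must be below hi_nm ({hi_nm})")
    mask = (ds.wavelengths_nm >= lo_nm) & (ds.wavelengths_nm <= hi_nm)
    if not mask.any():
        raise ValueError(f"no wavelengths in [{lo_nm}, {hi_nm}]")
    return ds.with_columns(np.flatnonzero(mask))


def _split_counts(n: int, fractions: Sequence[float]) -> tuple:
    f_cal, f_val, _ = fractions
    n_cal = int(np.floor(f_cal * n))
    n_val = int(round(f_val * n))
    n_val = min(n_val, n - n_cal)
    return n_cal, n_val, n - n_cal - n_val


def split_dataset(ds: SpectraDataset, spec: SplitSpec) -> SpectraDataset:
    """Assign cal/val/pre split tags, stratified by nitrogen level.

    Within each stratum of size n the counts are floor(f_cal*n) calibration,
    round(f_val*n) validation and the remainder prediction samples; which
    sample lands where is a seeded random permutation. With 60/20/20
    fractions this reproduces the canonical per-class triples 138/46/46,
    360/120/121 and 341/114/114 for strata of 230, 601 and 569 samples.
    """
    rng = np.random.default_rng(spec.seed)
    meta = ds.meta.copy()
    if spec.stratify_by_level:
        levels = meta["level"].to_numpy(dtype=object)
        if pd.isna(levels).any():
            raise ValueError("stratified split requires levels on every sample")
        strata = [np.flatnonzero(levels == lv) for lv in pd.unique(levels)]
    else:
        strata = [np.arange(ds.n_samples)]
    tags = np.empty(ds.n_samples, dtype=object)
    for idx in strata:
        n_cal, n_val, n_pre = _split_counts(len(idx), spec.fractions)
        perm = rng.permutation(idx)
        tags[perm[:n_cal]] = "cal"
        tags[perm[n_cal : n_cal + n_val]] = "val"
        tags[perm[n_cal + n_val :]] = "pre"
    meta["split"] = pd.array(tags, dtype="string")
    return SpectraDataset(ds.spectra, ds.wavelengths_nm, meta)


def write_spectra_csv(ds: SpectraDataset, path) -> None:
    """Write the dataset as a wide CSV (wavelength columns named by nm)."""
    wl_cols = {}
    for j, wl in enumerate(ds.wavelengths_nm):
        name = f"{int(wl)}" if float(wl).is_integer() else repr(float(wl))
        wl_cols[name] = ds.spectra[:, j]
    out = pd.concat(
        [ds.meta[list(RESERVED_COLUMNS)].reset_index(drop=True), pd.DataFrame(wl_cols)],
        axis=1,
    )
    out.to_csv(path, index=False, float_format="%.17g")


def read_spectra_csv(path, interpolate_to_1nm: bool = False) -> SpectraDataset:
    """Read a wide spectra CSV.

    Columns named ``lnc``, ``level``, ``environment``, ``cultivar`` and
    ``split`` are metadata; every other column name must parse as a
    wavelength in nm. With ``interpolate_to_1nm`` the spectra are linearly
    resampled onto an integer 1-nm grid spanning the file's axis.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas message varies
        raise ParseError(str(exc)) from exc
    meta_cols = [c for c in RESERVED_COLUMNS if c in df.columns]
    wl_cols = [c for c in df.columns if c not in RESERVED_COLUMNS]
    try:
        wl = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise ParseError(f"non-wavelength column name: {exc}") from exc
    order = np.argsort(wl)
    wl = wl[order]
    wl_cols = [wl_cols[i] for i in order]
    X = df[wl_cols].to_numpy()
    if X.dtype == object:
        for i in range(len(df)):
            for j, c in enumerate(wl_cols):
                try:
                    float(df[c].iloc[i])
                except (TypeError, ValueError):
                    raise ParseError(f"non-numeric cell at row {i}, column {c!r}")
        X = X.astype(float)
    meta = df[meta_cols].copy() if meta_cols else None
    if interpolate_to_1nm:
        grid = np.arange(np.ceil(wl[0]), np.floor(wl[-1]) + 1.0)
        X = np.vstack([np.interp(grid, wl, row) for row in X])
        wl = grid
    return SpectraDataset(X, wl, meta)


def summarize(ds: SpectraDataset) -> pd.DataFrame:
    """Per-level sample counts, LNC mean/sd, and split composition."""
    meta = ds.meta
    rows = []
    for lv, grp in meta.groupby("level", dropna=False):
        lnc = pd.to_numeric(grp["lnc"], errors="coerce")
        counts = grp["split"].value_counts()
        rows.append(
            {
                "level": lv,
                "n": len(grp),
                "lnc_mean": lnc.mean(),
                "lnc_sd": lnc.std(ddof=1),
                "n_cal": int(counts.get("cal", 0)),
                "n_val": int(counts.get("val", 0)),
                "n_pre": int(counts.get("pre", 0)),
            }
        )
    return pd.DataFrame(rows)
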