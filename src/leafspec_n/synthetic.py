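"""Synthetic cotton-leaf reflectance generator.

A phenomenological (Gaussian band algebra, not radiative-transfer) model of
430-2500 nm leaf reflectance with the statistical structure the pipeline
assumes:

* a smooth baseline with the canonical green-leaf shape — local peaks near
  550, 1650, 1820 and 2225 nm, valleys near 670, 1432 and 1950 nm, a red
  edge after 700 nm and a high NIR plateau between 775 and 1300 nm;
* nitrogen-sensitive Gaussian bands whose signed sensitivities enforce the
  observed regional contrasts (high-LNC leaves darker in 520-610 nm and in
  the 1400-1900 / 2000-2500 nm water-and-organics regions, brighter on the
  775-1300 nm plateau);
* per-sample multiplicative/additive scatter (gain a, offset b), additive
  instrument noise, and a lab/field environment split where field spectra
  get inflated noise plus a smooth random tilt;
* a three-class LNC composition (230 low / 601 medium / 569 high, truncated
  normals per class) totalling 1400 leaves, 648 of them lab-measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import truncnorm

from .evaluation import NitrogenLevelScheme, bin_lnc
from .types import SpectraDataset, Spectrum
import pandas as pd

#: per-class (mean, sd, lower, upper) of LNC in g/kg
DEFAULT_CLASS_LNC = {
    "low": (21.73, 2.37, 14.99, 25.00),
    "medium": (30.09, 2.84, 25.02, 34.96),
    "high": (40.19, 3.60, 35.02, 52.46),
}

#: signed nitrogen sensitivities by band centre (nm); +1 means reflectance
#: rises with LNC. 554/1490/1673/1746/2046 nm are nitrogen-related
#: absorption features; 1179 nm carries the NIR-plateau contrast.
DEFAULT_BAND_SENS = {
    554.0: -1.0,
    1179.0: +1.0,
    1490.0: -1.0,
    1673.0: -1.0,
    1746.0: -1.0,
    2046.0: -1.0,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; defaults emulate the study conditions."""

    wavelength_lo: float = 430.0
    wavelength_hi: float = 2500.0
    wavelength_step: float = 1.0
    class_counts: dict = field(
        default_factory=lambda: {"low": 230, "medium": 601, "high": 569}
    )
    class_lnc: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_LNC))
    band_sensitivities: dict = field(default_factory=lambda: dict(DEFAULT_BAND_SENS))
    band_sigma_nm: float = 8.0
    band_amplitude: float = 0.0012  # reflectance per g/kg at a band centre
    lnc_ref: float = 30.0  # g/kg; sensitivities are shifts per g/kg about this
    scatter_gain_sd: float = 0.05  # multiplicative scatter sd of gain a (a ~ 1)
    scatter_offset_sd: float = 0.01  # additive scatter sd of offset b
    noise_sd: float = 0.012  # additive per-wavelength noise sd (reflectance)
    lab_fraction: float = 648.0 / 1400.0
    field_noise_inflation: float = 2.0
    field_tilt_sd: float = 0.004  # sd of the smooth random field tilt coefficients
    seed: int = 0

    def __post_init__(self):
        if any(c <= 0 for c in self.class_counts.values()):
            raise ValueError("class counts must be positive")
        if any(v[1] <= 0 for v in self.class_lnc.values()):
            raise ValueError("class lnc sds must be positive")
        if self.band_sigma_nm <= 0 or self.noise_sd < 0:
            raise ValueError("band_sigma_nm must be positive, noise_sd nonnegative")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.arange(
            self.wavelength_lo, self.wavelength_hi + 0.5 * self.wavelength_step,
            self.wavelength_step,
        )

    @property
    def n_total(self) -> int:
        return int(sum(self.class_counts.values()))

    @property
    def planted_band_centers(self) -> np.ndarray:
        return np.array(sorted(self.band_sensitivities), dtype=float)

    def low_noise(self) -> "SyntheticConfig":
        """The low-noise regime: minimal instrument noise, no field inflation."""
        return replace(self, noise_sd=2e-4, field_noise_inflation=1.0, field_tilt_sd=5e-4)

    def noiseless(self) -> "SyntheticConfig":
        """No noise and no scatter: the deterministic band model only."""
        return replace(
            self,
            noise_sd=0.0,
            scatter_gain_sd=0.0,
            scatter_offset_sd=0.0,
            field_noise_inflation=1.0,
            field_tilt_sd=0.0,
        )


def _gauss(wl, centre, sigma):
    return np.exp(-0.5 * ((wl - centre) / sigma) ** 2)


def _sigmoid(wl, centre, width):
    return 1.0 / (1.0 + np.exp(-(wl - centre) / width))


def baseline_reflectance(wavelengths: np.ndarray) -> Spectrum:
    """The nitrogen-independent baseline leaf spectrum, values in (0, 1).

    A composite of Gaussian bumps/dips and sigmoid edges with local maxima
    at 550, 1650, 1820 and 2225 nm and local minima at 670, 1432 and
    1950 nm (each within the grid), a red-edge rise after 700 nm and a high
    plateau between 775 and 1300 nm. A small auxiliary dip near 1730 nm
    (C-H region) separates the 1650 and 1820 nm maxima.
    """
    wl = np.asarray(wavelengths, dtype=float)
    r = (
        0.06
        + 0.055 * _gauss(wl, 550, 26)
        - 0.035 * _gauss(wl, 668, 20)
        + 0.40 * _sigmoid(wl, 715, 14)
        - 0.06 * _sigmoid(wl, 1340, 50)
        - 0.13 * _gauss(wl, 1432, 38)
        + 0.050 * _gauss(wl, 1650, 42)
        - 0.030 * _gauss(wl, 1730, 16)
        + 0.085 * _gauss(wl, 1822, 26)
        - 0.240 * _gauss(wl, 1945, 48)
        + 0.080 * _gauss(wl, 2225, 48)
        - 0.180 * _sigmoid(wl, 2420, 55)
    )
    return Spectrum(wl, np.clip(r, 1e-4, 1 - 1e-4))


def _band_matrix(wl: np.ndarray, cfg: SyntheticConfig) -> np.ndarray:
    """(n_bands, n_wavelengths) signed Gaussian band profiles."""
    rows = [
        s * _gauss(wl, c, cfg.band_sigma_nm)
        for c, s in sorted(cfg.band_sensitivities.items())
    ]
    return np.asarray(rows)


def _leaf_reflectance(lnc, environment, cfg, rng, wl, base, bands):
    if lnc <= 0:
        raise ValueError("lnc must be positive (g/kg)")
    clean = base + cfg.band_amplitude * (lnc - cfg.lnc_ref) * bands.sum(axis=0)
    a = 1.0 + rng.normal(0.0, cfg.scatter_gain_sd) if cfg.scatter_gain_sd else 1.0
    a = max(a, 0.1)
    b = rng.normal(0.0, cfg.scatter_offset_sd) if cfg.scatter_offset_sd else 0.0
    noise_sd = cfg.noise_sd
    tilt = 0.0
    if environment == "field":
        noise_sd *= cfg.field_noise_inflation
        if cfg.field_tilt_sd > 0:
            u = (wl - wl.mean()) / (0.5 * (wl[-1] - wl[0]))
            t0, t1 = rng.normal(0.0, cfg.field_tilt_sd, size=2)
            tilt = t0 + t1 * u
    eps = rng.normal(0.0, noise_sd, size=wl.size) if noise_sd > 0 else 0.0
    return a * clean + b + tilt + eps


def generate_leaf(
    lnc: float, environment: str, cfg: SyntheticConfig | None = None, seed: int = 0
) -> Spectrum:
    """One synthetic leaf spectrum; deterministic for a fixed (lnc, cfg, seed)."""
    cfg = cfg or SyntheticConfig()
    wl = cfg.wavelengths
    base = baseline_reflectance(wl).reflectance
    bands = _band_matrix(wl, cfg)
    rng = np.random.default_rng(seed)
    return Spectrum(wl, _leaf_reflectance(float(lnc), environment, cfg, rng, wl, base, bands))


def generate_dataset(cfg: SyntheticConfig | None = None) -> SpectraDataset:
    """A full labelled dataset under the configured study conditions.

    Per class, LNC values are drawn from a truncated normal on the class
    range; environments are assigned so that ``round(lab_fraction * n)``
    samples are lab-measured; levels are re-derived from the drawn LNC with
    the default cutpoint scheme (consistent with the class ranges).
    """
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    wl = cfg.wavelengths
    base = baseline_reflectance(wl).reflectance
    bands = _band_matrix(wl, cfg)

    lncs = []
    for name in ("low", "medium", "high"):
        n = cfg.class_counts[name]
        mu, sd, lo, hi = cfg.class_lnc[name]
        a, b = (lo - mu) / sd, (hi - mu) / sd
        draws = truncnorm.rvs(a, b, loc=mu, scale=sd, size=n, random_state=rng)
        lncs.append(draws)
    lnc = np.concatenate(lncs)

    n_total = lnc.size
    n_lab = int(round(cfg.lab_fraction * n_total))
    env = np.array(["field"] * n_total, dtype=object)
    env[rng.permutation(n_total)[:n_lab]] = "lab"
    cultivar = rng.choice(np.array(["LMY24", "XLZ53"], dtype=object), size=n_total)

    X = np.empty((n_total, wl.size))
    for i in range(n_total):
        X[i] = _leaf_reflectance(float(lnc[i]), env[i], cfg, rng, wl, base, bands)

    meta = pd.DataFrame(
        {
            "lnc": lnc,
            "level": pd.array(bin_lnc(lnc, NitrogenLevelScheme()), dtype="string"),
            "environment": pd.array(env, dtype="string"),
            "cultivar": pd.array(cultivar, dtype="string"),
            "split": pd.array(["unassigned"] * n_total, dtype="string"),
        }
    )
    return SpectraDataset(X, wl, meta)
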