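import numpy as np
import pytest

from leafspec_n import SpectraDataset, Spectrum, SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_synthetic():
    """A small low-noise labelled dataset on a coarse grid (fast tests)."""
    cfg = SyntheticConfig(
        class_counts={"low": 40, "medium": 60, "high": 50},
        wavelength_step=10.0,
        seed=123,
    ).low_noise()
    return cfg, generate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_dataset(X, wl=None, **meta):
    import pandas as pd

    n = X.shape[0]
    wl = np.arange(X.shape[1], dtype=float) if wl is None else np.asarray(wl, float)
    df = pd.DataFrame({k: v for k, v in meta.items()})
    return SpectraDataset(X, wl, df if meta else None)


def planted_regression_data(rng, n=150, p=100, k=5, noise=0.05):
    """y linear in k known columns + noise; returns (dataset, informative idx)."""
    X = rng.normal(size=(n, p))
    idx = np.linspace(5, p - 5, k).astype(int)
    beta = np.linspace(1.0, 2.0, k)
    y = X[:, idx] @ beta + noise * rng.normal(size=n)
    ds = make_dataset(X, lnc=y - y.min() + 10.0)
    return ds, idx
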