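import numpy as np
import pytest

import leafspec as L


@pytest.fixture(scope="session")
def noise_only_dataset():
    """n=200 spectra with measurement noise only (no affine corruption).

    The planted-signal regime: band/SPAD correlations reflect the clean
    spectrum's SPAD derivative directly.
    """
    cfg = L.SimConfig(n_samples=200, seed=11, noise_sd=0.002,
                      scatter_sd=0.0, baseline_sd=0.0, tilt_sd=0.0)
    return L.generate_dataset(cfg)


@pytest.fixture(scope="session")
def easy_dataset():
    """Survey-sized (n=91) noise-only dataset for pipeline-level tests."""
    cfg = L.SimConfig(n_samples=91, seed=5, noise_sd=0.002,
                      scatter_sd=0.0, baseline_sd=0.0, tilt_sd=0.0)
    return L.generate_dataset(cfg)


@pytest.fixture(scope="session")
def default_dataset():
    """Full default study conditions (91 samples, scatter + baseline + noise)."""
    return L.generate_dataset(L.SimConfig(seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_spectra(rng):
    """20 samples x 6 bands of generic positive data with a target."""
    grid = L.WavelengthGrid(np.array([500.0, 510, 520, 530, 540, 550]))
    R = rng.uniform(0.05, 0.6, size=(20, 6))
    ids = [f"T{i:02d}" for i in range(20)]
    spectra = L.SpectraSet(sample_ids=ids, reflectance=R, grid=grid)
    targets = L.TargetVector(sample_ids=list(ids), spad=rng.uniform(35, 55, 20))
    return spectra, targets
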