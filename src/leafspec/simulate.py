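"""Chlorophyll-conditioned synthetic leaf reflectance spectra.

The generator produces datasets with the morphology of a green-leaf
reflectance curve — a green reflectance peak near 551 nm, the red
absorption valley near 670 nm, the chlorophyll-sensitive red edge near
720 nm, a high near-infrared plateau (~762–1096 nm) and the two water
absorption valleys near 1445 and 1924 nm — with the green peak, red
valley and red-edge position all driven by a latent per-leaf SPAD value.
On top of the clean curve each sample receives the per-sample affine
corruption (multiplicative gain, additive offset, linear wavelength tilt)
plus white noise that scatter-correction preprocessing (SNV, MSC) is
designed to remove.

The clean curve is a deliberate closed-form Gaussian/logistic
parameterization rather than a radiative-transfer model: every test that
relies on "which bands carry chlorophyll signal" can read the answer off
the known SPAD-derivative of the formula (:func:`spad_sensitivity`).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .core import SpectraSet, TargetVector, WavelengthGrid

__all__ = [
    "SimConfig",
    "SimTruth",
    "clean_spectrum",
    "spad_sensitivity",
    "corrupt",
    "generate_dataset",
]


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic dataset.

    Defaults mirror a single-campaign leaf survey: 91 plots with SPAD
    concentrated in 40–50 (truncated normal, mean 45, s.d. 5, bounds
    30–60).  Corruption magnitudes are package choices, not field
    estimates: ``scatter_sd`` is the log-scale s.d. of the per-sample
    multiplicative gain, ``baseline_sd`` the s.d. of the additive offset
    (reflectance units), ``tilt_sd`` the s.d. of a linear baseline slope
    per nm, and ``noise_sd`` the i.i.d. measurement noise s.d.
    """

    n_samples: int = 91
    seed: int = 0
    spad_mean: float = 45.0
    spad_sd: float = 5.0
    spad_bounds: tuple[float, float] = (30.0, 60.0)
    noise_sd: float = 0.005
    scatter_sd: float = 0.15
    baseline_sd: float = 0.02
    tilt_sd: float = 1e-5
    #: |dR/dSPAD| above which a band counts as chlorophyll-sensitive.
    #: Chosen so that a one-s.d. SPAD change (5 units) moves reflectance
    #: by at least the default measurement noise (0.005).
    sensitivity_threshold: float = 1e-3

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        lo, hi = self.spad_bounds
        if not lo < hi:
            raise ValueError("spad_bounds must be ordered (low < high)")
        for name in ("spad_sd", "noise_sd", "scatter_sd", "baseline_sd", "tilt_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.spad_mean <= 100:
            raise ValueError("spad_mean must be in (0, 100]")


@dataclasses.dataclass(frozen=True)
class SimTruth:
    """Ground truth recorded for every draw the generator makes."""

    spad: np.ndarray
    gain: np.ndarray
    offset: np.ndarray
    tilt: np.ndarray
    #: wavelengths (nm) where |dR/dSPAD| at the population-mean SPAD
    #: exceeds the configured sensitivity threshold
    sensitive_bands: np.ndarray
    sensitivity_threshold: float


def clean_spectrum(spad: float, grid: WavelengthGrid) -> np.ndarray:
    """Noise-free leaf reflectance R(lambda; SPAD) on the given grid.

    Piecewise closed form: visible base level 0.08; logistic red-edge rise
    to a 0.45 NIR plateau centered at 720 nm (width 15 nm, midpoint
    shifting +0.2 nm per SPAD unit above 45); green peak as a Gaussian at
    551 nm whose amplitude 0.18*exp(-SPAD/40) shrinks with chlorophyll;
    red valley as a Gaussian dip at 670 nm deepening with chlorophyll
    (0.05 + 0.002*SPAD, floored at 0.02 reflectance); SPAD-independent
    water valleys at 1445 and 1924 nm.  Final values clipped to
    [0.01, 0.6].
    """
    if not 0 < spad <= 100:
        raise ValueError(f"spad must be in (0, 100], got {spad}")
    lam = grid.wavelengths_nm
    if lam[0] < 350 or lam[-1] > 2500:
        raise ValueError("grid must lie within 350-2500 nm")

    edge_center = 720.0 + 0.2 * (spad - 45.0)
    r = 0.08 + (0.45 - 0.08) / (1.0 + np.exp(-(lam - edge_center) / 15.0))
    r = r + 0.18 * np.exp(-spad / 40.0) * np.exp(-((lam - 551.0) ** 2) / (2 * 30.0**2))
    r = r - (0.05 + 0.002 * spad) * np.exp(-((lam - 670.0) ** 2) / (2 * 25.0**2))
    r = np.maximum(r, 0.02)  # red-valley floor
    r = r - 0.12 * np.exp(-((lam - 1445.0) ** 2) / (2 * 40.0**2))
    r = r - 0.20 * np.exp(-((lam - 1924.0) ** 2) / (2 * 45.0**2))
    return np.clip(r, 0.01, 0.6)


def spad_sensitivity(spad: float, grid: WavelengthGrid, h: float = 0.01) -> np.ndarray:
    """Central-difference dR/dSPAD of the clean spectrum."""
    return (clean_spectrum(spad + h, grid) - clean_spectrum(spad - h, grid)) / (2 * h)


def corrupt(
    clean: np.ndarray,
    gain: float,
    offset: float = 0.0,
    tilt: float = 0.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    grid: WavelengthGrid | None = None,
) -> np.ndarray:
    """Apply per-sample affine corruption plus white noise, clipped at 0.

    ``gain*clean + offset + tilt*(lambda - 350) + N(0, noise_sd)``.  The
    tilt term needs the wavelength axis, so ``grid`` is required whenever
    ``tilt != 0``.
    """
    if gain <= 0:
        raise ValueError("gain must be positive")
    out = gain * np.asarray(clean, dtype=float) + offset
    if tilt != 0.0:
        if grid is None:
            raise ValueError("grid is required when tilt != 0")
        out = out + tilt * (grid.wavelengths_nm - 350.0)
    if noise_sd > 0:
        if rng is None:
            raise ValueError("rng is required when noise_sd > 0")
        out = out + rng.normal(0.0, noise_sd, size=out.shape)
    return np.maximum(out, 0.0)


def generate_dataset(
    cfg: SimConfig = SimConfig(), grid: WavelengthGrid | None = None
) -> tuple[SpectraSet, TargetVector, SimTruth]:
    """Draw a full synthetic dataset; identical seeds give identical bits.

    SPAD is truncated-normal; each spectrum is the clean curve for its
    SPAD pushed through :func:`corrupt` with per-sample gain
    ``exp(N(0, scatter_sd))``, offset ``N(0, baseline_sd)`` and tilt
    ``N(0, tilt_sd)``.
    """
    if grid is None:
        grid = WavelengthGrid.default()
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.spad_bounds
    a = (lo - cfg.spad_mean) / cfg.spad_sd
    b = (hi - cfg.spad_mean) / cfg.spad_sd
    spad = stats.truncnorm.rvs(a, b, loc=cfg.spad_mean, scale=cfg.spad_sd,
                               size=cfg.n_samples, random_state=rng)
    gain = np.exp(rng.normal(0.0, cfg.scatter_sd, size=cfg.n_samples))
    offset = rng.normal(0.0, cfg.baseline_sd, size=cfg.n_samples)
    tilt = rng.normal(0.0, cfg.tilt_sd, size=cfg.n_samples)

    lam = grid.wavelengths_nm
    clean = np.vstack([clean_spectrum(c, grid) for c in spad])
    R = gain[:, None] * clean + offset[:, None] + tilt[:, None] * (lam - 350.0)[None, :]
    if cfg.noise_sd > 0:
        R = R + rng.normal(0.0, cfg.noise_sd, size=R.shape)
    R = np.maximum(R, 0.0)

    deriv = spad_sensitivity(cfg.spad_mean, grid)
    sensitive = lam[np.abs(deriv) >= cfg.sensitivity_threshold]

    ids = [f"S{i + 1:03d}" for i in range(cfg.n_samples)]
    spectra = SpectraSet(sample_ids=ids, reflectance=R, grid=grid,
                         preprocessing_tag="original")
    targets = TargetVector(sample_ids=list(ids), spad=spad)
    truth = SimTruth(spad=spad, gain=gain, offset=offset, tilt=tilt,
                     sensitive_bands=sensitive,
                     sensitivity_threshold=cfg.sensitivity_threshold)
    return spectra, targets, truth
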