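"""Scatter-correction preprocessing: SNV and MSC.

Both transforms undo per-sample affine distortion (multiplicative gain
from scattering, additive baseline offset) in reflectance spectra.

Standard normal variate (SNV) standardizes each spectrum by its own
statistics over wavelengths:

    x_snv = (x - mean(x)) / sd(x),   sd with the m - 1 denominator,

which makes it exactly invariant to ``a*x + b`` for a > 0.

Multiplicative scatter correction (MSC) regresses each spectrum by
ordinary least squares onto a reference "ideal" spectrum (the training-set
mean), ``x_i ~ k_i * x_ref + b_i``, and inverts the fit:

    x_msc = (x_i - b_i) / k_i.

Unlike SNV, MSC keeps spectra on a common reflectance-like scale.  The
reference mean is fitted on training data only; held-out samples get
fresh per-sample (k_i, b_i) against the stored reference, so no test
information leaks into the correction.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .core import SpectraSet, WavelengthGrid

__all__ = ["MSCReference", "snv_transform", "msc_fit", "msc_transform"]

#: |slope| below which an MSC fit is considered degenerate
_K_MIN = 1e-8


def snv_transform(spectra: SpectraSet) -> SpectraSet:
    """Row-wise standard normal variate transform (tag ``snv``).

    Raises ``ValueError`` naming the sample if any row has zero variance
    across wavelengths (a flat spectrum carries no correctable signal).
    """
    R = spectra.reflectance
    if R.shape[1] < 2:
        raise ValueError("SNV needs at least 2 bands per spectrum")
    mu = R.mean(axis=1, keepdims=True)
    sd = R.std(axis=1, ddof=1, keepdims=True)
    # relative tolerance: a numerically constant row has sd at rounding level
    flat = np.flatnonzero(sd.ravel() <= 1e-12 * np.maximum(1.0, np.abs(mu.ravel())))
    if flat.size:
        raise ValueError(
            f"zero-variance spectrum for sample {spectra.sample_ids[flat[0]]!r}")
    return spectra.with_reflectance((R - mu) / sd, tag="snv")


@dataclasses.dataclass(eq=False)
class MSCReference:
    """The MSC 'ideal spectrum' plus per-sample fits from the fitting set."""

    mean_spectrum: np.ndarray
    grid: WavelengthGrid
    slopes: np.ndarray      # k_i of the fitting set
    intercepts: np.ndarray  # b_i of the fitting set

    def __post_init__(self) -> None:
        if self.mean_spectrum.shape != (len(self.grid),):
            raise ValueError("mean_spectrum length must match the grid")


def _affine_fit(rows: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS slope/intercept of each row regressed on ``ref`` over wavelengths."""
    ref_c = ref - ref.mean()
    denom = float(ref_c @ ref_c)
    slopes = (rows - rows.mean(axis=1, keepdims=True)) @ ref_c / denom
    intercepts = rows.mean(axis=1) - slopes * ref.mean()
    return slopes, intercepts


def msc_fit(spectra: SpectraSet) -> MSCReference:
    """Fit the MSC reference (column-mean spectrum) on a fitting set."""
    if spectra.n_samples < 2:
        raise ValueError("MSC needs at least 2 samples to form a reference mean")
    mean_spectrum = spectra.reflectance.mean(axis=0)
    if np.ptp(mean_spectrum) == 0.0:
        raise ValueError("constant mean spectrum: MSC reference is degenerate")
    slopes, intercepts = _affine_fit(spectra.reflectance, mean_spectrum)
    return MSCReference(mean_spectrum=mean_spectrum, grid=spectra.grid,
                        slopes=slopes, intercepts=intercepts)


def msc_transform(spectra: SpectraSet, ref: MSCReference) -> SpectraSet:
    """Correct each spectrum against the stored reference (tag ``msc``).

    Per-sample (k_i, b_i) are always re-fitted against ``ref.mean_spectrum``
    so the same reference serves training and held-out data.
    """
    if spectra.grid != ref.grid:
        raise ValueError("spectra grid does not match the MSC reference grid")
    slopes, intercepts = _affine_fit(spectra.reflectance, ref.mean_spectrum)
    small = np.flatnonzero(np.abs(slopes) <= _K_MIN)
    if small.size:
        raise ValueError(
            f"degenerate MSC slope |k| <= {_K_MIN:g} for sample "
            f"{spectra.sample_ids[small[0]]!r}")
    corrected = (spectra.reflectance - intercepts[:, None]) / slopes[:, None]
    return spectra.with_reflectance(corrected, tag="msc")
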