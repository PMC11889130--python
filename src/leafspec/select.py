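"""Sensitive-band screening and feature extraction.

Stage one screens wavelengths by the Pearson correlation between band
reflectance and SPAD, keeping bands with |r| >= 0.6 (the conventional
"strong correlation" cut; the magnitude is used because chlorophyll makes
the green-peak region *negatively* correlated yet clearly sensitive).

Stage two condenses the screened bands into a model-ready design matrix
by one of three extractors:

* ``gbt_importance`` — gradient-boosted trees ranked by split-count
  ("weight") importance, keeping the top k bands;
* ``rfe`` — recursive feature elimination with a random-forest base,
  dropping the least important surviving band one per iteration until k
  remain;
* ``pca`` — principal-component projection keeping the smallest number of
  leading components whose explained-variance ratios sum to >= 0.99.

Every extractor is fitted on training data only; the returned
:class:`FeatureSet` knows how to transform held-out spectra.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestRegressor
from sklearn.feature_selection import RFE
from xgboost import XGBRegressor

from .core import SpectraSet, TargetVector, WavelengthGrid, check_aligned

__all__ = [
    "CorrelationProfile",
    "BandMask",
    "FeatureSet",
    "pearson_profile",
    "threshold_mask",
    "gbt_importance_select",
    "rfe_select",
    "pca_project",
]


@dataclasses.dataclass(eq=False)
class CorrelationProfile:
    """Per-wavelength Pearson r between reflectance and SPAD."""

    grid: WavelengthGrid
    r: np.ndarray

    def __post_init__(self) -> None:
        if self.r.shape != (len(self.grid),):
            raise ValueError("r length must match the grid")
        if np.any(np.abs(self.r) > 1 + 1e-12):
            raise ValueError("|r| must not exceed 1")


@dataclasses.dataclass(eq=False)
class BandMask:
    """Boolean sensitive-band mask derived from a correlation profile."""

    grid: WavelengthGrid
    selected: np.ndarray
    threshold: float = 0.6

    def __post_init__(self) -> None:
        if self.selected.shape != (len(self.grid),):
            raise ValueError("mask length must match the grid")

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.wavelengths_nm[self.selected]


@dataclasses.dataclass(eq=False)
class FeatureSet:
    """Model-ready design matrix with provenance.

    ``provenance`` is one of ``gbt_importance``, ``rfe``, ``pca``.  Band
    selectors record the kept wavelengths (ascending); PCA records the
    training mean, loadings and explained-variance ratios instead, and
    ``selected_wavelengths`` is empty.
    """

    provenance: str
    design_matrix: np.ndarray
    grid: WavelengthGrid
    band_indices: np.ndarray                       # columns used at transform time
    selected_wavelengths: np.ndarray
    importances: np.ndarray | None = None          # gbt split counts (masked order)
    elimination_rank: np.ndarray | None = None     # rfe ranks, 1 = kept (masked order)
    pca_mean: np.ndarray | None = None
    pca_loadings: np.ndarray | None = None         # (n_components, n_masked_bands)
    explained_variance_ratio: np.ndarray | None = None

    @property
    def n_features(self) -> int:
        return self.design_matrix.shape[1]

    def transform(self, spectra: SpectraSet) -> np.ndarray:
        """Project held-out spectra into this feature space."""
        if spectra.grid != self.grid:
            raise ValueError("spectra grid does not match the FeatureSet grid")
        X = spectra.reflectance[:, self.band_indices]
        if self.provenance == "pca":
            return (X - self.pca_mean) @ self.pca_loadings.T
        return X


def pearson_profile(spectra: SpectraSet, targets: TargetVector) -> CorrelationProfile:
    """Pearson r of each wavelength's reflectance against SPAD.

    Zero-variance bands get r = 0 with a warning (they carry no signal and
    the coefficient is undefined there).  Requires n >= 3 aligned samples
    and a non-constant target.
    """
    check_aligned(spectra, targets)
    n = spectra.n_samples
    if n < 3:
        raise ValueError("pearson_profile needs at least 3 samples")
    y = targets.spad
    yc = y - y.mean()
    sy = np.sqrt(yc @ yc)
    if sy == 0.0:
        raise ValueError("target is constant; correlation undefined")
    Xc = spectra.reflectance - spectra.reflectance.mean(axis=0, keepdims=True)
    sx = np.sqrt(np.einsum("ij,ij->j", Xc, Xc))
    flat = sx == 0.0
    if np.any(flat):
        warnings.warn(f"{int(flat.sum())} zero-variance bands; their r set to 0",
                      stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ yc) / (sx * sy)
    r[flat] = 0.0
    r = np.clip(r, -1.0, 1.0)
    return CorrelationProfile(grid=spectra.grid, r=r)


def threshold_mask(profile: CorrelationProfile, threshold: float = 0.6) -> BandMask:
    """Bands with |r| >= threshold (default 0.6, the strong-correlation cut)."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    selected = np.abs(profile.r) >= threshold
    if not selected.any():
        warnings.warn(
            f"no band reaches |r| >= {threshold}; downstream extractors will fail",
            stacklevel=2)
    return BandMask(grid=profile.grid, selected=selected, threshold=threshold)


def _masked_matrix(spectra: SpectraSet, targets: TargetVector,
                   mask: BandMask) -> tuple[np.ndarray, np.ndarray]:
    check_aligned(spectra, targets)
    if spectra.grid != mask.grid:
        raise ValueError("spectra grid does not match the mask grid")
    idx = np.flatnonzero(mask.selected)
    if idx.size == 0:
        raise ValueError("empty band mask: no sensitive bands to select from")
    return idx, spectra.reflectance[:, idx]


def gbt_importance_select(
    spectra: SpectraSet,
    targets: TargetVector,
    mask: BandMask,
    k: int = 10,
    seed: int = 0,
    *,
    n_estimators: int = 200,
    max_depth: int = 4,
    learning_rate: float = 0.1,
    min_split_loss: float = 1.0,
) -> FeatureSet:
    """Top-k bands by gradient-boosted-tree split-count importance.

    The importance of a band is the number of times it is used as a split
    node across the whole ensemble ("weight" importance).  Ties break
    toward the lower wavelength; if fewer than k bands are masked they are
    all kept with a warning.

    Two numerical safeguards keep split counts meaningful on spectra,
    where neighbouring bands are near-duplicates: columns are fitted in a
    seeded random permutation (the booster breaks equal-gain ties by
    column order, which would otherwise funnel all tied splits into the
    lowest wavelength of a correlated block), and splits must improve the
    training loss by at least ``min_split_loss`` (squared target units),
    which prunes the residual-noise splits that would otherwise dominate
    the counts late in boosting.
    """
    idx, X = _masked_matrix(spectra, targets, mask)
    perm = np.random.default_rng(seed).permutation(idx.size)
    model = XGBRegressor(n_estimators=n_estimators, max_depth=max_depth,
                         learning_rate=learning_rate, gamma=min_split_loss,
                         random_state=seed, n_jobs=1, verbosity=0)
    model.fit(X[:, perm], targets.spad)
    score = model.get_booster().get_score(importance_type="weight")
    counts = np.zeros(idx.size)
    for name, c in score.items():
        counts[perm[int(name[1:])]] = c

    if idx.size <= k:
        if idx.size < k:
            warnings.warn(f"only {idx.size} masked bands available; keeping all "
                          f"(requested k={k})", stacklevel=2)
        keep = np.arange(idx.size)
    else:
        order = np.lexsort((mask.grid.wavelengths_nm[idx], -counts))
        keep = np.sort(order[:k])
    sel = idx[keep]
    return FeatureSet(
        provenance="gbt_importance",
        design_matrix=spectra.reflectance[:, sel],
        grid=spectra.grid,
        band_indices=sel,
        selected_wavelengths=spectra.grid.wavelengths_nm[sel],
        importances=counts,
    )


def rfe_select(
    spectra: SpectraSet,
    targets: TargetVector,
    mask: BandMask,
    k: int = 10,
    seed: int = 0,
    *,
    n_estimators: int = 100,
    max_features: str | float = "sqrt",
) -> FeatureSet:
    """Recursive feature elimination with a random-forest base regressor.

    One band — the lowest impurity-importance survivor — is dropped per
    iteration until k remain.  The elimination order is recorded as ranks
    in sklearn's RFE convention: kept bands rank 1, rank 2 was eliminated
    last, and the largest rank was eliminated first.
    """
    idx, X = _masked_matrix(spectra, targets, mask)
    if idx.size <= k:
        if idx.size < k:
            warnings.warn(f"only {idx.size} masked bands available; keeping all "
                          f"(requested k={k})", stacklevel=2)
        sel = idx
        rank = np.ones(idx.size, dtype=int)
    else:
        base = RandomForestRegressor(n_estimators=n_estimators,
                                     max_features=max_features,
                                     random_state=seed, n_jobs=1)
        rfe = RFE(base, n_features_to_select=k, step=1)
        rfe.fit(X, targets.spad)
        sel = idx[rfe.support_]
        rank = rfe.ranking_
    return FeatureSet(
        provenance="rfe",
        design_matrix=spectra.reflectance[:, sel],
        grid=spectra.grid,
        band_indices=sel,
        selected_wavelengths=spectra.grid.wavelengths_nm[sel],
        elimination_rank=rank,
    )


def pca_project(
    spectra: SpectraSet,
    mask: BandMask,
    cum_var: float = 0.99,
) -> FeatureSet:
    """Principal-component scores of the masked bands.

    Bands are mean-centered with training statistics (no variance
    scaling) and the smallest number of leading components whose
    explained-variance ratios sum to >= ``cum_var`` is kept.
    """
    if spectra.grid != mask.grid:
        raise ValueError("spectra grid does not match the mask grid")
    idx = np.flatnonzero(mask.selected)
    if idx.size == 0:
        raise ValueError("empty band mask: no sensitive bands to project")
    if spectra.n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")
    if not 0 < cum_var <= 1:
        raise ValueError("cum_var must be in (0, 1]")
    X = spectra.reflectance[:, idx]
    pca = PCA(svd_solver="full").fit(X)
    csum = np.cumsum(pca.explained_variance_ratio_)
    reached = np.flatnonzero(csum >= cum_var - 1e-12)
    m = int(reached[0]) + 1 if reached.size else len(csum)
    scores = pca.transform(X)[:, :m]
    return FeatureSet(
        provenance="pca",
        design_matrix=scores,
        grid=spectra.grid,
        band_indices=idx,
        selected_wavelengths=np.array([]),
        pca_mean=pca.mean_,
        pca_loadings=pca.components_[:m],
        explained_variance_ratio=pca.explained_variance_ratio_[:m],
    )
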