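"""Core containers for leaf reflectance spectra and chlorophyll targets.

The whole pipeline trades in three objects:

* :class:`WavelengthGrid` — the ordered wavelength axis (nm) shared by a
  set of spectra; the default grid is 350–2500 nm at 1 nm (2151 bands),
  matching a field spectroradiometer's export.
* :class:`SpectraSet` — a samples × wavelengths reflectance matrix bound
  to a grid and to unique sample ids, carrying a ``preprocessing_tag``
  that records whether rows are raw, SNV- or MSC-corrected.
* :class:`TargetVector` — per-sample SPAD chlorophyll readings aligned
  row-for-row to a :class:`SpectraSet`.

Alignment between spectra and targets is always by sample id and always
checked explicitly (see :func:`check_aligned`); downstream stages never
assume two containers happen to be in the same order.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

#: preprocessing states a SpectraSet can be in
PREPROCESSING_TAGS = ("original", "snv", "msc")

#: tolerance used to validate that SNV-tagged rows are standardized
_SNV_TOL = 1e-9


class AlignmentError(ValueError):
    """Sample ids of two containers do not correspond."""


@dataclasses.dataclass(frozen=True, eq=False)
class WavelengthGrid:
    """Strictly increasing wavelength axis in nanometres."""

    wavelengths_nm: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        if wl.ndim != 1 or wl.size == 0:
            raise ValueError("wavelength grid must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(wl)) or np.any(wl <= 0):
            raise ValueError("wavelengths must be finite and positive")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing with no duplicates")
        object.__setattr__(self, "wavelengths_nm", wl)

    @classmethod
    def default(cls) -> "WavelengthGrid":
        """The 350..2500 nm integer grid (2151 bands)."""
        return cls(np.arange(350.0, 2501.0))

    def __len__(self) -> int:
        return int(self.wavelengths_nm.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return np.array_equal(self.wavelengths_nm, other.wavelengths_nm)

    def __hash__(self) -> int:  # frozen dataclass with eq=False needs explicit hash
        return hash((self.wavelengths_nm.size,
                     float(self.wavelengths_nm[0]),
                     float(self.wavelengths_nm[-1])))


def _check_ids(sample_ids: Sequence[str]) -> list[str]:
    ids = [str(s) for s in sample_ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise ValueError(f"duplicate sample ids: {dupes}")
    return ids


@dataclasses.dataclass(eq=False)
class SpectraSet:
    """Reflectance matrix (rows = samples, columns = wavelengths).

    Raw (``original``) reflectance is unitless in [0, 1]-ish range and must
    be finite and non-negative.  SNV-tagged rows must each have zero mean
    and unit sample standard deviation (``m - 1`` denominator).
    """

    sample_ids: list[str]
    reflectance: np.ndarray
    grid: WavelengthGrid
    preprocessing_tag: str = "original"

    def __post_init__(self) -> None:
        self.sample_ids = _check_ids(self.sample_ids)
        R = np.asarray(self.reflectance, dtype=float)
        if R.ndim != 2:
            raise ValueError("reflectance must be a 2-D matrix")
        if R.shape[0] != len(self.sample_ids):
            raise ValueError(
                f"{len(self.sample_ids)} sample ids but {R.shape[0]} spectra rows")
        if R.shape[1] != len(self.grid):
            raise ValueError(
                f"grid has {len(self.grid)} wavelengths but matrix has {R.shape[1]} columns")
        if self.preprocessing_tag not in PREPROCESSING_TAGS:
            raise ValueError(f"unknown preprocessing tag {self.preprocessing_tag!r}")
        if not np.all(np.isfinite(R)):
            raise ValueError("reflectance must be finite")
        if self.preprocessing_tag == "original" and np.any(R < 0):
            raise ValueError("raw reflectance must be non-negative")
        if self.preprocessing_tag == "snv" and R.shape[1] >= 2 and R.shape[0] > 0:
            mu = R.mean(axis=1)
            sd = R.std(axis=1, ddof=1)
            if np.any(np.abs(mu) > _SNV_TOL) or np.any(np.abs(sd - 1.0) > _SNV_TOL):
                raise ValueError("snv-tagged rows must have mean 0 and sample s.d. 1")
        self.reflectance = R

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_bands(self) -> int:
        return self.reflectance.shape[1]

    def take(self, indices: np.ndarray) -> "SpectraSet":
        """Row subset in the given order (used by train/test splitting)."""
        idx = np.asarray(indices, dtype=int)
        return SpectraSet(
            sample_ids=[self.sample_ids[i] for i in idx],
            reflectance=self.reflectance[idx],
            grid=self.grid,
            preprocessing_tag=self.preprocessing_tag,
        )

    def with_reflectance(self, reflectance: np.ndarray, tag: str) -> "SpectraSet":
        """Same samples and grid, new values and preprocessing tag."""
        return SpectraSet(
            sample_ids=list(self.sample_ids),
            reflectance=reflectance,
            grid=self.grid,
            preprocessing_tag=tag,
        )


@dataclasses.dataclass(eq=False)
class TargetVector:
    """Per-sample SPAD chlorophyll values (unitless meter readings, > 0)."""

    sample_ids: list[str]
    spad: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = _check_ids(self.sample_ids)
        y = np.asarray(self.spad, dtype=float)
        if y.ndim != 1:
            raise ValueError("spad must be a 1-D vector")
        if y.size != len(self.sample_ids):
            raise ValueError(f"{len(self.sample_ids)} ids but {y.size} SPAD values")
        if not np.all(np.isfinite(y)):
            raise ValueError("SPAD values must be finite")
        if np.any(y <= 0):
            raise ValueError("SPAD values must be positive")
        self.spad = y

    def __len__(self) -> int:
        return int(self.spad.size)

    def take(self, indices: np.ndarray) -> "TargetVector":
        idx = np.asarray(indices, dtype=int)
        return TargetVector(sample_ids=[self.sample_ids[i] for i in idx],
                            spad=self.spad[idx])

    def align_to(self, spectra: SpectraSet) -> "TargetVector":
        """Reorder to the spectra's sample order (spectra order is canonical).

        Raises :class:`AlignmentError` if the id sets differ.
        """
        if self.sample_ids == spectra.sample_ids:
            return self
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in spectra.sample_ids if s not in pos]
        extra = [s for s in self.sample_ids if s not in set(spectra.sample_ids)]
        if missing or extra:
            raise AlignmentError(
                f"target/spectra id mismatch (missing from targets: {missing[:5]}, "
                f"not in spectra: {extra[:5]})")
        order = np.array([pos[s] for s in spectra.sample_ids], dtype=int)
        return self.take(order)


def check_aligned(spectra: SpectraSet, targets: TargetVector) -> None:
    """Raise :class:`AlignmentError` unless ids match element-wise in order."""
    if spectra.sample_ids != targets.sample_ids:
        raise AlignmentError(
            "spectra and targets are not aligned; call TargetVector.align_to first")
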