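"""Reflectance correction and scatter-removal preprocessing for NIR spectra.

Diffuse-reflectance spectra of intact fruit carry multiplicative and
additive scatter effects (path-length and surface-geometry variation) on
top of the chemical absorption signal.  The standard remedies implemented
here are multiplicative scatter correction (MSC — per-spectrum affine
regression against a reference spectrum) and the standard normal variate
transform (SNV — per-spectrum standardization).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ..errors import DegenerateInputError, InvalidParameterError

__all__ = [
    "RawSpectrum",
    "SpectraSet",
    "reflectance_correct",
    "downsample_wavelengths",
    "msc",
    "snv",
]


@dataclass(frozen=True)
class RawSpectrum:
    """Uncorrected detector counts with white/dark reference scans."""

    wavelengths: np.ndarray
    intensity: np.ndarray
    white_reference: np.ndarray
    dark_reference: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.wavelengths)
        for name in ("intensity", "white_reference", "dark_reference"):
            if len(getattr(self, name)) != n:
                raise InvalidParameterError(f"{name} length differs from wavelength grid")


@dataclass(frozen=True)
class SpectraSet:
    """A wavelength grid with an (N, W) reflectance matrix and optional
    per-sample soluble-solids reference values (degrees Brix)."""

    wavelengths: np.ndarray  # (W,) nm, strictly increasing
    reflectance: np.ndarray  # (N, W)
    brix: np.ndarray | None = None  # (N,)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        r = np.atleast_2d(np.asarray(self.reflectance, dtype=float))
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "reflectance", r)
        if r.shape[1] != len(wl):
            raise InvalidParameterError("reflectance columns must match wavelength grid")
        if len(wl) > 1 and not np.all(np.diff(wl) > 0):
            raise InvalidParameterError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(r)):
            raise InvalidParameterError("reflectance must be finite")
        if self.brix is not None:
            b = np.asarray(self.brix, dtype=float)
            object.__setattr__(self, "brix", b)
            if len(b) != r.shape[0]:
                raise InvalidParameterError("brix vector length must match sample count")

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.reflectance.shape[1]


def reflectance_correct(raw: RawSpectrum) -> np.ndarray:
    """Black/white correction ``R = (I - I_d) / (I_w - I_d)`` elementwise."""
    i = np.asarray(raw.intensity, dtype=float)
    iw = np.asarray(raw.white_reference, dtype=float)
    idark = np.asarray(raw.dark_reference, dtype=float)
    denom = iw - idark
    if np.any(denom == 0):
        raise DegenerateInputError("white and dark references coincide at some wavelength")
    return (i - idark) / denom


def downsample_wavelengths(spectra: SpectraSet, keep_every: int) -> SpectraSet:
    """Decimate the grid, keeping indices ``0, s, 2s, ...`` (one kept, the
    next ``s - 1`` dropped).  A 1771-point 400–1000 nm grid with ``s = 3``
    leaves 591 points."""
    if keep_every < 1:
        raise InvalidParameterError("stride must be >= 1")
    idx = np.arange(0, spectra.n_wavelengths, keep_every)
    return SpectraSet(
        wavelengths=spectra.wavelengths[idx],
        reflectance=spectra.reflectance[:, idx],
        brix=spectra.brix,
    )


def msc(spectra: SpectraSet, reference: np.ndarray | None = None) -> SpectraSet:
    """Multiplicative scatter correction against ``reference`` (default:
    the mean spectrum).  Each sample is modelled as ``R_i = b_i ref + a_i``
    by least squares and returned as ``(R_i - a_i) / b_i``."""
    r = spectra.reflectance
    if reference is None:
        if spectra.n_samples < 2:
            raise InvalidParameterError("MSC needs >= 2 samples when no reference is given")
        ref = r.mean(axis=0)
    else:
        ref = np.asarray(reference, dtype=float)
        if len(ref) != spectra.n_wavelengths:
            raise InvalidParameterError("reference length must match wavelength grid")
    ref_c = ref - ref.mean()
    denom = float(ref_c @ ref_c)
    if denom == 0:
        raise DegenerateInputError("reference spectrum has zero variance")
    b = (r - r.mean(axis=1, keepdims=True)) @ ref_c / denom
    a = r.mean(axis=1) - b * ref.mean()
    corrected = (r - a[:, None]) / b[:, None]
    return replace(spectra, reflectance=corrected)


def snv(spectra: SpectraSet) -> SpectraSet:
    """Standard normal variate: each spectrum centered to mean 0 and scaled
    to unit standard deviation across wavelengths."""
    r = spectra.reflectance
    sd = r.std(axis=1, ddof=0)
    if np.any(sd == 0):
        raise DegenerateInputError("constant spectrum cannot be SNV-transformed")
    out = (r - r.mean(axis=1, keepdims=True)) / sd[:, None]
    return replace(spectra, reflectance=out)
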