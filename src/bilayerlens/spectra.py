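"""Laurdan emission-spectrum analysis.

Laurdan's emission red-shifts with increasing hydration/dipolar relaxation
around its fluorophore, so the intensity-weighted mean emission wavelength
(spectral centre of mass, COM) is a single-number readout of local membrane
fluidity.  This module normalises spectra, computes COMs on a configurable
wavelength window, and tracks COM shifts against steroid concentration.

The COM uses trapezoid quadrature weights so non-uniform wavelength grids
(spectrograph pixels map non-linearly to nm) are handled correctly; it is
invariant to any multiplicative rescaling of the intensity, hence to the
normalisation mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EmissionSpectrum",
    "SpectralSeries",
    "normalize_spectrum",
    "center_of_mass",
    "average_spectra",
    "com_vs_concentration",
    "DEFAULT_RANGE_NM",
]

#: Default integration window (nm) — the Laurdan emission band transmitted by
#: a 380 nm long-pass detection path.
DEFAULT_RANGE_NM = (400.0, 550.0)


@dataclass
class EmissionSpectrum:
    wavelength_nm: np.ndarray
    intensity: np.ndarray
    label: str = ""
    mol_percent: float | None = None
    composition: str = ""
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavelength_nm.shape != self.intensity.shape:
            raise ValueError("wavelength and intensity grids must match")
        if self.wavelength_nm.size < 3:
            raise ValueError("a spectrum needs at least 3 points")
        if np.any(np.diff(self.wavelength_nm) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")


def _trapezoid_weights(x: np.ndarray) -> np.ndarray:
    """Quadrature weights such that sum(w * f) == trapz(f, x)."""
    w = np.zeros_like(x)
    dx = np.diff(x)
    w[:-1] += dx / 2.0
    w[1:] += dx / 2.0
    return w


def normalize_spectrum(spectrum: EmissionSpectrum, mode: str = "peak") -> EmissionSpectrum:
    """Return a copy normalised to unit peak or unit trapezoidal area."""
    total = float(np.sum(spectrum.intensity))
    if total <= 0:
        raise ValueError("cannot normalise an all-zero spectrum")
    if mode == "peak":
        scale = float(np.max(spectrum.intensity))
    elif mode == "area":
        scale = float(np.trapezoid(spectrum.intensity, spectrum.wavelength_nm))
    else:
        raise ValueError(f"unknown normalisation mode {mode!r}")
    return EmissionSpectrum(
        spectrum.wavelength_nm.copy(), spectrum.intensity / scale,
        label=spectrum.label, mol_percent=spectrum.mol_percent,
        composition=spectrum.composition, truth=dict(spectrum.truth),
    )


def center_of_mass(
    spectrum: EmissionSpectrum, range_nm: tuple[float, float] = DEFAULT_RANGE_NM
) -> float:
    """Spectral centre of mass over ``range_nm``:
    ``sum(w * lambda * I) / sum(w * I)`` with trapezoid weights ``w``."""
    lo, hi = range_nm
    mask = (spectrum.wavelength_nm >= lo) & (spectrum.wavelength_nm <= hi)
    if np.count_nonzero(mask) < 2:
        raise ValueError("wavelength range selects fewer than 2 grid points")
    lam = spectrum.wavelength_nm[mask]
    inten = spectrum.intensity[mask]
    w = _trapezoid_weights(lam)
    denom = float(np.sum(w * inten))
    if denom <= 0:
        raise ValueError("zero total intensity in range: COM undefined")
    return float(np.sum(w * lam * inten) / denom)


def average_spectra(spectra: Sequence[EmissionSpectrum], mode: str = "peak") -> EmissionSpectrum:
    """Pointwise mean of per-spectrum-normalised spectra on a shared grid."""
    if not spectra:
        raise ValueError("no spectra to average")
    grid = spectra[0].wavelength_nm
    for s in spectra[1:]:
        if s.wavelength_nm.shape != grid.shape or not np.allclose(s.wavelength_nm, grid):
            raise ValueError("spectra are on different wavelength grids (no silent resampling)")
    stack = np.stack([normalize_spectrum(s, mode).intensity for s in spectra])
    return EmissionSpectrum(grid.copy(), stack.mean(axis=0), label=f"mean(n={len(spectra)})")


@dataclass
class SpectralSeries:
    """Per-concentration COM statistics with shifts against the 0 mol%
    reference (blue shift = negative delta)."""

    mol_percent: np.ndarray
    mean_com_nm: np.ndarray
    sd_com_nm: np.ndarray
    n: np.ndarray
    delta_vs_ref_nm: np.ndarray
    sd_defined: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mol_percent": self.mol_percent,
                "mean_com_nm": self.mean_com_nm,
                "sd_com_nm": self.sd_com_nm,
                "n": self.n,
                "delta_vs_ref_nm": self.delta_vs_ref_nm,
            }
        )


def com_vs_concentration(
    spectra: Iterable[EmissionSpectrum],
    range_nm: tuple[float, float] = DEFAULT_RANGE_NM,
) -> SpectralSeries:
    """Group labelled spectra by mol%, average COMs, and report shifts
    relative to the 0 mol% reference."""
    groups: dict[float, list[float]] = {}
    for s in spectra:
        if s.mol_percent is None:
            raise ValueError(f"spectrum {s.label!r} lacks a mol_percent label")
        if not 0.0 <= s.mol_percent <= 100.0:
            raise ValueError("mol_percent must be in [0, 100]")
        groups.setdefault(float(s.mol_percent), []).append(center_of_mass(s, range_nm))
    if 0.0 not in groups:
        raise ValueError("missing 0 mol% reference spectra")
    concs = np.array(sorted(groups))
    means = np.array([np.mean(groups[c]) for c in concs])
    ns = np.array([len(groups[c]) for c in concs])
    sds = np.array(
        [np.std(groups[c], ddof=1) if len(groups[c]) > 1 else np.nan for c in concs]
    )
    ref = means[concs == 0.0][0]
    return SpectralSeries(
        mol_percent=concs, mean_com_nm=means, sd_com_nm=sds, n=ns,
        delta_vs_ref_nm=means - ref, sd_defined=ns > 1,
    )
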