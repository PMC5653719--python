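"""Broadband emission spectra and their plain-text file format.

A spectrum is a discrete set of (wavelength [nm], relative weight) samples
with strictly increasing wavelengths and weights normalized to sum to one.
Photons drawn from a broadband source pick their wavelength by inverse-CDF
sampling over these weights.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class SpectrumFormatError(ValueError):
    """Malformed spectrum file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class EmissionSpectrum:
    wavelengths_nm: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if wl.ndim != 1 or wl.shape != w.shape or wl.size == 0:
            raise ValueError("wavelengths and weights must be equal-length 1-D arrays")
        if wl.size > 1 and not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        total = w.sum()
        if total <= 0:
            raise ValueError("at least one weight must be positive")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "weights", w / total)

    @classmethod
    def monochromatic(cls, wavelength_nm: float) -> "EmissionSpectrum":
        return cls(np.array([float(wavelength_nm)]), np.array([1.0]))

    @property
    def is_monochromatic(self) -> bool:
        return self.wavelengths_nm.size == 1

    def cdf(self) -> np.ndarray:
        """Cumulative weights for inverse-CDF wavelength sampling."""
        c = np.cumsum(self.weights)
        c[-1] = 1.0
        return c

    def mean_wavelength_nm(self) -> float:
        return float(np.dot(self.wavelengths_nm, self.weights))


def generate_ipl_spectrum(lam_min_nm: float = 400.0, lam_max_nm: float = 1200.0,
                          n_samples: int = 81, cutoff_filter_nm: float = 400.0,
                          ) -> EmissionSpectrum:
    """Synthetic filtered xenon-flashlamp (IPL) emission spectrum.

    Smooth broadband envelope: a visible hump near 560 nm plus a weaker
    near-infrared shoulder near 900 nm, which is the qualitative shape of a
    filtered flashlamp discharge.  Weights are exactly zero below the
    cutoff filter and normalized to sum to one.  Deterministic for fixed
    arguments.
    """
    if not lam_min_nm < lam_max_nm:
        raise ValueError("lam_min_nm must be < lam_max_nm")
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    lam = np.linspace(lam_min_nm, lam_max_nm, int(n_samples))
    w = np.exp(-(((lam - 560.0) / 170.0) ** 2)) + 0.45 * np.exp(-(((lam - 900.0) / 260.0) ** 2))
    w[lam < cutoff_filter_nm] = 0.0
    if w.sum() <= 0:
        raise ValueError("cutoff filter removed the whole band")
    return EmissionSpectrum(lam, w)


def default_study_spectrum(variant: str) -> EmissionSpectrum:
    """The broadband spectrum belonging to a named study set-up.

    The beam-width study was run with a 525-1100 nm filtered band; other
    set-ups use the full 400-1200 nm IPL band.
    """
    if variant == "beamwidth_study":
        return generate_ipl_spectrum(525.0, 1100.0, 81, 525.0)
    return generate_ipl_spectrum()


HEADER = "wavelength_nm,relative_weight"


def write_spectrum(path, spectrum: EmissionSpectrum) -> None:
    with open(path, "w") as fh:
        fh.write(HEADER + "\n")
        for lam, w in zip(spectrum.wavelengths_nm, spectrum.weights):
            fh.write(f"{lam:.9g},{w:.12e}\n")


def read_spectrum(path) -> EmissionSpectrum:
    """Read a two-column delimited spectrum file (header line required).

    Weights are re-normalized on read; malformed rows raise
    :class:`SpectrumFormatError` with the line number.
    """
    wavelengths: list[float] = []
    weights: list[float] = []
    with open(path) as fh:
        lines = fh.readlines()
    if not lines:
        raise SpectrumFormatError("empty file", line=1)
    for lineno, raw in enumerate(lines[1:], start=2):
        text = raw.strip()
        if not text or text.startswith("#"):
            continue
        parts = text.split(",")
        if len(parts) != 2:
            raise SpectrumFormatError(f"expected 2 comma-separated fields, got {len(parts)}", lineno)
        try:
            lam, w = float(parts[0]), float(parts[1])
        except ValueError:
            raise SpectrumFormatError(f"non-numeric value in {text!r}", lineno) from None
        if w < 0:
            raise SpectrumFormatError(f"negative weight {w}", lineno)
        if wavelengths and lam <= wavelengths[-1]:
            raise SpectrumFormatError(f"wavelengths not strictly increasing at {lam}", lineno)
        wavelengths.append(lam)
        weights.append(w)
    if not wavelengths:
        raise SpectrumFormatError("no data rows", line=len(lines))
    return EmissionSpectrum(np.array(wavelengths), np.array(weights))
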