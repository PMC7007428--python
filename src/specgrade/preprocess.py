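"""Spectral preprocessing: fingerprint truncation, Savitzky-Golay second
derivative, vector normalisation.

The chain deliberately removes the dominant nuisance variation of ATR
measurements: differentiation annihilates constant and linear baselines,
and dividing each spectrum by its Euclidean norm removes multiplicative
gain, so two spectra differing only by gain and a linear baseline become
identical after :func:`preprocess`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_coeffs, savgol_filter

from .core import SpectralDataset


@dataclass(frozen=True)
class PreprocessParams:
    """Defaults follow the standard biofingerprint protocol: 1800-900 cm^-1
    window, 7-point quadratic Savitzky-Golay second derivative, vector
    normalisation."""

    fp_lo: float = 900.0
    fp_hi: float = 1800.0
    window: int = 7
    polyorder: int = 2
    deriv: int = 2
    normalisation: str = "vector"

    def __post_init__(self) -> None:
        if self.window % 2 == 0 or self.window < self.polyorder + 1:
            raise ValueError("window must be odd and >= polyorder + 1")
        if self.deriv > self.polyorder:
            raise ValueError("deriv must be <= polyorder")
        if not self.fp_lo < self.fp_hi:
            raise ValueError("fp_lo must be < fp_hi")
        if self.normalisation != "vector":
            raise ValueError(f"unknown normalisation {self.normalisation!r}")


def truncate(ds: SpectralDataset, fp_lo: float = 900.0, fp_hi: float = 1800.0) -> SpectralDataset:
    """Keep axis points with ``fp_lo <= wavenumber <= fp_hi`` (closed interval)."""
    mask = (ds.wavenumbers >= fp_lo) & (ds.wavenumbers <= fp_hi)
    if not mask.any():
        raise ValueError(
            f"truncation window [{fp_lo}, {fp_hi}] does not intersect the axis "
            f"[{ds.wavenumbers.min()}, {ds.wavenumbers.max()}]"
        )
    out = SpectralDataset(
        wavenumbers=ds.wavenumbers[mask],
        intensities=ds.intensities[:, mask],
        spectrum_ids=ds.spectrum_ids,
        patient_ids=ds.patient_ids,
        labels=ds.labels,
        stage_tag="truncated",
    )
    return out


def sg_kernel(window: int, polyorder: int, deriv: int, spacing: float = 1.0) -> np.ndarray:
    """Savitzky-Golay convolution coefficients for the window centre.

    Returned in window order (offset -h .. +h) so that
    ``kernel @ y[i-h : i+h+1]`` estimates the ``deriv``-th derivative of the
    least-squares ``polyorder`` fit at point ``i``, scaled by
    ``spacing**-deriv``.  Symmetric for even derivative orders.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window < polyorder + 1:
        raise ValueError("window must be >= polyorder + 1")
    if deriv > polyorder:
        raise ValueError("deriv must be <= polyorder")
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    return savgol_coeffs(window, polyorder, deriv=deriv, delta=spacing, use="dot")


def second_derivative(ds: SpectralDataset, params: PreprocessParams = PreprocessParams()) -> SpectralDataset:
    """Savitzky-Golay derivative filter along the wavenumber axis.

    Interior points come from centred windows; each edge point from the
    nearest fully interior polynomial fit evaluated at the edge offset, so
    the output has the same length as the input.  The sign convention is the
    mathematical derivative with respect to wavenumber (absorbance peaks
    yield negative second-derivative lobes).
    """
    if ds.n_points < params.window:
        raise ValueError(
            f"need at least {params.window} axis points, have {ds.n_points}"
        )
    spacing = ds.spacing
    deriv = savgol_filter(
        ds.intensities,
        window_length=params.window,
        polyorder=params.polyorder,
        deriv=params.deriv,
        delta=spacing,
        axis=1,
        mode="interp",
    )
    # savgol_filter differentiates with respect to column index; on a
    # descending axis each odd derivative flips sign.
    if params.deriv % 2 == 1 and ds.wavenumbers[0] > ds.wavenumbers[-1]:
        deriv = -deriv
    return ds.with_intensities(deriv, stage_tag="derivative")


def vector_normalize(ds: SpectralDataset) -> SpectralDataset:
    """Scale every spectrum to unit Euclidean norm."""
    norms = np.linalg.norm(ds.intensities, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ValueError(
            f"cannot vector-normalise all-zero spectrum {ds.spectrum_ids[zero[0]]!r}"
        )
    return ds.with_intensities(ds.intensities / norms[:, None], stage_tag="normalized")


def preprocess(ds: SpectralDataset, params: PreprocessParams = PreprocessParams()) -> SpectralDataset:
    """Truncate to the fingerprint window, differentiate, vector-normalise."""
    out = truncate(ds, params.fp_lo, params.fp_hi)
    out = second_derivative(out, params)
    return vector_normalize(out)
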