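"""Deterministic spectral preprocessing.

Pipeline order: baseline offset at a single anchor wavenumber, truncation to
the working range, Savitzky-Golay second derivative (15-point, 3rd-order by
default). The constant offset is mathematically irrelevant after a second
derivative but is retained because the non-derivative intermediate feeds the
quality metrics.

Derivatives are taken with respect to wavenumber (units: absorbance per
cm^-2), using the physical grid spacing, so features are comparable across
grids. Edge points use a shrinking-window local polynomial fit, preserving
the vector length.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .errors import ConfigError, DataError
from .spectrum import Spectrum, nearest_index


@dataclass(frozen=True)
class PreprocessConfig:
    baseline_anchor: float = 2800.0
    trunc_high: float = 4000.0
    trunc_low: float = 850.0
    sg_window: int = 15
    sg_polyorder: int = 3
    sg_deriv: int = 2

    def __post_init__(self) -> None:
        if self.sg_window % 2 != 1:
            raise ConfigError("sg_window must be odd")
        if not (self.sg_polyorder < self.sg_window):
            raise ConfigError("sg_polyorder must be < sg_window")
        if self.sg_deriv > self.sg_polyorder:
            raise ConfigError("sg_deriv must be <= sg_polyorder")
        if not (self.trunc_low < self.baseline_anchor < self.trunc_high):
            raise ConfigError("baseline anchor must lie inside the truncation range")


def baseline_offset(s: Spectrum, anchor: float = 2800.0) -> Spectrum:
    """Subtract the absorbance at the grid point nearest the anchor."""
    i = nearest_index(s.wavenumbers, anchor)
    return s.replace(absorbance=s.absorbance - s.absorbance[i])


def truncate(s: Spectrum, high: float = 4000.0, low: float = 850.0) -> Spectrum:
    """Keep grid points with low <= nu <= high (closed interval)."""
    if low >= high:
        raise ConfigError("truncation needs low < high")
    keep = (s.wavenumbers >= low) & (s.wavenumbers <= high)
    if not keep.any():
        raise DataError("truncation range contains no grid points")
    return s.replace(wavenumbers=s.wavenumbers[keep], absorbance=s.absorbance[keep])


def _edge_functionals(n: int, window: int, polyorder: int, deriv: int,
                      spacing: float) -> list[tuple[int, np.ndarray, np.ndarray]]:
    """Linear functionals giving the derivative at points too close to an
    edge for a centred window: fit a polynomial of ``polyorder`` on the
    truncated (shrinking) window in physical wavenumber offsets."""
    half = window // 2
    out = []
    for i in list(range(half)) + list(range(n - half, n)):
        idx = np.arange(max(0, i - half), min(n - 1, i + half) + 1)
        # physical offset nu_j - nu_i = (i - j) * spacing on a descending axis
        x = (i - idx) * spacing
        X = np.vander(x, polyorder + 1, increasing=True)
        coeffs = np.linalg.pinv(X)[deriv] * float(np.prod(range(1, deriv + 1)))
        out.append((i, idx, coeffs))
    return out


def sg_derivative_matrix(absorbance: np.ndarray, spacing: float,
                         window: int = 15, polyorder: int = 3,
                         deriv: int = 2) -> np.ndarray:
    """Savitzky-Golay derivative of each row, physical-units scaling.

    Interior points use the standard centred SG convolution; the ``window//2``
    points at each edge use shrinking-window local least squares.
    """
    A = np.atleast_2d(np.asarray(absorbance, dtype=float))
    n = A.shape[1]
    if n < window:
        raise DataError(f"spectrum length {n} shorter than SG window {window}")
    # even derivatives are direction-invariant, so the descending axis can be
    # treated as ascending-index with positive spacing
    out = savgol_filter(A, window, polyorder, deriv=deriv, delta=spacing, axis=1)
    if deriv % 2 == 1:
        out = -out  # d/dnu = -d/dindex on a descending axis
    for i, idx, coeffs in _edge_functionals(n, window, polyorder, deriv, spacing):
        out[:, i] = A[:, idx] @ coeffs
    return out if absorbance.ndim == 2 else out[0]


def sg_second_derivative(s: Spectrum, cfg: PreprocessConfig = PreprocessConfig()) -> Spectrum:
    spacing = float(abs(np.median(np.diff(s.wavenumbers))))
    d2 = sg_derivative_matrix(s.absorbance, spacing, cfg.sg_window,
                              cfg.sg_polyorder, cfg.sg_deriv)
    return s.replace(absorbance=d2)


def preprocess_for_model(s: Spectrum, cfg: PreprocessConfig = PreprocessConfig()) -> Spectrum:
    """Offset -> truncate -> SG second derivative."""
    out = baseline_offset(s, cfg.baseline_anchor)
    out = truncate(out, cfg.trunc_high, cfg.trunc_low)
    return sg_second_derivative(out, cfg)


def preprocess_matrix(wavenumbers: np.ndarray, absorbance: np.ndarray,
                      cfg: PreprocessConfig = PreprocessConfig()
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised ``preprocess_for_model`` over rows of a spectra matrix."""
    A = np.atleast_2d(np.asarray(absorbance, dtype=float))
    i = nearest_index(wavenumbers, cfg.baseline_anchor)
    A = A - A[:, [i]]
    keep = (wavenumbers >= cfg.trunc_low) & (wavenumbers <= cfg.trunc_high)
    if not keep.any():
        raise DataError("truncation range contains no grid points")
    nu = wavenumbers[keep]
    spacing = float(abs(np.median(np.diff(nu))))
    d2 = sg_derivative_matrix(A[:, keep], spacing, cfg.sg_window,
                              cfg.sg_polyorder, cfg.sg_deriv)
    return nu, d2
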