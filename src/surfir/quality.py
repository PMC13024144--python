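"""Spectral quality metrics on non-derivative absorbance spectra.

The headline metric is the 2920 cm^-1 CH2 antisymmetric-stretch peak height
over a two-anchor linear baseline, and its SNR against the RMS noise of the
featureless 2200-2000 cm^-1 region. The 2945-2880 cm^-1 peak area and the
1740 cm^-1 ester-carbonyl height serve as robustness companions. %RSD is the
scale-free precision summary, 100 * SD / mean.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigError, DataError, UndefinedMetricError
from .spectrum import Spectrum, nearest_index

CH_WINDOW = (2935.0, 2905.0)
CH_ANCHORS = (3000.0, 2800.0)
CARBONYL_WINDOW = (1750.0, 1730.0)
CARBONYL_ANCHORS = (1780.0, 1700.0)
NOISE_REGION = (2200.0, 2000.0)
CH_AREA_REGION = (2945.0, 2880.0)


def _region_mask(nu: np.ndarray, region: tuple[float, float]) -> np.ndarray:
    lo, hi = min(region), max(region)
    mask = (nu >= lo) & (nu <= hi)
    if not mask.any():
        raise ConfigError(f"region {region} contains no grid points")
    return mask


def _linear_baseline(s: Spectrum, anchors: tuple[float, float]) -> tuple[float, float]:
    """Slope/intercept of the line through the two anchor grid points."""
    i1 = nearest_index(s.wavenumbers, anchors[0])
    i2 = nearest_index(s.wavenumbers, anchors[1])
    x1, x2 = s.wavenumbers[i1], s.wavenumbers[i2]
    y1, y2 = s.absorbance[i1], s.absorbance[i2]
    if x1 == x2:
        raise ConfigError("baseline anchors coincide on the grid")
    slope = (y2 - y1) / (x2 - x1)
    return slope, y1 - slope * x1


def peak_height(s: Spectrum, search_window: tuple[float, float] = CH_WINDOW,
                baseline_anchors: tuple[float, float] = CH_ANCHORS) -> float:
    """Max absorbance in the window minus the anchor-to-anchor linear
    baseline at the argmax. May be negative when the band is absent."""
    if not (min(baseline_anchors) <= min(search_window)
            and max(baseline_anchors) >= max(search_window)):
        raise ConfigError("baseline anchors must bracket the search window")
    mask = _region_mask(s.wavenumbers, search_window)
    idx = np.flatnonzero(mask)
    j = idx[int(np.argmax(s.absorbance[idx]))]
    slope, intercept = _linear_baseline(s, baseline_anchors)
    return float(s.absorbance[j] - (slope * s.wavenumbers[j] + intercept))


def rms_noise(s: Spectrum, region: tuple[float, float] = NOISE_REGION) -> float:
    """RMS of residuals about the least-squares line over a flat region."""
    mask = _region_mask(s.wavenumbers, region)
    if mask.sum() < 10:
        raise DataError("noise region needs at least 10 grid points")
    x, y = s.wavenumbers[mask], s.absorbance[mask]
    coeffs = np.polyfit(x, y, 1)
    resid = y - np.polyval(coeffs, x)
    return float(np.sqrt(np.mean(resid**2)))


def snr(s: Spectrum) -> float:
    """2920 cm^-1 peak height over 2200-2000 cm^-1 RMS noise."""
    noise = rms_noise(s)
    if noise == 0:
        raise UndefinedMetricError("SNR undefined: RMS noise is exactly zero")
    return peak_height(s) / noise


def peak_area(s: Spectrum, region: tuple[float, float] = CH_AREA_REGION,
              baseline_anchors: tuple[float, float] = CH_ANCHORS) -> float:
    """Trapezoidal integral of baseline-corrected absorbance over a region
    (absorbance * cm^-1, integrated in ascending wavenumber)."""
    mask = _region_mask(s.wavenumbers, region)
    slope, intercept = _linear_baseline(s, baseline_anchors)
    nu = s.wavenumbers[mask]
    y = s.absorbance[mask] - (slope * nu + intercept)
    order = np.argsort(nu)
    return float(np.trapezoid(y[order], nu[order]))


def percent_rsd(values: Sequence[float]) -> float:
    """100 * sample SD (n-1 denominator) / mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise DataError("%RSD needs at least two values")
    mean = v.mean()
    if mean == 0:
        raise UndefinedMetricError("%RSD undefined: zero mean")
    return float(100.0 * v.std(ddof=1) / mean)


@dataclass(frozen=True)
class QualityMetrics:
    peak_height_2920: float
    rms_noise: float
    snr: float
    peak_area_2945_2880: float
    peak_height_1740: float


def quality_metrics(s: Spectrum) -> QualityMetrics:
    """All per-spectrum quality metrics at their default regions."""
    noise = rms_noise(s)
    height = peak_height(s)
    return QualityMetrics(
        peak_height_2920=height,
        rms_noise=noise,
        snr=height / noise if noise > 0 else float("nan"),
        peak_area_2945_2880=peak_area(s),
        peak_height_1740=peak_height(s, CARBONYL_WINDOW, CARBONYL_ANCHORS),
    )
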