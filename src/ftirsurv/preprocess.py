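"""Baseline correction, normalisation, smoothing and band windowing.

The canonical order of operations is fixed: baseline correction over the full
recorded range, then normalisation over the full range, then (optionally)
smoothing, then extraction of the analysis band.  Normalising before
windowing keeps group mean and difference spectra comparable across the whole
recorded range; the peak position inside a band is invariant to global
positive scaling, so the feature itself is unaffected by this choice.

Defaults follow common practice for ATR-FTIR tissue spectra: rubberband
(lower convex hull) baseline and unit-Euclidean-norm ("vector")
normalisation, no smoothing, analysis band [950, 1100] cm^-1 inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .io import Spectrum

__all__ = [
    "PreprocessConfig",
    "correct_baseline",
    "normalize",
    "smooth",
    "extract_window",
    "preprocess",
    "rubberband_baseline",
]

DEFAULT_BAND = (950.0, 1100.0)


@dataclass(frozen=True)
class PreprocessConfig:
    """Configuration for the spectral preprocessing pipeline.

    Parameters
    ----------
    baseline_method : {"rubberband", "polynomial", "none"}
        Rubberband subtracts the lower convex hull of the spectrum;
        polynomial subtracts an iteratively refit degree-``polynomial_degree``
        polynomial (points above the fit are excluded each round until the
        support set stabilises).
    normalization : {"vector", "minmax", "none"}
        Vector scales to unit Euclidean norm over the full recorded range;
        minmax maps the minimum to 0 and the maximum to 1.
    smoothing : {"none", "savitzky_golay"}
        Savitzky-Golay requires a uniform grid, an odd ``smoothing_window``
        and ``smoothing_order < smoothing_window``.
    analysis_band : (float, float)
        Closed wavenumber interval [lo, hi] in cm^-1 used for peak picking.
    """

    baseline_method: str = "rubberband"
    polynomial_degree: int = 2
    normalization: str = "vector"
    smoothing: str = "none"
    smoothing_window: int = 7
    smoothing_order: int = 2
    analysis_band: tuple[float, float] = field(default=DEFAULT_BAND)

    def __post_init__(self) -> None:
        if self.baseline_method not in ("rubberband", "polynomial", "none"):
            raise ValueError(f"unknown baseline method {self.baseline_method!r}")
        if self.normalization not in ("vector", "minmax", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.smoothing not in ("none", "savitzky_golay"):
            raise ValueError(f"unknown smoothing {self.smoothing!r}")
        if self.smoothing == "savitzky_golay":
            if self.smoothing_window < 3 or self.smoothing_window % 2 == 0:
                raise ValueError("smoothing window must be odd and >= 3")
            if self.smoothing_order >= self.smoothing_window:
                raise ValueError("smoothing order must be < window")
        lo, hi = self.analysis_band
        if not lo < hi:
            raise ValueError(f"analysis band [{lo}, {hi}] must have lo < hi")


def _lower_hull_indices(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Indices of the lower convex hull of the point set, left to right."""
    hull: list[int] = []
    for i in range(x.size):
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            # drop i2 if it lies on or above the chord i1 -> i
            cross = (x[i2] - x[i1]) * (y[i] - y[i1]) - (x[i] - x[i1]) * (y[i2] - y[i1])
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return np.array(hull)


def rubberband_baseline(s: Spectrum) -> np.ndarray:
    """Baseline estimated as the lower convex hull of the spectrum."""
    idx = _lower_hull_indices(s.wavenumbers, s.absorbance)
    return np.interp(s.wavenumbers, s.wavenumbers[idx], s.absorbance[idx])


def _polynomial_baseline(s: Spectrum, degree: int, max_iter: int = 100) -> np.ndarray:
    x, y = s.wavenumbers, s.absorbance
    if x.size < degree + 2:
        raise ValueError(
            f"polynomial baseline of degree {degree} needs >= {degree + 2} points, got {x.size}"
        )
    # centre/scale x for numerical conditioning
    xs = (x - x.mean()) / max(np.ptp(x) / 2, 1e-12)
    mask = np.ones(x.size, dtype=bool)
    fit = np.zeros_like(y)
    for _ in range(max_iter):
        coeffs = np.polynomial.polynomial.polyfit(xs[mask], y[mask], degree)
        fit = np.polynomial.polynomial.polyval(xs, coeffs)
        new_mask = y <= fit + 1e-12 * max(1.0, np.abs(y).max())
        if new_mask.sum() < degree + 2 or np.array_equal(new_mask, mask):
            break
        mask = new_mask
    return fit


def correct_baseline(s: Spectrum, config: PreprocessConfig) -> Spectrum:
    """Subtract the configured baseline estimate; the grid is unchanged."""
    if config.baseline_method == "none":
        return s
    if config.baseline_method == "rubberband":
        baseline = rubberband_baseline(s)
    else:
        baseline = _polynomial_baseline(s, config.polynomial_degree)
    return s.with_absorbance(s.absorbance - baseline)


def normalize(s: Spectrum, config: PreprocessConfig) -> Spectrum:
    """Scale absorbance: unit Euclidean norm ("vector") or min-max to [0, 1]."""
    if config.normalization == "none":
        return s
    y = s.absorbance
    if config.normalization == "vector":
        norm = float(np.linalg.norm(y))
        if norm == 0.0:
            raise ValueError("cannot vector-normalize an all-zero spectrum")
        return s.with_absorbance(y / norm)
    span = float(y.max() - y.min())
    if span == 0.0:
        raise ValueError("cannot min-max normalize a constant spectrum")
    return s.with_absorbance((y - y.min()) / span)


def smooth(s: Spectrum, config: PreprocessConfig) -> Spectrum:
    """Savitzky-Golay smoothing; identity when smoothing is disabled."""
    if config.smoothing == "none":
        return s
    steps = np.diff(s.wavenumbers)
    if np.ptp(steps) > 1e-6 * steps.mean():
        raise ValueError(
            "Savitzky-Golay smoothing requires a uniform wavenumber grid; "
            "use resample_to_grid first"
        )
    y = savgol_filter(
        s.absorbance, window_length=config.smoothing_window, polyorder=config.smoothing_order
    )
    return s.with_absorbance(y)


def extract_window(s: Spectrum, band: tuple[float, float]) -> Spectrum:
    """Sub-spectrum with wavenumbers in the closed interval [lo, hi]."""
    lo, hi = band
    mask = (s.wavenumbers >= lo) & (s.wavenumbers <= hi)
    if not mask.any():
        raise ValueError(
            f"band [{lo}, {hi}] does not intersect the spectrum support "
            f"[{s.wavenumbers[0]}, {s.wavenumbers[-1]}]"
        )
    from dataclasses import replace

    return replace(s, wavenumbers=s.wavenumbers[mask], absorbance=s.absorbance[mask])


def preprocess(s: Spectrum, config: PreprocessConfig, *, window: bool = False) -> Spectrum:
    """Apply baseline -> normalisation -> smoothing (-> optional windowing)."""
    out = correct_baseline(s, config)
    out = normalize(out, config)
    out = smooth(out, config)
    if window:
        out = extract_window(out, config.analysis_band)
    return out
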