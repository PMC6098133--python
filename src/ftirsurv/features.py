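"""Band peak-position biomarker extraction and per-patient feature tables.

The biomarker of interest is the wavenumber of the absorbance maximum within
the analysis band (default 950-1100 cm^-1) of a preprocessed spectrum.  It is
extracted per tissue type and replicate, replicate values are aggregated per
patient (mean by default, rounded to the reporting resolution), and the two
paired shifts are formed:

``shift_tt_tb = t_t - t_b``
    movement of the band apex from diagnosis to post-chemotherapy resection;
``shift_tb_tn = t_b - t_n``
    displacement of the tumour apex relative to the patient's normal bone.

Normal bone (``t_n``) is unavailable for some patients; the corresponding
shift is then missing and the patient is retained for all analyses that do
not use it.  A patient with no tumour-at-biopsy (``t_b``) spectra is dropped
entirely — t_b anchors every analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import Spectrum
from .preprocess import DEFAULT_BAND, PreprocessConfig, extract_window, preprocess

logger = logging.getLogger(__name__)

__all__ = [
    "SpectralFeatures",
    "peak_position",
    "aggregate_replicates",
    "compute_patient_features",
    "features_table",
    "group_mean_spectrum",
    "difference_spectrum",
]

FEATURE_NAMES = ("t_b", "t_t", "t_n", "shift_tt_tb", "shift_tb_tn")


@dataclass(frozen=True)
class SpectralFeatures:
    """Per-patient band-apex wavenumbers (cm^-1) and paired shifts."""

    patient_id: str
    t_b: float | None = None
    t_t: float | None = None
    t_n: float | None = None

    @property
    def shift_tt_tb(self) -> float | None:
        if self.t_t is None or self.t_b is None:
            return None
        return self.t_t - self.t_b

    @property
    def shift_tb_tn(self) -> float | None:
        if self.t_b is None or self.t_n is None:
            return None
        return self.t_b - self.t_n

    def get(self, name: str) -> float | None:
        if name not in FEATURE_NAMES:
            raise KeyError(f"unknown feature {name!r}; expected one of {FEATURE_NAMES}")
        return getattr(self, name)


def peak_position(
    s: Spectrum,
    band: tuple[float, float] = DEFAULT_BAND,
    apex_mode: str = "grid",
) -> float:
    """Wavenumber of the absorbance maximum within the closed band.

    ``grid`` mode returns the wavenumber of the maximum sample; ties on the
    maximum are broken toward the lowest wavenumber.  ``quadratic`` mode
    refines the apex by the vertex of the parabola through the discrete
    maximum and its two neighbours, clamped to the band and reported at
    0.1 cm^-1 resolution; if the maximum sits at a band edge the grid value
    is returned with a warning.
    """
    in_band = int(np.sum((s.wavenumbers >= band[0]) & (s.wavenumbers <= band[1])))
    if in_band < 3:
        raise ValueError(f"band {band} covers only {in_band} point(s); need >= 3")
    win = extract_window(s, band)
    y = win.absorbance
    x = win.wavenumbers
    i = int(np.argmax(y))  # argmax returns the first maximum: lowest wavenumber
    if apex_mode == "grid":
        return float(x[i])
    if apex_mode != "quadratic":
        raise ValueError(f"unknown apex mode {apex_mode!r}")
    if i == 0 or i == y.size - 1:
        logger.warning(
            "band maximum at window edge (%.1f cm^-1); falling back to grid apex", x[i]
        )
        return float(x[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:  # flat triple: plateau, keep the grid apex
        return float(x[i])
    # vertex of the interpolating parabola on the (possibly non-uniform) grid
    x0, x1, x2 = x[i - 1], x[i], x[i + 1]
    d1 = (y1 - y0) / (x1 - x0)
    d2 = (y2 - y1) / (x2 - x1)
    vertex = (x0 + x1) / 2 + d1 * (x2 - x0) / (2 * (d1 - d2)) if d1 != d2 else x1
    vertex = min(max(float(vertex), band[0]), band[1])
    return round(vertex, 1)


def aggregate_replicates(
    values: Sequence[float],
    method: str = "mean",
    resolution: float | None = 1.0,
) -> float:
    """Combine replicate peak positions into one per-patient value.

    Arithmetic mean by default (median configurable), then rounded half-up to
    ``resolution`` cm^-1 (pass None to disable rounding).  Sub-triplicate
    inputs are accepted with a logged warning.
    """
    vals = [float(v) for v in values]
    if not vals:
        raise ValueError("no replicate values to aggregate")
    if len(vals) < 3:
        logger.warning("only %d replicate(s) available (triplicate expected)", len(vals))
    if method == "mean":
        agg = sum(vals) / len(vals)
    elif method == "median":
        agg = float(np.median(vals))
    else:
        raise ValueError(f"unknown aggregation method {method!r}")
    if resolution is None:
        return agg
    # half-up rounding, robust to float representation of .5
    return math.floor(agg / resolution + 0.5) * resolution


def compute_patient_features(
    spectra: Iterable[Spectrum],
    band: tuple[float, float] = DEFAULT_BAND,
    *,
    config: PreprocessConfig | None = None,
    apex_mode: str = "grid",
    aggregate: str = "positions",
    agg_method: str = "mean",
    resolution: float | None = 1.0,
    preprocessed: bool = False,
) -> list[SpectralFeatures]:
    """Extract per-patient features from a collection of spectra.

    Parameters
    ----------
    aggregate : {"positions", "spectra"}
        ``positions`` picks the peak per replicate and averages the peak
        positions; ``spectra`` averages the replicate spectra pointwise first
        and picks a single peak.
    preprocessed : bool
        Set True when the spectra are already baseline-corrected/normalised.
    """
    config = config or PreprocessConfig(analysis_band=band)
    groups: dict[tuple[str, str], list[Spectrum]] = {}
    order: list[str] = []
    for s in spectra:
        key = (s.patient_id, s.tissue_type)
        groups.setdefault(key, []).append(s)
        if s.patient_id not in order:
            order.append(s.patient_id)

    out: list[SpectralFeatures] = []
    for pid in order:
        values: dict[str, float] = {}
        for tissue in ("t_b", "t_t", "t_n"):
            reps = groups.get((pid, tissue))
            if not reps:
                continue
            processed = reps if preprocessed else [preprocess(r, config) for r in reps]
            if aggregate == "spectra":
                mean = group_mean_spectrum(processed)
                peak = peak_position(mean, band, apex_mode)
                values[tissue] = aggregate_replicates([peak], resolution=resolution)
            else:
                peaks = [peak_position(p, band, apex_mode) for p in processed]
                values[tissue] = aggregate_replicates(
                    peaks, method=agg_method, resolution=resolution
                )
        if "t_b" not in values:
            logger.warning("patient %s has no t_b spectra; excluded from features", pid)
            continue
        out.append(SpectralFeatures(patient_id=pid, **values))

    n = len(out)
    for name in FEATURE_NAMES:
        avail = sum(f.get(name) is not None for f in out)
        logger.info("feature %s available for %d/%d patients", name, avail, n)
    return out


def features_table(features: Sequence[SpectralFeatures]) -> pd.DataFrame:
    """Features as a DataFrame (one row per patient, NaN for missing)."""
    rows = [
        {
            "patient_id": f.patient_id,
            "t_b": f.t_b,
            "t_t": f.t_t,
            "t_n": f.t_n,
            "shift_tt_tb": f.shift_tt_tb,
            "shift_tb_tn": f.shift_tb_tn,
        }
        for f in features
    ]
    return pd.DataFrame(rows, columns=["patient_id", *FEATURE_NAMES])


def group_mean_spectrum(spectra: Sequence[Spectrum]) -> Spectrum:
    """Pointwise arithmetic mean of spectra sharing a common grid."""
    if len(spectra) == 0:
        raise ValueError("cannot average an empty group of spectra")
    grid = spectra[0].wavenumbers
    for s in spectra[1:]:
        if s.wavenumbers.shape != grid.shape or not np.array_equal(s.wavenumbers, grid):
            raise ValueError("spectra are on different grids; use resample_to_grid first")
    mean = np.mean([s.absorbance for s in spectra], axis=0)
    return spectra[0].with_absorbance(mean, patient_id="", meta={"group_size": len(spectra)})


def difference_spectrum(a: Spectrum, b: Spectrum) -> Spectrum:
    """Pointwise difference a - b on a common grid.

    The pipeline's reporting convention is (complete-remission mean) minus
    (relapse/progression mean); the orientation is recorded in the metadata
    of the returned spectrum by the caller.
    """
    if a.wavenumbers.shape != b.wavenumbers.shape or not np.array_equal(
        a.wavenumbers, b.wavenumbers
    ):
        raise ValueError("spectra are on different grids; use resample_to_grid first")
    return a.with_absorbance(a.absorbance - b.absorbance)
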