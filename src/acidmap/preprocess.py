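"""Spectrum preparation: peak-1 bounds/area, cropping and normalization.

The internal-standard band ("peak 1", nominally 311 1/cm; some instrument
tables list it at 331 1/cm — one and the same band here) is quantified
before the spectrum is cropped: its right trough ``x2`` is the intensity
minimum inside a fixed shift window, its left endpoint ``x1`` the first
point left of the peak maximum whose intensity falls back to the trough
level ``y2``, and its area the trapezoidal integral over [x1, x2]. The
model input then keeps a fixed 1-based index window (80th..335th points,
256 values, shifts <= 1700 1/cm), which excludes the peak-1 region, and is
divided by the peak-1 area so that chip gain cancels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .exceptions import NormalizationError, PeakBoundsError, WindowError
from .io import FeatureVector, RamanSpectrum, SpectraDataset

TROUGH_WINDOW = (360.0, 390.0)
KEEP_WINDOW = (80, 335)  # 1-based inclusive
MAX_SHIFT = 1700.0
#: how far left of the trough the peak maximum is searched for (1/cm)
PEAK_SEARCH_SPAN = 150.0


@dataclass(frozen=True)
class Peak1Bounds:
    """Integration endpoints of the internal-standard peak."""

    x1: float
    x2: float
    y2: float
    i1: int
    i2: int


def find_peak1_bounds(
    s: RamanSpectrum, trough_window: tuple[float, float] = TROUGH_WINDOW
) -> Peak1Bounds:
    """Locate peak-1 endpoints.

    ``x2`` is the shift of the minimum intensity strictly inside
    ``trough_window`` (ties toward the lower shift). The horizontal level
    ``y2`` through that trough is traced left from the peak maximum; the
    first sample at or below the level is ``x1``.
    """
    lo, hi = trough_window
    if s.shifts[0] > lo - 50.0 or s.shifts[-1] < hi:
        raise PeakBoundsError("spectrum does not cover the trough window plus 50 1/cm left")
    win = np.flatnonzero((s.shifts > lo) & (s.shifts < hi))
    if win.size == 0:
        raise PeakBoundsError("no samples inside the trough window")
    i2 = int(win[np.argmin(s.intensities[win])])  # argmin takes the first tie
    y2 = float(s.intensities[i2])

    left = np.flatnonzero((s.shifts < s.shifts[i2]) & (s.shifts >= s.shifts[i2] - PEAK_SEARCH_SPAN))
    if left.size == 0:
        raise PeakBoundsError("no samples left of the trough")
    ipk = int(left[np.argmax(s.intensities[left])])
    if s.intensities[ipk] <= y2:
        raise PeakBoundsError("no peak rises above the trough level left of x2")
    below = np.flatnonzero(s.intensities[:ipk] <= y2)
    if below.size == 0:
        raise PeakBoundsError("intensity never falls back to the trough level left of the peak")
    i1 = int(below[-1])
    return Peak1Bounds(x1=float(s.shifts[i1]), x2=float(s.shifts[i2]), y2=y2, i1=i1, i2=i2)


def peak1_area(s: RamanSpectrum, b: Peak1Bounds) -> float:
    """Trapezoidal integral of the raw intensity over [x1, x2] (counts/cm)."""
    sl = slice(b.i1, b.i2 + 1)
    return float(np.trapezoid(s.intensities[sl], s.shifts[sl]))


def crop_and_vectorize(
    s: RamanSpectrum,
    keep: tuple[int, int] = KEEP_WINDOW,
    max_shift: float = MAX_SHIFT,
    bounds: Peak1Bounds | None = None,
) -> FeatureVector:
    """Crop to the fixed index window and attach the peak-1 area.

    ``keep`` is 1-based inclusive, so the default (80, 335) yields 256
    values. Shifts above ``max_shift`` carry no information and must lie
    outside the window; the peak-1 region lies below it.
    """
    k0, k1 = keep
    if len(s) < k1:
        raise WindowError(f"spectrum has {len(s)} points, window needs {k1}")
    values = s.intensities[k0 - 1 : k1].copy()
    if s.shifts[k1 - 1] > max_shift + 1e-6:
        raise WindowError(
            f"crop window extends to {s.shifts[k1 - 1]:.1f} 1/cm, above the "
            f"{max_shift:.0f} 1/cm cutoff"
        )
    if bounds is None:
        bounds = find_peak1_bounds(s)
    area = peak1_area(s, bounds)
    return FeatureVector(
        values=values,
        peak1_area=area,
        chip_id=s.chip_id,
        nominal_ph=s.nominal_ph,
        ph_tag=s.ph_tag,
        replicate=s.replicate,
    )


def normalize(v: FeatureVector) -> FeatureVector:
    """Divide the window by the peak-1 area (internal-standard normalization)."""
    if not v.peak1_area > 0:
        raise NormalizationError(f"nonpositive peak-1 area {v.peak1_area}")
    return replace(v, values=v.values / v.peak1_area, normalized=True)


def featurize(s: RamanSpectrum, normalized: bool = True) -> FeatureVector:
    """Full preparation of one spectrum: bounds, area, crop, normalization."""
    v = crop_and_vectorize(s)
    return normalize(v) if normalized else v


def featurize_dataset(
    dataset: SpectraDataset, normalized: bool = True
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Prepare every spectrum of a dataset.

    Returns the feature matrix (n x 256), the peak-1 areas (n,) and the
    dataset's metadata table (aligned, copied).
    """
    vecs = np.empty((len(dataset), KEEP_WINDOW[1] - KEEP_WINDOW[0] + 1))
    areas = np.empty(len(dataset))
    for i, spec in enumerate(dataset.spectra):
        fv = featurize(spec, normalized=normalized)
        vecs[i] = fv.values
        areas[i] = fv.peak1_area
    return vecs, areas, dataset.table.copy()
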