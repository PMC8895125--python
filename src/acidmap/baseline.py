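"""Ratiometric ("traditional") pH calibration.

The chip's chemometric readout is the intensity ratio r = I527/I311 of the
acid-enhanced indolenium band to the pH-invariant internal standard, with
each height corrected by a local linear baseline. Per chip, r is close to
linear in pH over 5-8 and a straight-line fit serves as that chip's own
calibration. As a chip-agnostic control, a single four-parameter logistic
r(pH) is fitted across all chips and inverted for prediction; its failure
on offset chips is precisely what motivates the learned calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .exceptions import FitError, RatioError
from .io import RamanSpectrum

RESPONSIVE_PEAK = 527.0
REFERENCE_PEAK = 311.0
BASELINE_HALF_SPAN = 25.0
PH_RANGE = (5.0, 8.0)


def corrected_height(
    s: RamanSpectrum, center: float, half_span: float = BASELINE_HALF_SPAN
) -> float:
    """Peak height at ``center`` above a local linear baseline.

    The baseline is the chord through the spectrum at ``center +- half_span``
    (linearly interpolated); the height is the interpolated intensity at
    ``center`` minus the chord value there.
    """
    x0, x1 = center - half_span, center + half_span
    if s.shifts[0] > x0 or s.shifts[-1] < x1:
        raise RatioError(f"spectrum does not cover the {center} 1/cm neighborhood")
    y0, yc, y1 = np.interp([x0, center, x1], s.shifts, s.intensities)
    return float(yc - 0.5 * (y0 + y1))


def intensity_ratio(
    s: RamanSpectrum,
    responsive: float = RESPONSIVE_PEAK,
    reference: float = REFERENCE_PEAK,
) -> float:
    """Baseline-corrected height ratio of the responsive to the reference peak."""
    h_ref = corrected_height(s, reference)
    if h_ref <= 0:
        raise RatioError(f"nonpositive reference-peak height {h_ref:.3g}")
    return corrected_height(s, responsive) / h_ref


def fit_chip_linear(
    ratios: np.ndarray, phs: np.ndarray
) -> tuple[float, float, float]:
    """Least-squares line pH = a*r + b for one chip.

    Returns (a, b, residual SD). Requires at least two distinct pH levels.
    """
    ratios = np.asarray(ratios, dtype=float)
    phs = np.asarray(phs, dtype=float)
    if np.unique(np.round(phs, 6)).size < 2 or np.ptp(ratios) == 0:
        raise FitError("need >= 2 distinct pH levels with distinct ratios")
    a, b = np.polyfit(ratios, phs, 1)
    resid = phs - (a * ratios + b)
    return float(a), float(b), float(np.std(resid))


def master_calibration(
    reporter, grid: np.ndarray | None = None, ph_grid: np.ndarray | None = None
) -> tuple[float, float]:
    """Reference linear calibration of an ideal chip.

    Fit of pH on the intensity ratio of noise-free, baseline-free, unit-gain
    spectra of the given reporter over pH 5..8. This is the factory
    calibration against which every chip's pH-6.50 error (err) is judged.
    """
    from .simulate import ChipModel, canonical_grid, synth_spectrum

    if grid is None:
        grid = canonical_grid()
    if ph_grid is None:
        ph_grid = np.arange(5.0, 8.001, 0.25)
    ideal = ChipModel(chip_id="master", baseline_params=(0.0, 0.0, 0.0), noise_sigma=0.0)
    ratios = np.array(
        [
            intensity_ratio(synth_spectrum(ideal, reporter, float(ph), grid=grid, noise=False))
            for ph in ph_grid
        ]
    )
    a, b, _ = fit_chip_linear(ratios, np.asarray(ph_grid, dtype=float))
    return a, b


def _logistic4(ph, top, bottom, mid, slope):
    """Ratio as a 4-parameter logistic of pH (top = acidic plateau)."""
    return bottom + (top - bottom) / (1.0 + np.power(10.0, slope * (ph - mid)))


@dataclass
class RatioCalibration:
    """Fitted ratio calibrations: per-chip lines plus the global logistic."""

    per_chip: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    global_params: tuple[float, float, float, float] | None = None
    global_resid_sd: float | None = None
    ph_range: tuple[float, float] = PH_RANGE

    def predict_chip(self, chip_id: str, r: np.ndarray | float) -> np.ndarray | float:
        a, b, _ = self.per_chip[chip_id]
        return np.clip(a * np.asarray(r, dtype=float) + b, *self.ph_range)

    def predict_global(self, r: np.ndarray | float) -> np.ndarray | float:
        """Invert the global logistic; clipped to the calibrated pH range."""
        if self.global_params is None:
            raise FitError("global model not fitted")
        top, bottom, mid, slope = self.global_params
        r = np.asarray(r, dtype=float)
        # keep the argument of the inversion strictly inside (bottom, top)
        eps = 1e-9 * max(1.0, abs(top - bottom))
        rc = np.clip(r, min(top, bottom) + eps, max(top, bottom) - eps)
        u = (top - bottom) / (rc - bottom) - 1.0
        ph = mid + np.log10(np.clip(u, 1e-12, None)) / slope
        ph = np.where(r >= max(top, bottom), self.ph_range[0], ph)
        ph = np.where(r <= min(top, bottom), self.ph_range[1], ph)
        return np.clip(ph, *self.ph_range)


def fit_global_nonlinear(
    ratios: np.ndarray, phs: np.ndarray, calib: RatioCalibration | None = None
) -> RatioCalibration:
    """Fit the chip-agnostic 4-parameter-logistic control model.

    Requires data spanning at least 4 pH levels. The fitted curve is
    monotone decreasing in pH (larger ratio = more acidic).
    """
    ratios = np.asarray(ratios, dtype=float)
    phs = np.asarray(phs, dtype=float)
    if np.unique(np.round(phs, 6)).size < 4:
        raise FitError("global fit needs >= 4 distinct pH levels")
    p0 = (float(ratios.max()), float(ratios.min()), float(np.median(phs)), 1.0)
    try:
        popt, _ = curve_fit(
            _logistic4,
            phs,
            ratios,
            p0=p0,
            bounds=([0.0, 0.0, 2.0, 0.05], [np.inf, np.inf, 12.0, 10.0]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"global logistic fit did not converge: {exc}") from exc
    if popt[0] <= popt[1]:
        raise FitError("fitted logistic is not decreasing in pH")
    calib = calib or RatioCalibration()
    calib.global_params = tuple(float(p) for p in popt)
    calib.global_resid_sd = float(np.std(ratios - _logistic4(phs, *popt)))
    return calib


def save_calibration(calib: RatioCalibration, path: str) -> None:
    """Serialize a ratio calibration as a JSON document of named parameters."""
    import json

    doc = {
        "per_chip": {k: list(v) for k, v in calib.per_chip.items()},
        "global_params": list(calib.global_params) if calib.global_params else None,
        "global_resid_sd": calib.global_resid_sd,
        "ph_range": list(calib.ph_range),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_calibration(path: str) -> RatioCalibration:
    import json

    with open(path) as fh:
        doc = json.load(fh)
    return RatioCalibration(
        per_chip={k: tuple(v) for k, v in doc["per_chip"].items()},
        global_params=tuple(doc["global_params"]) if doc["global_params"] else None,
        global_resid_sd=doc["global_resid_sd"],
        ph_range=tuple(doc["ph_range"]),
    )


def predict_ph_regression(
    calib: RatioCalibration, s: RamanSpectrum, chip_id: str | None = None
) -> float:
    """pH estimate for one spectrum from the fitted ratio calibration.

    Uses the chip's own line when ``chip_id`` is known to the calibration,
    the global logistic otherwise. Always finite, clipped to pH 5-8.
    """
    r = intensity_ratio(s)
    if chip_id is not None and chip_id in calib.per_chip:
        return float(calib.predict_chip(chip_id, r))
    return float(calib.predict_global(r))
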