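"""Linear spectral calibration: pixel displacement -> emission wavelength.

The map is fitted against reference images in which known laser lines
(e.g. 405, 488, 532, 552, 637 nm) appear as vertical stripes in the
spectral image at measurable peak pixel positions.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class SpectralCalibration:
    slope: float              # nm per pixel
    intercept: float          # nm at zero displacement
    reference_offset: float   # px from spatial x to the zero-displacement column
    fit_residual_rms: float   # nm

    def __post_init__(self):
        if self.slope == 0:
            raise CalibrationError("slope must be nonzero")
        if self.fit_residual_rms < 0:
            raise CalibrationError("fit_residual_rms must be >= 0")


def fit_calibration(peak_pixels, known_wavelengths,
                    reference_offset: float = 0.0) -> SpectralCalibration:
    """Least-squares line ``wavelength = slope * pixel + intercept``.

    ``peak_pixels`` are displacements relative to the zeroth-order
    reference position (after subtracting ``reference_offset``).
    """
    px = np.asarray(peak_pixels, dtype=np.float64)
    wl = np.asarray(known_wavelengths, dtype=np.float64)
    if px.shape != wl.shape or px.ndim != 1:
        raise CalibrationError("peak_pixels and known_wavelengths must match")
    if px.size < 2:
        raise CalibrationError("at least two calibration points are required")
    if np.ptp(px) == 0:
        raise CalibrationError("all peak pixels identical; cannot fit a line")
    slope, intercept = np.polyfit(px, wl, 1)
    resid = wl - (slope * px + intercept)
    return SpectralCalibration(
        slope=float(slope), intercept=float(intercept),
        reference_offset=float(reference_offset),
        fit_residual_rms=float(np.sqrt(np.mean(resid ** 2))))


def pixel_to_wavelength(cal: SpectralCalibration, spatial_x: float,
                        spectral_x) -> float | np.ndarray:
    """Wavelength at a spectral-image column, referenced to the emitter's
    zeroth-order position (both in pixels)."""
    return cal.slope * (np.asarray(spectral_x, dtype=np.float64)
                        - spatial_x - cal.reference_offset) + cal.intercept


def wavelength_to_pixel(cal: SpectralCalibration, spatial_x: float,
                        wavelength) -> float | np.ndarray:
    """Inverse of :func:`pixel_to_wavelength`."""
    return (np.asarray(wavelength, dtype=np.float64) - cal.intercept) / cal.slope \
        + spatial_x + cal.reference_offset


def _gauss(x, a, mu, sigma, c):
    return a * np.exp(-((x - mu) ** 2) / (2 * sigma ** 2)) + c


def find_line_peaks(image: np.ndarray, n_lines: int,
                    min_separation_px: int = 5) -> np.ndarray:
    """Sub-pixel column positions of vertical calibration lines.

    The image is collapsed to a column-mean profile; candidate maxima are
    refined by a 1-D Gaussian fit on a local window.
    """
    profile = np.asarray(image, dtype=np.float64).mean(axis=0)
    idx, props = find_peaks(profile, distance=min_separation_px,
                            prominence=np.ptp(profile) * 0.05)
    if idx.size < n_lines:
        raise CalibrationError(
            f"found only {idx.size} candidate lines, expected {n_lines}")
    # Keep the n most prominent, in ascending pixel order.
    keep = np.sort(idx[np.argsort(props["prominences"])[::-1][:n_lines]])
    centers = []
    half = max(3, min_separation_px // 2)
    x = np.arange(profile.size, dtype=np.float64)
    for p in keep:
        lo, hi = max(0, p - half), min(profile.size, p + half + 1)
        xs, ys = x[lo:hi], profile[lo:hi]
        try:
            popt, _ = curve_fit(
                _gauss, xs, ys,
                p0=[ys.max() - ys.min(), float(p), 1.5, ys.min()],
                maxfev=5000)
            mu = float(popt[1])
            centers.append(mu if lo <= mu <= hi else float(p))
        except RuntimeError:
            centers.append(float(p))
    return np.asarray(centers)


def save_calibration(cal: SpectralCalibration, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(cal), indent=2))


def load_calibration(path: str | Path) -> SpectralCalibration:
    return SpectralCalibration(**json.loads(Path(path).read_text()))
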