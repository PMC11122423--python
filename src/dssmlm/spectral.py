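"""Spectral analysis of enhanced ROIs: 1-D spectra, peaks, windows, channels."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .calibration import SpectralCalibration, pixel_to_wavelength
from .enhancer import SpectralROI


class NoPeak(ValueError):
    """Raised when a spectrum is flat/invalid and has no defined peak."""


@dataclass(frozen=True)
class Spectrum1D:
    wavelengths: np.ndarray   # nm, one per ROI column
    intensities: np.ndarray   # max-normalized profile
    peak_wavelength: float | None = None
    valid: bool = True

    def __post_init__(self):
        if len(self.wavelengths) != len(self.intensities):
            raise ValueError("wavelengths and intensities must match in length")


@dataclass(frozen=True)
class Localization:
    frame: int
    x: float            # nm
    y: float            # nm
    wavelength: float | None = None
    photons: float = 0.0
    merged_count: int = 1
    channel: str | None = None

    def __post_init__(self):
        if self.merged_count < 1:
            raise ValueError("merged_count must be >= 1")


@dataclass(frozen=True)
class ChannelSpec:
    name: str
    window: tuple[float, float]  # [nm, nm], inclusive

    def __post_init__(self):
        if not self.window[0] < self.window[1]:
            raise ValueError("window must satisfy lambda_min < lambda_max")


def extract_spectrum(roi: SpectralROI, cal: SpectralCalibration,
                     camera_pixel_size: float = 100.0) -> Spectrum1D:
    """Column-wise mean profile of a spectral ROI, max-normalized, with
    wavelengths obtained from the calibration referenced to the owning
    localization's spatial position."""
    pixels = np.asarray(roi.pixels, dtype=np.float64)
    if pixels.size == 0:
        raise ValueError("empty ROI")
    profile = pixels.mean(axis=0)
    cols = roi.roi_origin[1] + np.arange(pixels.shape[1])
    spatial_x_px = roi.anchor[0] / camera_pixel_size
    wavelengths = pixel_to_wavelength(cal, spatial_x_px, cols)
    rng = profile.max() - profile.min()
    if profile.max() <= 0 or rng == 0:
        # all-zero or perfectly flat: no spectral signature
        flat = np.ones_like(profile) if profile.max() > 0 else profile
        return Spectrum1D(wavelengths, flat, None, valid=False)
    intensities = profile / profile.max()
    peak = float(wavelengths[int(np.argmax(intensities))])
    return Spectrum1D(wavelengths, intensities, peak, valid=True)


def find_peak(spec: Spectrum1D, parabolic: bool = False) -> float:
    """Wavelength of the global maximum (ties -> lower wavelength).

    With ``parabolic`` a 3-point parabolic refinement is applied around
    the discrete maximum.
    """
    if not spec.valid:
        raise NoPeak("flat or invalid spectrum")
    it = np.asarray(spec.intensities, dtype=np.float64)
    wl = np.asarray(spec.wavelengths, dtype=np.float64)
    order = np.argsort(wl)
    it, wl = it[order], wl[order]
    i = int(np.argmax(it))  # argmax returns the first (lowest-wavelength) tie
    if not parabolic or i == 0 or i == len(it) - 1:
        return float(wl[i])
    y0, y1, y2 = it[i - 1], it[i], it[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(wl[i])
    delta = 0.5 * (y0 - y2) / denom
    step = (wl[i + 1] - wl[i - 1]) / 2.0
    return float(wl[i] + np.clip(delta, -1, 1) * step)


def filter_by_window(locs: list[Localization],
                     window: tuple[float, float]) -> list[Localization]:
    """Keep localizations with lambda_min <= wavelength <= lambda_max
    (inclusive bounds); order preserved."""
    lo, hi = window
    if not lo < hi:
        raise ValueError("invalid spectral window")
    return [l for l in locs
            if l.wavelength is not None and lo <= l.wavelength <= hi]


def assign_channels(locs: list[Localization], channels: list[ChannelSpec]
                    ) -> dict[str, list[Localization]]:
    """Partition localizations into disjoint spectral-window channels plus
    an ``"unassigned"`` bin."""
    for i, a in enumerate(channels):
        for b in channels[i + 1:]:
            if a.window[0] <= b.window[1] and b.window[0] <= a.window[1]:
                raise ValueError(
                    f"channel windows {a.name} and {b.name} overlap")
    out: dict[str, list[Localization]] = {c.name: [] for c in channels}
    out["unassigned"] = []
    for l in locs:
        target = "unassigned"
        if l.wavelength is not None:
            for c in channels:
                if c.window[0] <= l.wavelength <= c.window[1]:
                    target = c.name
                    break
        out[target].append(replace(l, channel=None if target == "unassigned"
                                   else target))
    return out


DEFAULT_FILTER_WINDOWS = {
    "AF647": (640.0, 700.0),
    "CF680": (670.0, 730.0),
}

DEFAULT_TWO_COLOR_CHANNELS = [
    ChannelSpec("ATTO542", (550.0, 610.0)),
    ChannelSpec("ATTO655", (650.0, 710.0)),
]
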