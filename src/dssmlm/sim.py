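"""Synthetic sSMLM frame generator and training-set builders.

Each simulated acquisition frame is a pair of photon-count images: a
spatial image holding sparse 2-D Gaussian PSFs, and a spectral image in
which every emitter appears as its PSF convolved along the dispersion
axis with the dye's emission spectrum.  Shot (Poisson) noise and
Gaussian read noise are applied on top of a constant background.

Coordinate convention (shared by all modules): 0-based pixel indices,
positions in nm measured from the centre of the top-left pixel, x
rightward (the dispersion axis), y downward.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .calibration import SpectralCalibration


class ConfigError(ValueError):
    """Raised when an optics configuration cannot produce valid frames."""


@dataclass(frozen=True)
class OpticsConfig:
    """Physical parameters of the simulated (or real) instrument."""

    camera_pixel_size: float = 100.0     # nm / px
    psf_sigma: float = 130.0             # nm (~1.3 px)
    spectral_dispersion: float = 2.6     # nm / px along +x
    split_ratio: float = 0.75            # fraction of photons to spectral arm (1:3)
    background_rate: float = 7.0         # photons / px / frame
    read_noise_sd: float = 1.5           # e-
    fov: tuple[float, float] = (6.4, 6.4)  # (width, height) in um
    # Geometry tying the spectral image to the spatial one.
    reference_offset: float = 8.0        # px from spatial x to zero-displacement column
    calibration_intercept: float = 550.0  # nm at zero displacement
    dispersion_sign: int = 1             # +1: wavelength increases with +x
    spectral_width: int | None = None    # columns in spectral image (None: width + 64)
    # Photon budget per blinking event (lognormal); calibrated so that the
    # noisy-vs-clean spectral ROI SSIM at defaults is ~0.59.
    mean_photons: float = 5000.0
    photon_sd: float = 1500.0

    def __post_init__(self):
        for name in ("camera_pixel_size", "psf_sigma", "spectral_dispersion",
                     "background_rate", "mean_photons", "photon_sd"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        if not 0.0 < self.split_ratio < 1.0:
            raise ConfigError("split_ratio must lie in (0, 1)")
        if self.read_noise_sd < 0:
            raise ConfigError("read_noise_sd must be non-negative")
        if self.fov[0] <= 0 or self.fov[1] <= 0:
            raise ConfigError("fov must be strictly positive")
        if self.dispersion_sign not in (-1, 1):
            raise ConfigError("dispersion_sign must be +1 or -1")

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma / self.camera_pixel_size

    @property
    def frame_shape(self) -> tuple[int, int]:
        """(height, width) of the spatial image in pixels."""
        w = int(round(self.fov[0] * 1000.0 / self.camera_pixel_size))
        h = int(round(self.fov[1] * 1000.0 / self.camera_pixel_size))
        return h, w

    @property
    def spectral_shape(self) -> tuple[int, int]:
        h, w = self.frame_shape
        ws = self.spectral_width if self.spectral_width is not None else w + 64
        return h, ws


@dataclass(frozen=True)
class DyeSpectrum:
    """Tabulated relative emission spectrum of one fluorophore."""

    name: str
    wavelengths: np.ndarray  # nm, strictly increasing
    intensities: np.ndarray  # max-normalized to 1
    peak_wavelength: float = field(default=0.0)

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=np.float64)
        it = np.asarray(self.intensities, dtype=np.float64)
        if wl.ndim != 1 or wl.shape != it.shape:
            raise ValueError("wavelengths/intensities must be matching 1-D arrays")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(it < 0):
            raise ValueError("intensities must be non-negative")
        it = it / it.max()
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", it)
        object.__setattr__(self, "peak_wavelength", float(wl[int(np.argmax(it))]))


def _skewed_emission(name: str, peak: float, sigma_blue: float = 12.0,
                     sigma_red: float = 18.0) -> DyeSpectrum:
    wl = np.arange(peak - 60.0, peak + 121.0, 2.0)
    it = np.where(wl < peak,
                  np.exp(-((wl - peak) ** 2) / (2 * sigma_blue ** 2)),
                  np.exp(-((wl - peak) ** 2) / (2 * sigma_red ** 2)))
    return DyeSpectrum(name, wl, it)


def default_dyes() -> dict[str, DyeSpectrum]:
    """Approximate emission profiles of the dyes used throughout."""
    return {
        "AF647": _skewed_emission("AF647", 671.0),
        "CF680": _skewed_emission("CF680", 699.0),
        "ATTO542": _skewed_emission("ATTO542", 560.0),
        "ATTO655": _skewed_emission("ATTO655", 681.0),
    }


@dataclass(frozen=True)
class EmitterTruth:
    frame_index: int  # 1-based
    x: float          # nm
    y: float          # nm
    photons: float
    dye: DyeSpectrum

    def __post_init__(self):
        if self.frame_index < 1:
            raise ValueError("frame_index must be >= 1")
        if self.photons <= 0:
            raise ValueError("photons must be > 0")


@dataclass
class FramePair:
    spatial_image: np.ndarray
    spectral_image: np.ndarray
    frame_index: int

    def __post_init__(self):
        if self.spatial_image.shape[0] != self.spectral_image.shape[0]:
            raise ValueError("spatial and spectral images must share height")
        if self.frame_index < 1:
            raise ValueError("frame_index must be >= 1")


@dataclass
class TrainingPairSpatial:
    input_patch: np.ndarray
    target_grid: np.ndarray
    emitter_count: int


@dataclass
class TrainingPairSpectral:
    noisy_roi: np.ndarray
    clean_roi: np.ndarray
    roi_shape: tuple[int, int]


def true_calibration(optics: OpticsConfig) -> SpectralCalibration:
    """The exact pixel->wavelength map the simulator renders with."""
    return SpectralCalibration(
        slope=optics.dispersion_sign * optics.spectral_dispersion,
        intercept=optics.calibration_intercept,
        reference_offset=optics.reference_offset,
        fit_residual_rms=0.0,
    )


def _pixel_gauss(centers: np.ndarray, n_pix: int, sigma_px: float,
                 lo: int, hi: int) -> np.ndarray:
    """Pixel-integrated 1-D Gaussians.

    centers: (k,) continuous pixel positions; returns (k, hi-lo) with
    row k holding the integral of N(center_k, sigma) over each pixel.
    """
    edges = np.arange(lo, hi + 1, dtype=np.float64) - 0.5
    z = (edges[None, :] - np.asarray(centers, dtype=np.float64)[:, None])
    z /= (sigma_px * np.sqrt(2.0))
    cdf = 0.5 * (1.0 + erf(z))
    return np.diff(cdf, axis=1)


def _render_spatial(img: np.ndarray, cx: float, cy: float, mass: float,
                    sigma_px: float) -> None:
    h, w = img.shape
    r = int(np.ceil(5 * sigma_px)) + 1
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    gx = _pixel_gauss(np.array([cx]), w, sigma_px, x0, x1)[0]
    gy = _pixel_gauss(np.array([cy]), h, sigma_px, y0, y1)[0]
    img[y0:y1, x0:x1] += mass * np.outer(gy, gx)


def _spectrum_weights(dye: DyeSpectrum) -> np.ndarray:
    """Per-sample-point probability mass (trapezoid weights, unit sum)."""
    wl, it = dye.wavelengths, dye.intensities
    dw = np.empty_like(wl)
    dw[1:-1] = (wl[2:] - wl[:-2]) / 2.0
    dw[0] = wl[1] - wl[0]
    dw[-1] = wl[-1] - wl[-2]
    p = it * dw
    return p / p.sum()


def _render_spectral(img: np.ndarray, cx: float, cy: float, mass: float,
                     dye: DyeSpectrum, optics: OpticsConfig) -> None:
    """Spectral PSF: emission spectrum mapped through the dispersion,
    convolved with the Gaussian PSF profile in x, outer product with the
    Gaussian profile in y."""
    h, w = img.shape
    sigma_px = optics.psf_sigma_px
    slope = optics.dispersion_sign * optics.spectral_dispersion
    # Continuous column position of each spectrum sample point.
    xk = cx + optics.reference_offset + (dye.wavelengths - optics.calibration_intercept) / slope
    pk = _spectrum_weights(dye)
    r = int(np.ceil(5 * sigma_px)) + 1
    x0 = max(0, int(np.floor(xk.min())) - r)
    x1 = min(w, int(np.ceil(xk.max())) + r + 1)
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    gx = _pixel_gauss(xk, w, sigma_px, x0, x1)        # (k, ncols)
    sx = pk @ gx                                      # (ncols,)
    gy = _pixel_gauss(np.array([cy]), h, sigma_px, y0, y1)[0]
    img[y0:y1, x0:x1] += mass * np.outer(gy, sx)


def render_frame(optics: OpticsConfig, emitters: list[EmitterTruth],
                 frame_index: int) -> FramePair:
    """Noise-free expected-photon render (no background)."""
    spatial = np.zeros(optics.frame_shape, dtype=np.float64)
    spectral = np.zeros(optics.spectral_shape, dtype=np.float64)
    px = optics.camera_pixel_size
    for e in emitters:
        cx, cy = e.x / px, e.y / px
        _render_spatial(spatial, cx, cy, (1.0 - optics.split_ratio) * e.photons,
                        optics.psf_sigma_px)
        _render_spectral(spectral, cx, cy, optics.split_ratio * e.photons,
                         e.dye, optics)
    return FramePair(spatial, spectral, frame_index)


def _apply_noise(frame: FramePair, optics: OpticsConfig,
                 rng: np.random.Generator) -> FramePair:
    out = []
    for img in (frame.spatial_image, frame.spectral_image):
        noisy = rng.poisson(img + optics.background_rate).astype(np.float64)
        if optics.read_noise_sd > 0:
            noisy += rng.normal(0.0, optics.read_noise_sd, size=img.shape)
        out.append(noisy)
    return FramePair(out[0], out[1], frame.frame_index)


def simulate_stack(optics: OpticsConfig, dyes: list[DyeSpectrum], n_frames: int,
                   density: float, seed: int, noise: bool = True,
                   return_clean: bool = False):
    """Simulate a blinking-movie stack with ground truth.

    Emitter count per frame is Poisson(density x FOV area); positions are
    uniform over the FOV, photon budgets lognormal, dyes uniform over
    ``dyes``.  Returns ``(frames, truths)`` or, with ``return_clean``,
    ``(frames, clean_frames, truths)``.
    """
    if density <= 0:
        raise ValueError("density must be > 0")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if not dyes:
        raise ConfigError("at least one dye is required")
    h, w = optics.frame_shape
    min_extent = int(np.ceil(4 * optics.psf_sigma_px)) + 1
    if h < min_extent or w < min_extent:
        raise ConfigError("FOV too small to contain a single PSF")

    rng = np.random.default_rng(seed)
    area = optics.fov[0] * optics.fov[1]
    sigma_ln = np.sqrt(np.log(1.0 + (optics.photon_sd / optics.mean_photons) ** 2))
    mu_ln = np.log(optics.mean_photons) - sigma_ln ** 2 / 2.0
    fov_w_nm = optics.fov[0] * 1000.0
    fov_h_nm = optics.fov[1] * 1000.0

    frames, clean_frames, truths = [], [], []
    for fi in range(1, n_frames + 1):
        n_emit = rng.poisson(density * area)
        ems = []
        for _ in range(n_emit):
            ems.append(EmitterTruth(
                frame_index=fi,
                x=float(rng.uniform(0.0, fov_w_nm)),
                y=float(rng.uniform(0.0, fov_h_nm)),
                photons=float(rng.lognormal(mu_ln, sigma_ln)),
                dye=dyes[int(rng.integers(len(dyes)))],
            ))
        clean = render_frame(optics, ems, fi)
        noisy = _apply_noise(clean, optics, rng) if noise else clean
        frames.append(noisy)
        if return_clean:
            clean_frames.append(clean)
        truths.extend(ems)
    if return_clean:
        return frames, clean_frames, truths
    return frames, truths


def spike_index(position_px: float, upsampling: int) -> int:
    """Map a continuous pixel coordinate onto the upsampled target grid."""
    return int(round(position_px * upsampling))


def make_spatial_training_set(stack: list[FramePair], truths: list[EmitterTruth],
                              patch_size: int = 208, upsampling: int = 4,
                              n_pairs: int = 15000, seed: int = 0,
                              camera_pixel_size: float = 100.0,
                              min_emitters: int = 3,
                              per_spike_mass: float = 1.0) -> list[TrainingPairSpatial]:
    """Sample overlapping spatial patches with >= ``min_emitters`` emitters.

    Targets are upsampled grids with one spike of ``per_spike_mass`` at
    round(position_px * upsampling) per ground-truth emitter.
    """
    if upsampling < 1:
        raise ValueError("upsampling must be >= 1")
    h, w = stack[0].spatial_image.shape
    if patch_size > min(h, w):
        raise ValueError("patch_size exceeds frame size")

    by_frame: dict[int, list[EmitterTruth]] = {}
    for t in truths:
        by_frame.setdefault(t.frame_index, []).append(t)

    stride = max(1, patch_size // 2)
    origins = [(f, oy, ox)
               for f in range(len(stack))
               for oy in range(0, h - patch_size + 1, stride)
               for ox in range(0, w - patch_size + 1, stride)]
    rng = np.random.default_rng(seed)
    rng.shuffle(origins)

    hi = patch_size * upsampling - 1
    pairs: list[TrainingPairSpatial] = []
    for f, oy, ox in origins:
        if len(pairs) >= n_pairs:
            break
        frame = stack[f]
        inside = []
        for t in by_frame.get(frame.frame_index, []):
            rx = t.x / camera_pixel_size - ox
            ry = t.y / camera_pixel_size - oy
            ix, iy = spike_index(rx, upsampling), spike_index(ry, upsampling)
            if 0 <= ix <= hi and 0 <= iy <= hi:
                inside.append((iy, ix))
        if len(inside) < min_emitters:
            continue
        target = np.zeros((patch_size * upsampling, patch_size * upsampling),
                          dtype=np.float32)
        for iy, ix in inside:
            target[iy, ix] += per_spike_mass
        patch = frame.spatial_image[oy:oy + patch_size, ox:ox + patch_size]
        pairs.append(TrainingPairSpatial(patch.astype(np.float32), target, len(inside)))

    if len(pairs) < n_pairs:
        warnings.warn(
            f"requested {n_pairs} spatial training pairs but only "
            f"{len(pairs)} valid patches were found", stacklevel=2)
    return pairs


def make_spectral_training_set(stack_noisy: list[FramePair],
                               stack_clean: list[FramePair],
                               truths: list[EmitterTruth],
                               cal: SpectralCalibration,
                               mode: str = "labeled",
                               n_pairs: int = 143000,
                               seed: int = 0,
                               camera_pixel_size: float = 100.0) -> list[TrainingPairSpectral]:
    """Crop paired noisy/clean spectral-PSF ROIs around ground-truth emitters."""
    from .enhancer import RoiOutOfBounds, crop_spectral_roi

    if len(stack_noisy) != len(stack_clean):
        raise ValueError("noisy and clean stacks must have equal length")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(truths))
    pairs: list[TrainingPairSpectral] = []
    skipped = 0
    for i in order:
        if len(pairs) >= n_pairs:
            break
        t = truths[i]
        fn = stack_noisy[t.frame_index - 1]
        fc = stack_clean[t.frame_index - 1]
        try:
            roi_n = crop_spectral_roi(fn, (t.x, t.y), cal, mode,
                                      camera_pixel_size=camera_pixel_size)
            roi_c = crop_spectral_roi(fc, (t.x, t.y), cal, mode,
                                      camera_pixel_size=camera_pixel_size)
        except RoiOutOfBounds:
            skipped += 1
            continue
        pairs.append(TrainingPairSpectral(
            roi_n.pixels.astype(np.float32), roi_c.pixels.astype(np.float32),
            roi_n.pixels.shape))
    if len(pairs) < n_pairs:
        warnings.warn(
            f"requested {n_pairs} spectral training pairs but only "
            f"{len(pairs)} could be cropped ({skipped} skipped out-of-bounds)",
            stacklevel=2)
    return pairs


def labelfree_optics(**overrides) -> OpticsConfig:
    """Label-free (intrinsic-contrast) preset: low photon budget, finer dispersion."""
    base = dict(mean_photons=1000.0, photon_sd=300.0, spectral_dispersion=2.1,
                calibration_intercept=500.0, background_rate=7.0)
    base.update(overrides)
    return OpticsConfig(**base)
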